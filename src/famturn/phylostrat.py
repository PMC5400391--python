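"""Phylostratigraphic gene ages, detection-bias normalization, and
age-vs-induction analyses.

A gene's phylostratigraphic age is the divergence time of the deepest clade
containing a proteome with a detectable homolog, under fixed thresholds:
the best hit must cover at least 40% of the query protein's length and have
at least 20% identity.  The max rule is deliberately conservative -- one
qualifying deep hit makes a gene ancient regardless of younger hits.

Because short and rapidly evolving proteins are harder to detect at deep
strata, raw ages are biased young for such genes.  The normalization
regresses raw age on log-transformed, mean-centered expression (a proxy for
evolutionary rate) or length, and subtracts the fitted effect:
``normalized_age = age - beta * (log x - mean(log x))``; centering
preserves the mean age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy import stats

#: default age-category map: category name -> stratum (clade) name
DEFAULT_CATEGORIES = {
    "young": "Schizophora",
    "intermediate": "Insecta",
    "old": "Protostomia",
    "ancient": "Opisthokonta",
}

HIT_COLUMNS = ["gene", "proteome", "pident", "aln_len", "qlen"]


class PhylostratError(ValueError):
    pass


@dataclass(frozen=True)
class StrataKey:
    """Ordered strata (clade name, divergence age in MY, youngest first),
    the proteome-to-stratum assignment, and the four-category map."""

    strata: tuple                       # ((clade, age), ...) ages increasing
    proteome_to_stratum: dict
    categories: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORIES))
    focal_proteome: str | None = None

    def __post_init__(self):
        ages = [a for _, a in self.strata]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise PhylostratError("strata ages must be strictly increasing")
        known = {name for name, _ in self.strata}
        bad = set(self.proteome_to_stratum.values()) - known
        if bad:
            raise PhylostratError(f"proteomes assigned to unknown strata: {bad}")

    @property
    def ages(self) -> dict:
        return dict(self.strata)

    @property
    def youngest_age(self) -> float:
        return self.strata[0][1]

    def category_ages(self) -> dict:
        """category name -> reference age, ordered young to ancient."""
        ages = self.ages
        out = {}
        for cat, clade in self.categories.items():
            if clade not in ages:
                raise PhylostratError(f"category {cat!r} uses unknown stratum {clade!r}")
            out[cat] = ages[clade]
        return dict(sorted(out.items(), key=lambda kv: kv[1]))

    @classmethod
    def from_yaml(cls, path) -> "StrataKey":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            strata=tuple((s["name"], float(s["age"])) for s in doc["strata"]),
            proteome_to_stratum=dict(doc["proteomes"]),
            categories=dict(doc.get("categories", DEFAULT_CATEGORIES)),
            focal_proteome=doc.get("focal_proteome"),
        )

    def to_yaml(self, path) -> None:
        doc = {
            "strata": [{"name": n, "age": a} for n, a in self.strata],
            "proteomes": dict(self.proteome_to_stratum),
            "categories": dict(self.categories),
            "focal_proteome": self.focal_proteome,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def assign_ages(hits: pd.DataFrame, key: StrataKey,
                min_coverage: float = 0.40,
                min_identity: float = 20.0) -> pd.DataFrame:
    """Deepest-qualifying-hit age per gene.

    ``hits`` columns: gene, proteome, pident, aln_len, qlen.  Hits to the
    focal proteome (self/paralog evidence) are ignored.  Genes with no
    qualifying non-self hit get the youngest stratum's age.
    """
    missing = [c for c in HIT_COLUMNS if c not in hits.columns]
    if missing:
        raise PhylostratError(f"hit table missing columns {missing}")
    unknown = set(hits["proteome"]) - set(key.proteome_to_stratum) \
        - ({key.focal_proteome} if key.focal_proteome else set())
    if unknown:
        raise PhylostratError(f"unknown proteome ids: {sorted(unknown)[:5]}")
    df = hits[hits["proteome"] != key.focal_proteome].copy()
    qual = (df["aln_len"] >= min_coverage * df["qlen"]) & \
        (df["pident"] >= min_identity)
    ages_map = key.ages
    df["age"] = df["proteome"].map(key.proteome_to_stratum).map(ages_map)
    deepest = df.loc[qual].groupby("gene")["age"].max()
    genes = pd.Index(hits["gene"].unique(), name="gene")
    out = deepest.reindex(genes).fillna(key.youngest_age)
    return out.rename("age").reset_index()


def normalize_ages(records: pd.DataFrame, predictor: str = "expression",
                   pseudocount: float = 1.0) -> tuple:
    """Subtract the fitted linear effect of log(predictor) from raw ages.

    The predictor is log-transformed (with a pseudocount for expression,
    which can be zero) and mean-centered, so normalization preserves the
    mean age.  Returns ``(records with 'normalized_age', fitted beta)``.
    """
    if predictor not in records.columns:
        raise PhylostratError(f"no column {predictor!r} in records")
    vals = records[predictor].to_numpy(dtype=float)
    if predictor == "expression":
        vals = vals + pseudocount
    if np.any(vals <= 0):
        raise PhylostratError(f"{predictor} must be positive (after pseudocount)")
    x = np.log(vals)
    x = x - x.mean()
    if np.allclose(x, 0):
        raise PhylostratError(f"{predictor} is constant; slope undefined")
    age = records["age"].to_numpy(dtype=float)
    beta = float(np.dot(x, age) / np.dot(x, x))  # OLS slope, centered x
    out = records.copy()
    out["normalized_age"] = age - beta * x
    return out, beta


def induction_vs_age(records: pd.DataFrame, age_field: str = "age") -> tuple:
    """Logistic regression of the induced flag on age (MY).

    Returns ``(beta, se, p)`` for the age coefficient (Wald).
    """
    y = records["induced"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise PhylostratError("need both induced and non-induced genes")
    X = sm.add_constant(records[age_field].to_numpy(dtype=float))
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # includes perfect separation
        raise PhylostratError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise PhylostratError("logistic fit did not converge (separation?)")
    return float(res.params[1]), float(res.bse[1]), float(res.pvalues[1])


def categorize(ages: np.ndarray, key: StrataKey, snapped: bool = True) -> list:
    """Map ages to the four categories.

    Raw (stratum-valued) ages go to the youngest category whose reference
    age is at least the gene's age; continuous normalized ages go to the
    nearest category boundary, clamped to [youngest, oldest].
    """
    cat_ages = key.category_ages()
    cats = list(cat_ages)
    bounds = np.array([cat_ages[c] for c in cats])
    out = []
    for a in np.asarray(ages, dtype=float):
        if snapped:
            idx = int(np.searchsorted(bounds, a - 1e-9))
            idx = min(idx, len(cats) - 1)
        else:
            idx = int(np.argmin(np.abs(bounds - a)))
        out.append(cats[idx])
    return out


def category_analysis(records: pd.DataFrame, key: StrataKey,
                      age_field: str = "age",
                      correction: bool = False) -> pd.DataFrame:
    """Per-category induced proportion and chi-squared test of each
    category against the rest (no continuity correction by default)."""
    snapped = age_field == "age"
    cats = categorize(records[age_field].to_numpy(), key, snapped=snapped)
    df = records.assign(category=cats)
    order = list(key.category_ages())
    total_ind = df["induced"].sum()
    total_n = len(df)
    rows = []
    for cat in order:
        sub = df[df["category"] == cat]
        n = len(sub)
        if n == 0:
            rows.append({"category": cat, "n": 0, "n_induced": 0,
                         "prop_induced": np.nan, "p": np.nan})
            continue
        ind_in = int(sub["induced"].sum())
        ind_out = int(total_ind - ind_in)
        table = np.array([[ind_in, n - ind_in],
                          [ind_out, (total_n - n) - ind_out]])
        if table[1].sum() == 0 or np.any(table.sum(axis=0) == 0):
            p = np.nan
        else:
            p = float(stats.chi2_contingency(table, correction=correction)[1])
        rows.append({"category": cat, "n": n, "n_induced": ind_in,
                     "prop_induced": ind_in / n, "p": p})
    out = pd.DataFrame(rows)
    out.attrs["overall_prop_induced"] = float(total_ind / total_n)
    return out
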