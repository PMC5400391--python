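"""Poisson and mixed-Poisson regression of per-branch event counts.

The response for a (family, branch) row is an event count (duplications,
losses, or their sum = turnover); the natural log of the branch length
enters as an offset, so fitted coefficients are log event rates per unit
branch length.  Among-family rate heterogeneity -- the dominant source of
overdispersion in real gene-family data -- is absorbed by a per-family
Normal random intercept u_f ~ N(0, sigma^2); the marginal likelihood is
maximized directly, with the one-dimensional family integrals evaluated by
adaptive Gauss-Hermite quadrature (1 node = Laplace approximation).

The mixed likelihood exploits a Poisson identity: within a family the
linear predictor is eta_i + sigma*u, so the family log-likelihood depends
on the data only through S_f = sum_i y_i and C_f = sum_i exp(eta_i),

    l_f(u) = sigma*u*S_f - C_f*exp(sigma*u) - u^2/2  (+ const),

which is strictly concave in u; the conditional modes are found by a damped
Newton iteration vectorized across families.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.numdiff import approx_hess3

from .reconcile import BranchEventTable
from .treeio import SpeciesTree

LOG2PI = math.log(2.0 * math.pi)


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what.

    ``branch_terms`` maps a term name to a set of branch ids (indicator of
    lineage membership); ``family_terms`` are columns of the annotation
    table (0/1 flags or categoricals, which are dummy-expanded dropping the
    first level); ``interactions`` are (branch_term, family_term) pairs.
    ``drop_branches`` removes rows before fitting (e.g. basal lineages when
    per-clade rates are compared).
    """

    response: str = "turnover"
    branch_terms: tuple = ()          # ((name, frozenset of branch ids), ...)
    family_terms: tuple = ()
    interactions: tuple = ()
    random_intercept: bool = False
    aghq_nodes: int = 7
    drop_branches: frozenset = frozenset()

    def __post_init__(self):
        if self.response not in ("turnover", "duplication", "loss"):
            raise ValueError(f"unknown response {self.response!r}")
        if self.aghq_nodes < 1:
            raise ValueError("aghq_nodes must be >= 1")


@dataclass
class RateModelFit:
    """Fitted coefficients on the log-rate scale, with Wald SEs from the
    observed information of the (marginal) log-likelihood."""

    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    llf: float
    sigma2: float
    converged: bool
    boundary: bool
    n_obs: int
    n_families: int
    method: str

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2.0 * stats.norm.sf(np.abs(self.zvalues)),
                         index=self.params.index)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self.params,
            "se": self.bse,
            "z": self.zvalues,
            "p": self.pvalues,
        })


@dataclass
class ContrastResult:
    name: str
    contrast: np.ndarray
    estimate: float
    se: float
    z: float
    p: float
    p_adj: float
    adjust: str


@dataclass
class FamilyTestResult:
    """One row of the :func:`per_family_rates` result table: the focal-
    lineage log rate ratio for a single family with its BH q-value."""

    family: str
    estimate: float
    se: float
    p: float
    q: float
    boundary: bool


# ---------------------------------------------------------------------------
# design construction


def _data_frame(table) -> pd.DataFrame:
    return table.data if isinstance(table, BranchEventTable) else table


def build_design(table, spec: ModelSpec, annotations: pd.DataFrame | None = None):
    """Build (y, X, offset, family codes) from an event table and spec."""
    df = _data_frame(table)
    if spec.drop_branches:
        df = df[~df["branch"].isin(spec.drop_branches)]
    if len(df) == 0:
        raise ValueError("no rows left after branch filtering")
    if spec.response == "turnover":
        y = (df["dup"] + df["loss"]).to_numpy(dtype=float)
    else:
        col = "dup" if spec.response == "duplication" else "loss"
        y = df[col].to_numpy(dtype=float)
    if (df["length"] <= 0).any():
        raise ValueError("branch lengths must be positive for the log offset")
    offset = np.log(df["length"].to_numpy(dtype=float))

    cols = {"const": np.ones(len(df))}
    term_cols: dict = {}
    for name, branches in spec.branch_terms:
        cols[name] = df["branch"].isin(set(branches)).to_numpy(dtype=float)
        term_cols[name] = [name]
    if spec.family_terms:
        if annotations is None:
            raise ValueError("family_terms require an annotation table")
        ann = annotations.set_index("family") if "family" in annotations.columns \
            else annotations
        for term in spec.family_terms:
            vals = df["family"].map(ann[term])
            if vals.isna().any():
                missing = df.loc[vals.isna(), "family"].unique()[:5]
                raise ValueError(f"families missing annotation {term!r}: {list(missing)}")
            if pd.api.types.is_numeric_dtype(vals) or vals.dtype == bool:
                cols[term] = vals.to_numpy(dtype=float)
                term_cols[term] = [term]
            else:
                dummies = pd.get_dummies(vals, prefix=term, prefix_sep="[",
                                         drop_first=True)
                names = []
                for c in dummies.columns:
                    cname = c + "]"
                    cols[cname] = dummies[c].to_numpy(dtype=float)
                    names.append(cname)
                term_cols[term] = names
    for a, b in spec.interactions:
        for ca in term_cols[a]:
            for cb in term_cols[b]:
                cols[f"{ca}:{cb}"] = cols[ca] * cols[cb]
    X = pd.DataFrame(cols, index=df.index)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient after filtering")
    fam_codes, fam_ids = pd.factorize(df["family"], sort=False)
    return y, X, offset, fam_codes, list(fam_ids)


# ---------------------------------------------------------------------------
# naive Poisson (GLM)


def fit_poisson(table, spec: ModelSpec | None = None,
                annotations: pd.DataFrame | None = None) -> RateModelFit:
    """Maximum-likelihood Poisson regression (IRLS, log link, no random
    effects)."""
    spec = spec or ModelSpec()
    y, X, offset, fam, fam_ids = build_design(table, spec, annotations)
    if y.sum() == 0:
        raise FitError("all-zero response: the event rate MLE is at the "
                       "-inf boundary (no finite intercept)")
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    res = model.fit(maxiter=200)
    if not res.converged:
        raise FitError("IRLS did not converge")
    cov = pd.DataFrame(np.asarray(res.cov_params()), index=X.columns, columns=X.columns)
    return RateModelFit(
        params=pd.Series(np.asarray(res.params), index=X.columns),
        bse=pd.Series(np.asarray(res.bse), index=X.columns),
        cov=cov, llf=float(res.llf), sigma2=0.0,
        converged=True, boundary=False,
        n_obs=len(y), n_families=len(fam_ids), method="glm",
    )


# ---------------------------------------------------------------------------
# mixed Poisson (marginal ML via AGHQ)


def _safe_inverse(H: np.ndarray) -> np.ndarray:
    """Invert an observed-information matrix, clipping non-positive
    curvature directions (numerical-differentiation noise near flat
    optima) to a small positive value."""
    H = 0.5 * (H + H.T)
    w, V = np.linalg.eigh(H)
    floor = max(1e-8, 1e-10 * np.max(np.abs(w)))
    w = np.maximum(w, floor)
    return (V / w) @ V.T


def _family_stats(y, eta0, fam, n_fam):
    """Per-family S_f = sum y and logC_f = logsumexp(eta0)."""
    S = np.bincount(fam, weights=y, minlength=n_fam)
    mx = np.full(n_fam, -np.inf)
    np.maximum.at(mx, fam, eta0)
    with np.errstate(over="ignore"):
        sumexp = np.bincount(fam, weights=np.exp(eta0 - mx[fam]), minlength=n_fam)
    logC = mx + np.log(sumexp)
    return S, logC


def _conditional_modes(S, logC, sig, u0=None, tol=1e-10, maxiter=100):
    """Damped Newton for the strictly concave per-family integrands."""
    u = np.zeros_like(S) if u0 is None else u0.copy()
    for _ in range(maxiter):
        logE = np.minimum(logC + sig * u, 700.0)
        E = np.exp(logE)
        g = sig * (S - E) - u
        h = -(sig * sig) * E - 1.0
        step = np.clip(g / h, -4.0, 4.0)
        u = u - step
        if np.max(np.abs(g)) < tol:
            break
    return u


def _marginal_loglik(theta, y, X, offset, fam, n_fam, z, w, lgam_sum):
    beta, logsig = theta[:-1], theta[-1]
    sig = math.exp(logsig)
    eta0 = X @ beta + offset
    S, logC = _family_stats(y, eta0, fam, n_fam)
    const_beta = float(y @ eta0) - lgam_sum
    u = _conditional_modes(S, logC, sig)
    logE = np.minimum(logC + sig * u, 700.0)
    shalf = 1.0 / np.sqrt((sig * sig) * np.exp(logE) + 1.0)
    U = u[:, None] + math.sqrt(2.0) * shalf[:, None] * z[None, :]
    with np.errstate(over="ignore"):
        lU = sig * U * S[:, None] - np.exp(np.minimum(logC[:, None] + sig * U, 700.0)) \
            - 0.5 * U * U
    ll_f = np.log(math.sqrt(2.0) * shalf) + logsumexp(
        lU + np.log(w)[None, :] + (z * z)[None, :], axis=1)
    return float(ll_f.sum()) + const_beta - 0.5 * LOG2PI * n_fam


def fit_poisson_mixed(table, spec: ModelSpec | None = None,
                      annotations: pd.DataFrame | None = None,
                      start: np.ndarray | None = None) -> RateModelFit:
    """Poisson regression with a per-family Normal random intercept.

    Marginal ML over (beta, log sigma); adaptive Gauss-Hermite quadrature
    with ``spec.aghq_nodes`` nodes (1 = Laplace).  A vanishing sigma is a
    valid boundary fit, flagged via ``boundary``; fixed-effect SEs are then
    taken at sigma fixed to its estimate.
    """
    spec = spec or ModelSpec(random_intercept=True)
    y, X, offset, fam, fam_ids = build_design(table, spec, annotations)
    n_fam = len(fam_ids)
    if n_fam < 2:
        raise FitError("mixed model requires >= 2 families")
    if y.sum() == 0:
        raise FitError("all-zero response")
    Xv = X.to_numpy()
    lgam_sum = float(gammaln(y + 1.0).sum())
    z, w = hermgauss(spec.aghq_nodes)

    def negll(theta):
        return -_marginal_loglik(theta, y, Xv, offset, fam, n_fam, z, w, lgam_sum)

    if start is None:
        naive = fit_poisson(table, ModelSpec(
            response=spec.response, branch_terms=spec.branch_terms,
            family_terms=spec.family_terms, interactions=spec.interactions,
            drop_branches=spec.drop_branches), annotations)
        start = np.append(naive.params.to_numpy(), math.log(0.5))
    res = optimize.minimize(negll, start, method="BFGS",
                            options={"gtol": 1e-6, "maxiter": 500})
    if not res.success:
        res2 = optimize.minimize(negll, res.x, method="Nelder-Mead",
                                 options={"xatol": 1e-8, "fatol": 1e-8,
                                          "maxiter": 5000})
        if res2.fun <= res.fun:
            res = res2
    theta = res.x
    sig = math.exp(theta[-1])
    boundary = sig < 1e-3
    k = Xv.shape[1]
    if boundary:
        # at sigma = 0 the marginal likelihood is the plain GLM likelihood;
        # polish the boundary fit so llf >= the naive fit exactly
        glm_theta = np.append(naive.params.to_numpy(), -30.0) if start is None \
            else np.append(theta[:k], -30.0)
        if negll(glm_theta) <= res.fun:
            theta = glm_theta
            res.fun = negll(glm_theta)
            sig = 0.0
    if boundary:
        # information in log sigma vanishes at the boundary; profile it out
        def negll_beta(beta):
            return negll(np.append(beta, theta[-1]))
        H = approx_hess3(theta[:-1], negll_beta)
        cov_b = _safe_inverse(H)
    else:
        H = approx_hess3(theta, negll)
        cov_b = _safe_inverse(H)[:k, :k]
    bse = np.sqrt(np.diag(cov_b))
    if not np.all(np.isfinite(bse)) or np.any(bse == 0):
        raise FitError("singular observed information at the optimum")
    return RateModelFit(
        params=pd.Series(theta[:k], index=X.columns),
        bse=pd.Series(bse, index=X.columns),
        cov=pd.DataFrame(cov_b, index=X.columns, columns=X.columns),
        llf=-float(res.fun), sigma2=sig * sig,
        converged=bool(res.success or np.isfinite(res.fun)),
        boundary=boundary,
        n_obs=len(y), n_families=n_fam,
        method=f"aghq{spec.aghq_nodes}",
    )


# ---------------------------------------------------------------------------
# inference helpers


def linear_contrast(fit: RateModelFit, contrasts, adjust: str = "holm",
                    names=None) -> list:
    """Wald z tests of H0: c'beta = 0 for a set of contrast vectors, with
    optional Holm or Bonferroni adjustment across the set."""
    if adjust not in ("none", "holm", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    C = [np.asarray(c, dtype=float) for c in contrasts]
    k = len(fit.params)
    V = fit.cov.to_numpy()
    b = fit.params.to_numpy()
    names = names or [f"c{i}" for i in range(len(C))]
    rows = []
    for name, c in zip(names, C):
        if c.shape != (k,):
            raise ValueError(f"contrast {name!r} has length {c.size}, expected {k}")
        est = float(c @ b)
        var = float(c @ V @ c)
        if np.all(c == 0):
            rows.append((name, c, 0.0, 0.0, 0.0, 1.0))
            continue
        if var <= 0:
            raise ValueError(f"contrast {name!r}: singular covariance (c'Vc <= 0)")
        se = math.sqrt(var)
        zstat = est / se
        p = 2.0 * stats.norm.sf(abs(zstat))
        rows.append((name, c, est, se, zstat, p))
    ps = [r[5] for r in rows]
    if adjust == "none":
        padj = ps
    else:
        padj = multipletests(ps, method=adjust)[1]
    return [
        ContrastResult(name, c, est, se, zstat, p, float(pa), adjust)
        for (name, c, est, se, zstat, p), pa in zip(rows, padj)
    ]


def per_family_rates(table, st: SpeciesTree, musca_branch) -> tuple:
    """Per-family turnover model: intercept + focal-lineage indicator.

    ``musca_branch`` is a branch id or set of branch ids defining the focal
    lineage.  Families with zero events are skipped (no information); a
    family whose events fall entirely on or entirely off the focal lineage
    is a boundary case (the lineage coefficient diverges) and is flagged.
    Returns ``(results DataFrame with BH q-values, skipped family list)``.
    """
    focal = {musca_branch} if isinstance(musca_branch, str) else set(musca_branch)
    df = _data_frame(table).copy()
    df["y"] = df["dup"] + df["loss"]
    df["x"] = df["branch"].isin(focal).astype(float)
    results, skipped = [], []
    for fam, sub in df.groupby("family", sort=False):
        if sub["y"].sum() == 0 or len(sub) < 2:
            skipped.append(fam)
            continue
        y_on = sub.loc[sub["x"] == 1, "y"].sum()
        y_off = sub.loc[sub["x"] == 0, "y"].sum()
        boundary = (y_on == 0) or (y_off == 0)
        X = np.column_stack([np.ones(len(sub)), sub["x"].to_numpy()])
        try:
            with warnings.catch_warnings():
                # boundary families separate perfectly by construction; the
                # flag below records that instead of a warning per family
                warnings.simplefilter("ignore")
                res = sm.GLM(sub["y"].to_numpy(), X, family=sm.families.Poisson(),
                             offset=np.log(sub["length"].to_numpy())).fit(maxiter=100)
            est, se = float(res.params[1]), float(res.bse[1])
            p = 2.0 * stats.norm.sf(abs(est / se)) if se > 0 else 1.0
        except Exception:
            skipped.append(fam)
            continue
        results.append({"family": fam, "estimate": est, "se": se, "p": p,
                        "boundary": boundary})
    if not results:
        raise FitError("no family had enough events to fit")
    out = pd.DataFrame(results)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out[["family", "estimate", "se", "p", "q", "boundary"]], skipped


def enrichment_fisher(a: int, b: int, c: int, d: int) -> tuple:
    """Two-sided Fisher exact test of the 2x2 table [[a, b], [c, d]].

    Conditional (hypergeometric) two-sided p summing tables at most as
    probable as the observed one; returns (sample odds ratio a*d/(b*c), p).
    """
    cells = [a, b, c, d]
    if any((not float(x).is_integer()) or x < 0 for x in cells):
        raise ValueError("cell counts must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("a margin of the 2x2 table is zero")
    orat = math.inf if b * c == 0 else (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return orat, float(p)


def filter_families(table: BranchEventTable, st: SpeciesTree) -> tuple:
    """Keep families basally present (gene-tree root maps to the species
    root) with at least one event on a real branch.

    Returns ``(filtered table, report dict)``.
    """
    meta = table.families
    basal = meta["lca"] == st.root
    with_events = meta["events"] > 0
    keep = meta.index[basal & with_events]
    report = {
        "input_families": len(meta),
        "dropped_not_basal": int((~basal).sum()),
        "dropped_no_events": int((basal & ~with_events).sum()),
        "kept": len(keep),
    }
    if len(keep) == 0:
        raise FitError(f"no families pass the filters: {report}")
    kept_set = set(keep)
    data = table.data[table.data["family"].isin(kept_set)].reset_index(drop=True)
    return BranchEventTable(data=data, families=meta.loc[keep]), report
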