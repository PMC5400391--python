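"""Synthetic inputs for every module: a calibrated stand-in dipteran
species tree, random ultrametric trees, family annotation tables, and a
phylostratigraphy data generator with planted effect sizes.

The 14-taxon fixture tree mirrors the clade structure used throughout the
package's worked examples -- Muscidae sister to Glossinidae+Drosophilidae
within Schizophora, with Culicidae (5 mosquitoes) as the outgroup -- and a
250-MY root-to-leaf depth with timetree-style internal calibrations.  The
exact branch lengths are plausible stand-ins, not published estimates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .phylostrat import DEFAULT_CATEGORIES, StrataKey
from .treeio import SpeciesTree, species_tree_from_newick

#: leaf sets of the named clades of the fixture tree
DROSOPHILIDS = ("Dmel", "Dyak", "Dana", "Dpse", "Dwil", "Dmoj", "Dvir")
MOSQUITOES = ("Agam", "Aste", "Adar", "Aaeg", "Cqui")

DIPTERAN_NEWICK = (
    "((Mdom:70,(Gmor:65,((((Dmel:15,Dyak:15):17,Dana:32):8,Dpse:40):10,"
    "(Dwil:45,(Dmoj:20,Dvir:20):25):5):15):5):180,"
    "(((Agam:30,Aste:30):70,Adar:100):80,(Aaeg:150,Cqui:150):30):70);"
)

IMMUNE_CLASSES = ("recognition", "signaling", "modulation", "effector")
HMM_FAMILIES = ("CEC", "LYS", "TEP", "PGRP", "NIM", "TLL", "PPO", "DEF")


def dipteran_tree() -> SpeciesTree:
    """The fixed 14-taxon dipteran-like fixture tree (26 branches, 250 MY
    deep)."""
    return species_tree_from_newick(DIPTERAN_NEWICK)


def make_species_tree(n_species: int, depth: float = 250.0,
                      seed: int = 0) -> SpeciesTree:
    """Random rooted binary ultrametric tree: random topology by sequential
    joins, internal node ages drawn uniformly below the parent's age."""
    if n_species < 3:
        raise ValueError("need at least 3 species")
    rng = np.random.default_rng(seed)
    names = [f"sp{i}" for i in range(n_species)]
    # random topology: repeatedly join two random subtrees
    nodes = [(nm,) for nm in names]
    joins = []
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(("join", a, b))
        joins.append(nodes[-1])

    def age_and_newick(node, parent_age):
        if node[0] != "join":
            return 0.0, node[0], None
        my_age = parent_age * rng.uniform(0.4, 0.95) if parent_age is not None else depth
        parts = []
        for child in (node[1], node[2]):
            c_age, c_nwk, _ = age_and_newick(child, my_age)
            parts.append(f"{c_nwk}:{my_age - c_age:.17g}")
        return my_age, "(" + ",".join(parts) + ")", None

    _, nwk, _ = age_and_newick(nodes[0], None)
    return species_tree_from_newick(nwk + ";")


def make_annotations(n_families: int, frac_immune: float = 0.033,
                     class_probs=None, seed: int = 0,
                     family_ids=None) -> pd.DataFrame:
    """Family covariate table: immune flag, functional class, HMM family.

    Nonimmune families get class and HMM family "none".  The default
    immune fraction matches the rough share of immune orthogroups among
    all dipteran gene families.
    """
    rng = np.random.default_rng(seed)
    if family_ids is None:
        family_ids = [f"fam{i}" for i in range(n_families)]
    if len(family_ids) != n_families:
        raise ValueError("family_ids length mismatch")
    if class_probs is None:
        class_probs = np.full(len(IMMUNE_CLASSES), 1.0 / len(IMMUNE_CLASSES))
    immune = (rng.random(n_families) < frac_immune).astype(int)
    classes = np.where(
        immune == 1,
        rng.choice(IMMUNE_CLASSES, size=n_families, p=class_probs),
        "none",
    )
    hmms = np.where(
        immune == 1, rng.choice(HMM_FAMILIES, size=n_families), "none")
    return pd.DataFrame({
        "family": family_ids,
        "immune": immune,
        "class": classes,
        "hmm_family": hmms,
    })


DEFAULT_STRATA = (
    ("Schizophora", 66.0),
    ("Insecta", 400.0),
    ("Protostomia", 700.0),
    ("Opisthokonta", 950.0),
)


def default_strata_key() -> StrataKey:
    proteomes = {}
    for name, _ in DEFAULT_STRATA:
        for k in (1, 2):
            proteomes[f"{name}_p{k}"] = name
    return StrataKey(
        strata=DEFAULT_STRATA,
        proteome_to_stratum=proteomes,
        categories=dict(DEFAULT_CATEGORIES),
        focal_proteome="Mdom_self",
    )


def make_phylostrat_data(n_genes: int = 2000,
                         key: StrataKey | None = None,
                         age_expr_slope: float = 0.8,
                         induction_beta: float = -5.5e-4,
                         baseline_induced: float = 0.081,
                         stratum_probs=(0.30, 0.30, 0.20, 0.20),
                         seed: int = 0) -> tuple:
    """Generate (hits, genes, key) with planted effect sizes.

    Detection-bias structure: a latent z = age_expr_slope * x + noise (x is
    the standardized log-expression deviation) is cut at the quantiles of
    ``stratum_probs`` to pick each gene's true stratum, so highly expressed
    genes tend to look older, as homology detection bias produces in real
    phylostratigraphy.  Induction is then drawn from a logistic model in
    the (snapped) stratum age with slope ``induction_beta`` per MY,
    calibrated so the mean induced fraction is ``baseline_induced``.

    Hits: every stratum at or below the gene's true stratum receives one
    qualifying best hit (coverage >= 50%, identity >= 30%), plus one
    non-qualifying decoy (coverage 20%) one stratum deeper, so the deepest-
    hit rule reconstructs the planted age exactly at default thresholds.
    """
    rng = np.random.default_rng(seed)
    key = key or default_strata_key()
    strata = list(key.strata)
    ages = np.array([a for _, a in strata])
    probs = np.asarray(stratum_probs, dtype=float)
    if len(probs) != len(strata):
        raise ValueError("stratum_probs length must match number of strata")
    probs = probs / probs.sum()

    x = rng.standard_normal(n_genes)                  # log-expression deviation
    z = age_expr_slope * x + rng.standard_normal(n_genes)
    cuts = np.quantile(z, np.cumsum(probs)[:-1])
    stratum_idx = np.searchsorted(cuts, z)
    age = ages[stratum_idx]

    expression = np.exp(3.0 + x)                      # mean normalized counts
    length = np.exp(rng.normal(5.9, 0.45, size=n_genes)).astype(int) + 50

    alpha = logit(baseline_induced) - induction_beta * float(age.mean())
    induced = (rng.random(n_genes) < expit(alpha + induction_beta * age)).astype(int)

    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    genes = pd.DataFrame({
        "gene": gene_ids,
        "true_age": age,
        "expression": expression,
        "induced": induced,
        "length": length,
    })

    stratum_proteomes = {}
    for name, _ in strata:
        stratum_proteomes[name] = [p for p, s in key.proteome_to_stratum.items()
                                   if s == name]
    hit_rows = []
    for g, sidx, qlen in zip(gene_ids, stratum_idx, length):
        for j in range(sidx + 1):
            prot = stratum_proteomes[strata[j][0]][0]
            hit_rows.append({
                "gene": g, "proteome": prot,
                "pident": float(rng.uniform(30.0, 90.0)),
                "aln_len": int(qlen * rng.uniform(0.5, 0.95)),
                "qlen": int(qlen),
            })
        if sidx + 1 < len(strata):  # non-qualifying decoy one stratum deeper
            prot = stratum_proteomes[strata[sidx + 1][0]][0]
            hit_rows.append({
                "gene": g, "proteome": prot,
                "pident": float(rng.uniform(10.0, 19.0)),
                "aln_len": int(qlen * 0.2),
                "qlen": int(qlen),
            })
    hits = pd.DataFrame(hit_rows)
    return hits, genes, key
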