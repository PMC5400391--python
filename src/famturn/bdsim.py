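"""Gene-family birth-death simulation inside a fixed species tree.

A family starts as a single gene lineage at the species-tree root, which
immediately enters both root-child branches (no stem edge).  Along each
branch every extant gene lineage independently duplicates at rate ``lambda``
and is lost at rate ``mu``; sampling is exact (competing exponential risks,
Gillespie along the branch).  At every speciation node each surviving
lineage is copied into both child branches.  The observable gene tree is
the true tree with all-extinct subtrees pruned and unary nodes suppressed.

Filters mirror common guest-tree simulator practice: observable leaf-count
bounds, per-species copy-number bounds, and a root-survival filter that
requires extant descendants in both subtrees below the species root (a
family still basally present across the tree).
"""

from __future__ import annotations

import math
import sys
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .treeio import GeneTree, SpeciesTree


class SimulationError(RuntimeError):
    """Rejection sampling cannot reach the requested number of families."""


class _Explosion(Exception):
    """Internal: a single family exceeded the event cap; treated as a
    rejected attempt by the batch sampler."""


@dataclass(frozen=True)
class SimulationConfig:
    duplication_rate: float
    loss_rate: float
    n_families: int = 1000
    min_leaves: int = 4
    max_leaves: int = 10_000
    min_per_species: int = 0
    max_per_species: int = 10_000
    root_survival_filter: bool = True
    rng_seed: int | None = None
    event_cap: int = 500_000
    max_attempts: int | None = None

    def __post_init__(self):
        if not (math.isfinite(self.duplication_rate) and self.duplication_rate >= 0):
            raise ValueError("duplication_rate must be finite and >= 0")
        if not (math.isfinite(self.loss_rate) and self.loss_rate >= 0):
            raise ValueError("loss_rate must be finite and >= 0")
        if self.min_leaves > self.max_leaves:
            raise ValueError("min_leaves > max_leaves")
        if self.min_per_species > self.max_per_species:
            raise ValueError("min_per_species > max_per_species")
        if self.n_families <= 0:
            raise ValueError("n_families must be positive")


@dataclass
class SimulatedFamily:
    """One simulated family: observable tree (None if fully extinct), the
    true event log ``(branch, 'duplication'|'loss', time from branch start)``
    and per-branch true counts."""

    gene_tree: GeneTree | None
    events: list
    dup_true: Counter
    loss_true: Counter
    survived_root_filter: bool

    @property
    def extinct(self) -> bool:
        return self.gene_tree is None

    @property
    def n_leaves(self) -> int:
        return 0 if self.gene_tree is None else self.gene_tree.n_leaves

    def species_counts(self) -> dict:
        return {} if self.gene_tree is None else self.gene_tree.species_counts()


def simulate_family(st: SpeciesTree, cfg: SimulationConfig,
                    rng: np.random.Generator | None = None) -> SimulatedFamily:
    """Simulate one family; never rejects (the caller filters)."""
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    lam, mu = cfg.duplication_rate, cfg.loss_rate
    total = lam + mu
    pdup = lam / total if total > 0 else 0.0
    events: list = []
    dup_true: Counter = Counter()
    loss_true: Counter = Counter()
    nev = 0

    sys.setrecursionlimit(max(sys.getrecursionlimit(), 200_000))

    def evolve(branch: str, remaining: float):
        """One gene lineage on ``branch`` with ``remaining`` time to the
        branch-end node; returns the surviving observable structure or None."""
        nonlocal nev
        w = rng.exponential(1.0 / total) if total > 0 else math.inf
        if w < remaining:
            nev += 1
            if nev > cfg.event_cap:
                raise _Explosion
            t_event = st.length[branch] - (remaining - w)
            if rng.random() < pdup:
                events.append((branch, "duplication", t_event))
                dup_true[branch] += 1
                a = evolve(branch, remaining - w)
                b = evolve(branch, remaining - w)
                if a is not None and b is not None:
                    return ("node", a, b)
                return a if a is not None else b
            events.append((branch, "loss", t_event))
            loss_true[branch] += 1
            return None
        # reached the branch-end node
        ch = st.children[branch]
        if not ch:
            return ("leaf", branch)
        a = evolve(ch[0], st.length[ch[0]])
        b = evolve(ch[1], st.length[ch[1]])
        if a is not None and b is not None:
            return ("node", a, b)
        return a if a is not None else b

    c1, c2 = st.children[st.root]
    left = evolve(c1, st.length[c1])
    right = evolve(c2, st.length[c2])
    survived_root = left is not None and right is not None
    if left is not None and right is not None:
        struct = ("node", left, right)
    else:
        struct = left if left is not None else right

    gt = None if struct is None else _structure_to_gene_tree(struct)
    return SimulatedFamily(gt, events, dup_true, loss_true, survived_root)


def _structure_to_gene_tree(struct) -> GeneTree:
    """Convert the nested ('node', a, b) / ('leaf', species) structure into a
    GeneTree with deterministic leaf names ``<species>_g<k>``."""
    parent, children, postorder, species = {}, {}, [], {}
    sp_counter: Counter = Counter()
    next_internal = [0]

    out_id = {}
    stack = [(struct, False, None)]
    while stack:
        node, done, par = stack.pop()
        if not done:
            stack.append((node, True, par))
            if node[0] == "node":
                stack.append((node[2], False, node))
                stack.append((node[1], False, node))
            continue
        if node[0] == "leaf":
            sp = node[1]
            sp_counter[sp] += 1
            vid = f"{sp}_g{sp_counter[sp]}"
            species[vid] = sp
            children[vid] = ()
        else:
            vid = f"g{next_internal[0]}"
            next_internal[0] += 1
            children[vid] = (out_id[id(node[1])], out_id[id(node[2])])
            for c in children[vid]:
                parent[c] = vid
        out_id[id(node)] = vid
        postorder.append(vid)
    root = postorder[-1]
    parent[root] = None
    return GeneTree(root, parent, children, postorder, species)


def accepts(fam: SimulatedFamily, cfg: SimulationConfig,
            st: SpeciesTree | None = None) -> bool:
    """Apply the configured leaf-count, per-species and root-survival filters.

    ``st`` is only needed when ``min_per_species > 0`` (absent species count
    as zero copies)."""
    n = fam.n_leaves
    if n < cfg.min_leaves or n > cfg.max_leaves:
        return False
    counts = fam.species_counts()
    if max(counts.values(), default=0) > cfg.max_per_species:
        return False
    if cfg.min_per_species > 0:
        if st is None:
            raise ValueError("min_per_species > 0 requires the species tree")
        if any(counts.get(sp, 0) < cfg.min_per_species for sp in st.leaves):
            return False
    if cfg.root_survival_filter and not fam.survived_root_filter:
        return False
    return True


def simulate_batch(st: SpeciesTree, cfg: SimulationConfig,
                   rng: np.random.Generator | None = None):
    """Rejection-sample until ``cfg.n_families`` families pass the filters.

    Returns ``(families, stats)`` where stats records attempts and the
    realized acceptance rate.  Aborts with a diagnostic if the acceptance
    rate over a probe window falls below 1e-4.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    families, attempts, exploded = [], 0, 0
    cap = cfg.max_attempts or cfg.n_families * 20_000
    while len(families) < cfg.n_families:
        attempts += 1
        if attempts > cap:
            raise SimulationError(
                f"gave up after {attempts - 1} attempts with "
                f"{len(families)} accepted families"
            )
        try:
            fam = simulate_family(st, cfg, rng)
        except _Explosion:
            exploded += 1
            continue
        if accepts(fam, cfg, st):
            families.append(fam)
        if attempts % 5000 == 0 and len(families) / attempts < 1e-4:
            raise SimulationError(
                f"acceptance rate {len(families)}/{attempts} < 1e-4: rates "
                f"(dup={cfg.duplication_rate}, loss={cfg.loss_rate}) are too "
                "extreme for the configured filters"
            )
    stats = {
        "attempts": attempts,
        "accepted": len(families),
        "acceptance_rate": len(families) / attempts,
        "exploded": exploded,
    }
    return families, stats


def rate_grid(st: SpeciesTree, rates, n_per_rate: int, seed: int = 0,
              **cfg_kwargs) -> dict:
    """Run :func:`simulate_batch` at each rate with ``lambda = mu = rate``.

    Returns ``{rate: (families, stats)}``; each batch gets an independent
    child seed so the archive is reproducible as a whole.
    """
    out = {}
    for i, rate in enumerate(rates):
        cfg = SimulationConfig(
            duplication_rate=float(rate), loss_rate=float(rate),
            n_families=n_per_rate, **cfg_kwargs,
        )
        rng = np.random.default_rng([seed, i])
        out[float(rate)] = simulate_batch(st, cfg, rng)
    return out
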