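"""Parsimony (LCA) reconciliation of gene trees against a species tree.

Each gene-tree node ``v`` is mapped to the most recent common ancestor
``M(v)`` of its descendant species.  ``v`` is a duplication iff it maps to
the same species node as one of its children; the duplication is booked on
the branch above ``M(v)`` (pseudo-branch ``ROOT`` when ``M(v)`` is the
species root).  Losses follow the standard depth-difference convention: on
the gene-tree edge (u, v), every species node skipped strictly between
``M(u)`` and ``M(v)`` contributes one loss on its off-path child branch,
and when ``u`` is a duplication the path additionally starts at ``M(u)``
itself (the side not taken at ``M(u)`` is a loss).

Absence of the family outside the subtree it maps into is *not* counted as
loss: families are analyzed on the subtree where they are basally present,
and whether that subtree is the whole tree is a separate filtering step
(see :func:`famturn.turnover.filter_families`).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .treeio import ROOT_BRANCH, GeneTree, SpeciesTree


class ReconciliationError(ValueError):
    pass


@dataclass
class Reconciliation:
    """LCA map, per-node event calls, and per-species-branch event counts for
    one gene tree.  Counters are keyed by branch id; duplications mapping to
    the species root appear under ``ROOT``."""

    mapping: dict
    node_event: dict
    dup_counts: Counter
    loss_counts: Counter
    root_map: str

    @property
    def n_root_dups(self) -> int:
        return self.dup_counts.get(ROOT_BRANCH, 0)

    def total_events(self, include_root: bool = False) -> int:
        d = sum(self.dup_counts.values())
        if not include_root:
            d -= self.dup_counts.get(ROOT_BRANCH, 0)
        return d + sum(self.loss_counts.values())


def lca_reconcile(gt: GeneTree, st: SpeciesTree) -> Reconciliation:
    valid = set(st.leaves)
    M: dict = {}
    node_event: dict = {}
    dup_counts: Counter = Counter()
    loss_counts: Counter = Counter()

    for v in gt.postorder:
        ch = gt.children[v]
        if not ch:
            sp = gt.species.get(v)
            if sp not in valid:
                raise ReconciliationError(
                    f"gene-tree leaf {v!r} maps to unknown species {sp!r}"
                )
            M[v] = sp
        else:
            a, b = ch
            M[v] = st.lca(M[a], M[b])
            if M[v] == M[a] or M[v] == M[b]:
                node_event[v] = "duplication"
                branch = ROOT_BRANCH if M[v] == st.root else M[v]
                dup_counts[branch] += 1
            else:
                node_event[v] = "speciation"

    # losses along every gene-tree edge (u, v)
    for u in gt.postorder:
        for v in gt.children[u]:
            top, bot = M[u], M[v]
            if top == bot:
                continue
            path = [bot]
            x = bot
            while x != top:
                x = st.parent[x]
                path.append(x)
            # path[i] for i >= 1 are skipped ancestors; path[-1] == top
            last = len(path) - 1
            for i in range(1, len(path)):
                s = path[i]
                if i == last and node_event.get(u) != "duplication":
                    break
                on_path_child = path[i - 1]
                c1, c2 = st.children[s]
                off = c2 if c1 == on_path_child else c1
                loss_counts[off] += 1

    return Reconciliation(M, node_event, dup_counts, loss_counts, M[gt.root])


def split_at_root_duplications(gt: GeneTree, st: SpeciesTree) -> list:
    """Recursively split a gene tree while its root is a duplication.

    Returns the resulting trees in left-to-right order; each has a
    speciation (or single-leaf) root.  Mirrors the practice of splitting
    families that duplicated before the base of the species tree, which both
    removes un-datable root events and gives each basal copy its own family.
    """
    out = []
    queue = [gt]
    while queue:
        t = queue.pop(0)
        if t.n_leaves == 1:
            out.append(t)
            continue
        rec = lca_reconcile(t, st)
        if rec.node_event.get(t.root) == "duplication":
            a, b = t.children[t.root]
            queue = [t.subtree(a), t.subtree(b)] + queue
        else:
            out.append(t)
    return out


@dataclass
class BranchEventTable:
    """Dense long-format event table: one row per (family, non-root branch).

    ``data`` columns: family, branch, dup, loss, length.  ``families`` is a
    per-family summary (root map, leaf count, root duplications, total
    events on real branches) used by the basal-presence filter.
    """

    data: pd.DataFrame
    families: pd.DataFrame

    @property
    def family_ids(self) -> list:
        return list(self.families.index)

    def collapse(self) -> pd.DataFrame:
        """Aggregate to one row per family (Poisson additivity: sums of
        counts and of branch lengths are sufficient for family-constant
        covariate models)."""
        g = self.data.groupby("family", sort=False)
        out = g[["dup", "loss", "length"]].sum()
        out["branch"] = "TREE"
        return out.reset_index()


def build_event_table(recs, st: SpeciesTree) -> BranchEventTable:
    """Assemble reconciliations into a dense BranchEventTable.

    ``recs`` is an iterable of ``(family_id, Reconciliation)`` (or
    ``(family_id, GeneTree)``, reconciled on the fly).  Root-branch events
    are reported in the family summary but excluded from the data rows.
    """
    branches = st.branches
    lengths = [st.length[b] for b in branches]
    rows = []
    fam_rows = []
    seen = set()
    for fam, rec in recs:
        if fam in seen:
            raise ValueError(f"duplicate family id {fam!r}")
        seen.add(fam)
        if isinstance(rec, GeneTree):
            rec = lca_reconcile(rec, st)
        dups = [rec.dup_counts.get(b, 0) for b in branches]
        losses = [rec.loss_counts.get(b, 0) for b in branches]
        rows.append((fam, dups, losses))
        fam_rows.append({
            "family": fam,
            "lca": rec.root_map,
            "root_dups": rec.n_root_dups,
            "events": sum(dups) + sum(losses),
        })
    data = pd.DataFrame(
        [
            {"family": fam, "branch": b, "dup": d, "loss": l, "length": ln}
            for fam, dups, losses in rows
            for b, d, l, ln in zip(branches, dups, losses, lengths)
        ],
        columns=["family", "branch", "dup", "loss", "length"],
    )
    families = pd.DataFrame(fam_rows).set_index("family") if fam_rows else \
        pd.DataFrame(columns=["lca", "root_dups", "events"])
    return BranchEventTable(data=data, families=families)


def reconcile_families(gene_trees, st: SpeciesTree, split: bool = False,
                       names=None) -> BranchEventTable:
    """Reconcile a collection of gene trees into one event table.

    With ``split=True`` every tree is first split at root duplications and
    the parts become families ``<name>.1``, ``<name>.2``, ...
    """
    if names is None:
        names = [gt.name or f"fam{i}" for i, gt in enumerate(gene_trees)]
    pairs = []
    for name, gt in zip(names, gene_trees):
        if split:
            parts = split_at_root_duplications(gt, st)
            if len(parts) == 1:
                pairs.append((name, lca_reconcile(parts[0], st)))
            else:
                for j, part in enumerate(parts, 1):
                    pairs.append((f"{name}.{j}", lca_reconcile(part, st)))
        else:
            pairs.append((name, lca_reconcile(gt, st)))
    return build_event_table(pairs, st)
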