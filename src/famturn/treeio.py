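"""Tree input/output and the branch coordinate system.

Every downstream module addresses species-tree branches by the id of the
child node the branch subtends; the root subtends no branch.  Events that a
reconciliation places above the root are booked on the pseudo-branch
``ROOT``, which carries no length and is excluded from regression tables.

Species trees must be rooted, binary, and ultrametric (all root-to-leaf
path lengths equal within a relative tolerance): branch lengths act as the
time exposure (regression offset) for event counts, so a non-ultrametric
tree would silently distort rate comparisons between lineages.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import reduce
from pathlib import Path

import dendropy
import pandas as pd

#: id of the pseudo-branch above the species-tree root (no length; excluded
#: from regression tables).
ROOT_BRANCH = "ROOT"


class TreeValidationError(ValueError):
    """An input tree violates a structural requirement."""


def _assign_ids(dtree: dendropy.Tree) -> dict:
    """Deterministic node ids: leaf = taxon label, internal = existing label
    or ``N<postorder index>``."""
    ids = {}
    seen = set()
    for i, nd in enumerate(dtree.postorder_node_iter()):
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise TreeValidationError("leaf without a label")
            label = nd.taxon.label
        else:
            label = nd.label if nd.label else f"N{i}"
        if label in ids.values() or label in seen:
            raise TreeValidationError(f"duplicate node label {label!r}")
        seen.add(label)
        ids[nd] = label
    return ids


def _plain_structure(dtree: dendropy.Tree):
    ids = _assign_ids(dtree)
    parent, children, length, postorder = {}, {}, {}, []
    for nd in dtree.postorder_node_iter():
        v = ids[nd]
        postorder.append(v)
        children[v] = tuple(ids[c] for c in nd.child_nodes())
        parent[v] = ids[nd.parent_node] if nd.parent_node is not None else None
        if nd.parent_node is not None:
            length[v] = nd.edge.length
    root = ids[dtree.seed_node]
    return root, parent, children, length, postorder


@dataclass
class SpeciesTree:
    """Rooted binary ultrametric species tree.

    ``length[v]`` is the length of the branch *above* node ``v`` (the branch
    with id ``v``); the root carries no branch.  ``postorder`` visits
    children before parents and ends at the root.
    """

    root: str
    parent: dict
    children: dict
    length: dict
    postorder: list

    _depth: dict = field(default_factory=dict, repr=False)
    _level: dict = field(default_factory=dict, repr=False)
    _leafset: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for v in reversed(self.postorder):  # parents before children
            p = self.parent[v]
            if p is None:
                self._depth[v], self._level[v] = 0.0, 0
            else:
                self._depth[v] = self._depth[p] + self.length[v]
                self._level[v] = self._level[p] + 1
        for v in self.postorder:
            ch = self.children[v]
            if not ch:
                self._leafset[v] = frozenset([v])
            else:
                self._leafset[v] = frozenset().union(*(self._leafset[c] for c in ch))

    # -- structure queries -------------------------------------------------
    @property
    def leaves(self) -> list:
        return [v for v in self.postorder if not self.children[v]]

    @property
    def branches(self) -> list:
        """All branch ids (every non-root node), postorder."""
        return [v for v in self.postorder if v != self.root]

    def is_leaf(self, v) -> bool:
        return not self.children[v]

    def depth(self, v) -> float:
        """Path length from the root down to node ``v``."""
        return self._depth[v]

    def level(self, v) -> int:
        return self._level[v]

    def leaf_set(self, v) -> frozenset:
        return self._leafset[v]

    def lca(self, a: str, b: str) -> str:
        la, lb = self._level[a], self._level[b]
        while la > lb:
            a, la = self.parent[a], la - 1
        while lb > la:
            b, lb = self.parent[b], lb - 1
        while a != b:
            a, b = self.parent[a], self.parent[b]
        return a

    def mrca(self, nodes) -> str:
        return reduce(self.lca, nodes)

    def total_length(self) -> float:
        return float(sum(self.length.values()))

    def subtree_branches(self, v, include_stem: bool = True) -> frozenset:
        """Branch ids inside the clade rooted at ``v`` (optionally with the
        stem branch above ``v``)."""
        out = set()
        stack = [v]
        while stack:
            x = stack.pop()
            for c in self.children[x]:
                out.add(c)
                stack.append(c)
        if include_stem and v != self.root:
            out.add(v)
        return frozenset(out)

    # -- output ------------------------------------------------------------
    def _newick_node(self, v) -> str:
        ch = self.children[v]
        if not ch:
            body = v
        else:
            body = "(" + ",".join(self._newick_node(c) for c in ch) + ")"
        if self.parent[v] is None:
            return body
        return f"{body}:{self.length[v]:.17g}"

    def newick(self) -> str:
        return self._newick_node(self.root) + ";"

    def write(self, path) -> None:
        Path(path).write_text(self.newick() + "\n")


@dataclass(frozen=True)
class CladeSet:
    """A named set of species-tree branch ids used as a regression predicate."""

    name: str
    branches: frozenset
    exclude_basal: bool = False

    @classmethod
    def from_species(cls, st: SpeciesTree, name: str, species,
                     include_stem: bool = True) -> "CladeSet":
        m = st.mrca(list(species))
        return cls(name=name, branches=st.subtree_branches(m, include_stem))


@dataclass
class GeneTree:
    """Rooted gene tree with a leaf-to-species map.

    Branch lengths are irrelevant for parsimony reconciliation and are not
    stored.  ``event`` is filled by reconciliation (speciation/duplication
    call per internal node).
    """

    root: str
    parent: dict
    children: dict
    postorder: list
    species: dict
    name: str = ""
    event: dict = field(default_factory=dict)

    @property
    def leaves(self) -> list:
        return [v for v in self.postorder if not self.children[v]]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def species_counts(self) -> dict:
        out = {}
        for v in self.leaves:
            sp = self.species[v]
            out[sp] = out.get(sp, 0) + 1
        return out

    def subtree(self, v) -> "GeneTree":
        keep = []
        stack, seen = [v], []
        # iterative postorder
        stack = [(v, False)]
        while stack:
            x, done = stack.pop()
            if done:
                keep.append(x)
                continue
            stack.append((x, True))
            for c in reversed(self.children[x]):
                stack.append((c, False))
        kset = set(keep)
        return GeneTree(
            root=v,
            parent={x: (self.parent[x] if x != v else None) for x in kset},
            children={x: self.children[x] for x in kset},
            postorder=keep,
            species={x: s for x, s in self.species.items() if x in kset},
            name=self.name,
        )

    def _newick_node(self, v) -> str:
        ch = self.children[v]
        if not ch:
            return v
        return "(" + ",".join(self._newick_node(c) for c in ch) + ")"

    def newick(self) -> str:
        return self._newick_node(self.root) + ";"


# ---------------------------------------------------------------------------
# readers


def _validate_species(root, parent, children, length, postorder,
                      tolerance: float) -> SpeciesTree:
    for v in postorder:
        ch = children[v]
        if ch and len(ch) != 2:
            raise TreeValidationError(
                f"node {v!r} has {len(ch)} children; species trees must be binary"
            )
        if v != root:
            ln = length.get(v)
            if ln is None:
                raise TreeValidationError(f"branch above {v!r} has no length")
            if not ln > 0:
                raise TreeValidationError(
                    f"branch above {v!r} has non-positive length {ln}"
                )
    st = SpeciesTree(root, parent, children, length, postorder)
    lvs = st.leaves
    if len(lvs) < 2:
        raise TreeValidationError("species tree needs at least 2 leaves")
    depths = {v: st.depth(v) for v in lvs}
    hi = max(depths, key=depths.get)
    lo = min(depths, key=depths.get)
    if depths[hi] <= 0:
        raise TreeValidationError("tree has zero height")
    if (depths[hi] - depths[lo]) / depths[hi] > tolerance:
        raise TreeValidationError(
            "tree is not ultrametric: root-to-leaf depth "
            f"{depths[hi]:.6g} ({hi}) vs {depths[lo]:.6g} ({lo})"
        )
    return st


def species_tree_from_newick(newick: str, tolerance: float = 1e-6) -> SpeciesTree:
    dt = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return _validate_species(*_plain_structure(dt), tolerance=tolerance)


def read_species_tree(path, tolerance: float = 1e-6) -> SpeciesTree:
    """Read and validate a species tree from a Newick file."""
    dt = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    return _validate_species(*_plain_structure(dt), tolerance=tolerance)


def resolve_species(label: str, rule: dict):
    """Resolve a gene-tree leaf label to a species name.

    ``rule`` is ``{"mode": "prefix"|"regex"|"table", "value": ...}``: prefix
    splits at a separator (default ``_``), regex takes the first capture
    group, table is an explicit label-to-species mapping.
    """
    mode = rule.get("mode", "prefix")
    if mode == "prefix":
        sep = rule.get("value") or "_"
        return label.split(sep)[0] if sep in label else None
    if mode == "regex":
        m = re.match(rule["value"], label)
        return m.group(1) if m and m.groups() else None
    if mode == "table":
        return rule["value"].get(label)
    raise ValueError(f"unknown species-map mode {mode!r}")


def _gene_tree_from_dendropy(dt, rule, species_tree, name) -> GeneTree:
    dt.suppress_unifurcations()
    root, parent, children, length, postorder = _plain_structure(dt)
    species = {}
    valid = set(species_tree.leaves) if species_tree is not None else None
    for v in postorder:
        if children[v]:
            continue
        sp = resolve_species(v, rule)
        if sp is None or (valid is not None and sp not in valid):
            raise TreeValidationError(
                f"cannot resolve leaf label {v!r} to a known species"
            )
        species[v] = sp
    gt = GeneTree(root, parent, children, postorder, species, name=name)
    if gt.n_leaves < 1:
        raise TreeValidationError("empty gene tree")
    return gt


def gene_tree_from_newick(newick: str, rule: dict | None = None,
                          species_tree: SpeciesTree | None = None,
                          name: str = "") -> GeneTree:
    rule = rule or {"mode": "prefix"}
    dt = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return _gene_tree_from_dendropy(dt, rule, species_tree, name)


def read_gene_trees(path, rule: dict | None = None,
                    species_tree: SpeciesTree | None = None) -> list:
    """Read one or more Newick gene trees; leaf labels are resolved to
    species via ``rule`` and (optionally) validated against a species tree."""
    rule = rule or {"mode": "prefix"}
    tl = dendropy.TreeList.get(path=str(path), schema="newick",
                               preserve_underscores=True)
    out = []
    for i, dt in enumerate(tl):
        out.append(_gene_tree_from_dendropy(dt, rule, species_tree, name=f"fam{i}"))
    return out


def branch_table(st: SpeciesTree) -> pd.DataFrame:
    """One row per non-root branch: (branch, parent, child, length)."""
    rows = [
        {"branch": v, "parent": st.parent[v], "child": v, "length": st.length[v]}
        for v in st.branches
    ]
    return pd.DataFrame(rows, columns=["branch", "parent", "child", "length"])
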