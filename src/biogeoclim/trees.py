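"""Time-calibrated trees: containers, Newick round-trip and subtree extraction.

Node ages are in Ma before present; the root carries the oldest age. Internal
nodes must be binary (polytomies are rejected at read time); the root may be
unifurcating, which covers single-tip stem lineages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["TreeError", "TimeCalibratedTree", "read_newick", "parse_newick", "write_newick"]


class TreeError(ValueError):
    """Raised for malformed or non-time-calibrated tree input."""


@dataclass
class TimeCalibratedTree:
    """Rooted binary tree with node ages (Ma before present).

    Nodes are indexed 0..n_nodes-1 in a fixed order: tips first (sorted by
    label), then internal nodes in postorder. ``parent[root] == -1``.
    """

    parent: np.ndarray            # (n_nodes,) int, -1 at root
    children: list[tuple[int, ...]]
    ages: np.ndarray              # (n_nodes,) float, Ma
    tip_labels: list[str]         # labels for nodes 0..n_tips-1

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.ages = np.asarray(self.ages, dtype=float)
        self._validate()

    # -- basic structure -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root])

    def branch_length(self, node: int) -> float:
        p = self.parent[node]
        if p < 0:
            return 0.0
        return float(self.ages[p] - self.ages[node])

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return order[::-1]

    def tip_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.tip_labels)}

    def _validate(self) -> None:
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root, found {len(roots)}")
        for v, kids in enumerate(self.children):
            if v < self.n_tips and kids:
                raise TreeError(f"tip node {v} has children")
            if v >= self.n_tips and v != roots[0] and len(kids) != 2:
                raise TreeError(f"internal node {v} is not binary ({len(kids)} children)")
            if v == roots[0] and v >= self.n_tips and len(kids) not in (1, 2):
                raise TreeError(f"root has {len(kids)} children")
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0 and self.ages[p] < self.ages[v] - 1e-9:
                raise TreeError(
                    f"parent age {self.ages[p]:.6g} younger than child age "
                    f"{self.ages[v]:.6g} at node {v}"
                )
        if np.any(self.ages[: self.n_tips] < -1e-9):
            raise TreeError("tip ages must be >= 0")

    # -- distances -------------------------------------------------------
    def patristic_distances(self) -> np.ndarray:
        """Pairwise path lengths between tips (Myr)."""
        n = self.n_tips
        # depth of every node from root
        depth = self.root_age - self.ages
        # ancestor lists
        anc: list[list[int]] = []
        for t in range(n):
            path = [t]
            v = t
            while self.parent[v] >= 0:
                v = int(self.parent[v])
                path.append(v)
            anc.append(path)
        sets = [set(p) for p in anc]
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                mrca = next(v for v in anc[i] if v in sets[j])
                d[i, j] = d[j, i] = (depth[i] - depth[mrca]) + (depth[j] - depth[mrca])
        return d

    def subtree(self, tips: list[str]) -> "TimeCalibratedTree":
        """Induced subtree on ``tips``, rooted at their MRCA, with degree-2
        nodes suppressed (branch lengths merged)."""
        idx = self.tip_index()
        missing = [t for t in tips if t not in idx]
        if missing:
            raise TreeError(f"tips not in tree: {missing}")
        keep = {idx[t] for t in tips}
        if len(keep) < 2:
            raise TreeError("subtree needs at least two tips")
        # count retained descendants per node
        ndesc = np.zeros(self.n_nodes, dtype=int)
        for v in self.postorder():
            if v < self.n_tips:
                ndesc[v] = 1 if v in keep else 0
            else:
                ndesc[v] = sum(ndesc[c] for c in self.children[v])
        # new root: deepest node with all retained tips below
        total = len(keep)
        new_root = self.root
        changed = True
        while changed:
            changed = False
            for c in self.children[new_root]:
                if ndesc[c] == total:
                    new_root = c
                    changed = True
                    break

        def build(v: int) -> tuple:
            """Return nested (label, age, children) pruning non-retained."""
            if v < self.n_tips:
                return (self.tip_labels[v], float(self.ages[v]), [])
            kids = [c for c in self.children[v] if ndesc[c] > 0]
            if len(kids) == 1:
                return build(kids[0])
            return (None, float(self.ages[v]), [build(c) for c in kids])

        nested = build(new_root)
        return _from_nested(nested)

    # -- serialization ---------------------------------------------------
    def to_newick(self) -> str:
        def rec(v: int) -> str:
            bl = self.branch_length(v)
            if v < self.n_tips:
                return f"{_quote(self.tip_labels[v])}:{bl:.12g}"
            inner = ",".join(rec(c) for c in self.children[v])
            if self.parent[v] < 0:
                return f"({inner})"
            return f"({inner}):{bl:.12g}"

        return rec(self.root) + ";"


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _from_nested(nested) -> TimeCalibratedTree:
    tips: list[tuple[str, float]] = []
    internals: list[tuple[float, list]] = []

    def collect(node):
        label, age, kids = node
        if not kids:
            tips.append((label, age))
        else:
            for k in kids:
                collect(k)

    collect(nested)
    tip_labels = sorted(lab for lab, _ in tips)
    if len(set(tip_labels)) != len(tip_labels):
        raise TreeError("duplicate tip labels")
    n_tips = len(tip_labels)
    tip_pos = {lab: i for i, lab in enumerate(tip_labels)}
    parent: list[int] = [-1] * n_tips
    children: list[tuple[int, ...]] = [()] * n_tips
    ages: list[float] = [0.0] * n_tips

    def build(node) -> int:
        label, age, kids = node
        if not kids:
            i = tip_pos[label]
            ages[i] = age
            return i
        kid_ids = [build(k) for k in kids]
        i = len(parent)
        parent.append(-1)
        children.append(tuple(kid_ids))
        ages.append(age)
        for k in kid_ids:
            parent[k] = i
        return i

    build(nested)
    for lab, age in tips:
        ages[tip_pos[lab]] = age
    return TimeCalibratedTree(np.array(parent), children, np.array(ages), tip_labels)


def parse_newick(newick: str, root_age: float | None = None) -> TimeCalibratedTree:
    """Parse a Newick string into a :class:`TimeCalibratedTree`.

    Ages are ``root_age`` minus the path length from the root. When
    ``root_age`` is omitted the tree is assumed to reach the present: the
    root age is set to the maximum root-to-tip path length, so the deepest
    tips sit at age 0.
    """
    try:
        dt = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"Newick parse error: {exc}") from exc

    seed = dt.seed_node
    # depth from root, flagging negative branch lengths and polytomies
    depths: dict = {seed: 0.0}
    for nd in dt.preorder_node_iter():
        if nd is not seed:
            bl = nd.edge.length
            if bl is None:
                raise TreeError("branch without length in Newick input")
            if bl < 0:
                raise TreeError(f"negative branch length {bl}")
            depths[nd] = depths[nd.parent_node] + bl
        kids = nd.child_nodes()
        if nd is seed:
            if len(kids) > 2:
                raise TreeError(f"polytomy at root (node with {len(kids)} children)")
        elif kids and len(kids) != 2:
            lab = nd.taxon.label if nd.taxon else "internal"
            raise TreeError(f"polytomy at node '{lab}' ({len(kids)} children)")

    if root_age is None:
        root_age = max(depths[lf] for lf in dt.leaf_node_iter())
        if root_age == 0.0 and seed.edge.length:
            root_age = seed.edge.length

    def nested(nd) -> tuple:
        kids = nd.child_nodes()
        age = root_age - depths[nd]
        if not kids:
            if nd.taxon is None:
                raise TreeError("unlabelled tip in Newick input")
            return (nd.taxon.label, age, [])
        return (None, age, [nested(c) for c in kids])

    if not seed.child_nodes():
        # degenerate single-node tree; synthesize a stem from the root edge
        stem = seed.edge.length or 0.0
        if root_age is None:
            root_age = stem
        label = seed.taxon.label if seed.taxon else "tip"
        node = (None, root_age, [(label, root_age - stem, [])])
        return _from_nested(node)
    return _from_nested(nested(seed))


def read_newick(path, root_age: float | None = None) -> TimeCalibratedTree:
    """Read a Newick file; see :func:`parse_newick` for age conventions."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_newick(fh.read(), root_age=root_age)


def write_newick(tree: TimeCalibratedTree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.to_newick() + "\n")
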