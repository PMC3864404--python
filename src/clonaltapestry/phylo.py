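"""Mutational-profile phylogenies.

Per-sample mutation profiles (allelic ratios or binary presence calls) are
compared with a Pearson-correlation distance, an all-zero "control" profile is
appended to act as an aberration-free root, and the distance matrix is resolved
with neighbour joining (Saitou–Nei).  The same neighbour-joining engine is
reused for the copy-number architecture trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTROL_LABEL = "control"

__all__ = [
    "CONTROL_LABEL",
    "Node",
    "PhyloTree",
    "DistanceMatrix",
    "profile_distance_matrix",
    "neighbour_joining",
    "write_newick",
]


@dataclass
class Node:
    """A node of a (possibly multifurcating) tree.

    ``length`` is the branch length to the parent; it is meaningless on the
    root node and kept at 0 there.
    """

    name: str | None = None
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf():
            return [self]
        out: list[Node] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]  # type: ignore[misc]


@dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary internal root.

    ``control`` names the designated aberration-free leaf used as the
    outgroup when the tree is serialized.
    """

    root: Node
    control: str | None = None

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def path_distances(self) -> pd.DataFrame:
        """All pairwise leaf-to-leaf path distances (sum of branch lengths)."""
        dists: dict[str, dict[str, float]] = {}

        def walk(node: Node) -> dict[str, float]:
            # distance from every leaf under `node` to `node`
            if node.is_leaf():
                return {node.name: 0.0}  # type: ignore[dict-item]
            below: list[dict[str, float]] = []
            for c in node.children:
                sub = {k: v + c.length for k, v in walk(c).items()}
                below.append(sub)
            for i in range(len(below)):
                for j in range(i + 1, len(below)):
                    for a, da in below[i].items():
                        for b, db in below[j].items():
                            dists.setdefault(a, {})[b] = da + db
                            dists.setdefault(b, {})[a] = da + db
            merged: dict[str, float] = {}
            for sub in below:
                merged.update(sub)
            return merged

        walk(self.root)
        labels = sorted(self.leaf_names())
        mat = pd.DataFrame(0.0, index=labels, columns=labels)
        for a in labels:
            for b in labels:
                if a != b:
                    mat.loc[a, b] = dists[a][b]
        return mat


class DistanceMatrix:
    """A symmetric, hollow, non-negative labelled distance matrix."""

    def __init__(self, data: np.ndarray | pd.DataFrame, labels: list[str] | None = None):
        if isinstance(data, pd.DataFrame):
            labels = [str(c) for c in data.columns]
            data = data.to_numpy(dtype=float)
        if labels is None:
            raise ValueError("labels are required when data is an array")
        arr = np.asarray(data, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1] or arr.shape[0] != len(labels):
            raise ValueError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(arr)):
            raise ValueError("distance matrix contains non-finite entries")
        if not np.allclose(arr, arr.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(arr) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(arr < 0):
            raise ValueError("distances must be non-negative")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels")
        self.labels = list(labels)
        self.data = 0.5 * (arr + arr.T)

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.labels, columns=self.labels)


def _pearson_or_zero(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r, defined as 0 when either vector has zero variance.

    The convention keeps the all-zero control profile at distance 1 from
    every sample instead of producing an undefined correlation.
    """
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float((xc * yc).sum() / (sx * sy))


def profile_distance_matrix(matrix, mode: str = "vaf", add_control: bool = True) -> DistanceMatrix:
    """Pearson-correlation distance between per-sample mutation profiles.

    Parameters
    ----------
    matrix:
        A :class:`~clonaltapestry.presence.PresenceMatrix` (or any object with
        ``calls`` and ``vaf`` DataFrames indexed mutations x samples).
    mode:
        ``"vaf"`` uses the observed allelic ratios (inconclusive cells set to
        0); ``"binary"`` uses 1/0 presence calls.
    add_control:
        Append an all-zero profile labelled ``"control"`` acting as the
        aberration-free root.

    d(i, j) = 1 - r(profile_i, profile_j); zero-variance profiles get r = 0.
    """
    if mode not in ("vaf", "binary"):
        raise ValueError(f"unknown mode {mode!r}")
    calls = matrix.calls
    if calls.shape[0] < 2:
        raise ValueError("need at least 2 mutations to form profiles")
    if calls.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if mode == "binary":
        prof = (calls == "P").astype(float)
    else:
        prof = matrix.vaf.where(calls != "I", 0.0).fillna(0.0).astype(float)
    labels = [str(s) for s in prof.columns]
    vectors = [prof[s].to_numpy(dtype=float) for s in prof.columns]
    if add_control:
        if CONTROL_LABEL in labels:
            raise ValueError(f"a sample is already named {CONTROL_LABEL!r}")
        labels.append(CONTROL_LABEL)
        vectors.append(np.zeros(prof.shape[0]))
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = _pearson_or_zero(vectors[i], vectors[j])
            d[i, j] = d[j, i] = max(0.0, 1.0 - r)  # guard float r slightly > 1
    return DistanceMatrix(d, labels)


def _sort_key(node: Node) -> str:
    return min(node.leaf_names())


def neighbour_joining(dm: DistanceMatrix, control: str | None = None) -> PhyloTree:
    """Saitou–Nei neighbour joining.

    Iteratively joins the pair minimizing the Q criterion
    Q(i,j) = (n-2) d(i,j) - r_i - r_j; branch lengths follow the standard
    formulas with negatives clamped to 0.  Ties on Q are broken by the
    lexicographically smallest pair of cluster labels (a cluster is labelled
    by its smallest leaf), so the result is deterministic.

    The returned tree is unrooted, represented with a trifurcating root; if
    ``control`` (default: a leaf named ``"control"`` if present) exists it is
    recorded and placed as the outgroup on serialization.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 labels")
    if control is None and CONTROL_LABEL in dm.labels:
        control = CONTROL_LABEL
    if control is not None and control not in dm.labels:
        raise ValueError(f"control leaf {control!r} not among labels")

    nodes: list[Node] = [Node(name=l) for l in dm.labels]
    D = dm.data.copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best: tuple[float, str, str, int, int] | None = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                ki = _sort_key(nodes[active[ai]])
                kj = _sort_key(nodes[active[aj]])
                key = (q, *sorted((ki, kj)))
                if best is None or key < (best[0], best[1], best[2]):
                    best = (q, *sorted((ki, kj)), ai, aj)
        assert best is not None
        ai, aj = best[3], best[4]
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li = max(0.0, li)
        lj = max(0.0, lj)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        new = Node(children=sorted([child_i, child_j], key=_sort_key))
        # distances from the new node to the remaining clusters
        new_row = np.zeros(D.shape[0])
        for ak in range(m):
            if ak in (ai, aj):
                continue
            k = active[ak]
            new_row[k] = max(0.0, 0.5 * (D[i, k] + D[j, k] - dij))
        nodes.append(new)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(new_row)] = new_row
        D[: len(new_row), -1] = new_row
        new_idx = D.shape[0] - 1
        active = [k for k in active if k not in (i, j)] + [new_idx]

    # two clusters remain: hang one off the other with the residual distance
    i, j = active
    a, b = nodes[i], nodes[j]
    d_final = D[i, j]
    if not a.is_leaf():
        root, other = a, b
    else:
        root, other = b, a
    other.length = max(0.0, d_final)
    root.children = sorted(root.children + [other], key=_sort_key)
    root.length = 0.0
    return PhyloTree(root=root, control=control)


def _reroot_at_leaf(tree: PhyloTree, leaf_name: str) -> Node:
    """Re-hang the unrooted tree so `leaf_name` is the first child of the root.

    The new root is the internal node the leaf attaches to; all edges keep
    their lengths.
    """
    # undirected adjacency over node objects
    adj: dict[int, list[tuple[Node, float]]] = {}
    by_id: dict[int, Node] = {}

    def collect(node: Node) -> None:
        by_id[id(node)] = node
        for c in node.children:
            adj.setdefault(id(node), []).append((c, c.length))
            adj.setdefault(id(c), []).append((node, c.length))
            collect(c)

    collect(tree.root)
    leaf = next(l for l in tree.root.leaves() if l.name == leaf_name)
    anchor, leaf_len = adj[id(leaf)][0]

    def build(node: Node, parent: Node | None, length: float) -> Node:
        out = Node(name=node.name, length=length)
        for nb, l in adj.get(id(node), []):
            if parent is not None and nb is parent:
                continue
            if nb is node:
                continue
            out.children.append(build(nb, node, l))
        out.children.sort(key=_sort_key)
        return out

    new_root = Node(name=None, length=0.0)
    new_root.children = [build(leaf, anchor, leaf_len)]
    for nb, l in adj[id(anchor)]:
        if nb is leaf:
            continue
        new_root.children.append(build(nb, anchor, l))
    # keep control first, remaining children canonically ordered
    new_root.children = [new_root.children[0]] + sorted(new_root.children[1:], key=_sort_key)
    return new_root


def _format_length(x: float) -> str:
    return format(float(x), ".6g")


def _to_newick(node: Node) -> str:
    if node.is_leaf():
        return f"{node.name}:{_format_length(node.length)}"
    inner = ",".join(_to_newick(c) for c in sorted(node.children, key=_sort_key))
    return f"({inner}):{_format_length(node.length)}"


def write_newick(tree: PhyloTree, path=None) -> str:
    """Serialize to a canonical Newick string (6 significant digits).

    Children are ordered by their smallest leaf label so the output is
    invariant to join order; if the tree has a control leaf it is written as
    the outgroup (first child of the root).
    """
    root = _reroot_at_leaf(tree, tree.control) if tree.control else tree.root
    parts = ",".join(_to_newick(c) for c in (root.children if not root.is_leaf() else [root]))
    text = f"({parts});"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
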