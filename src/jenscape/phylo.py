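"""Distance-based phylogenetics: p-distances, distance corrections,
Neighbor-Joining and BioNJ, bootstrap support, rooting, and tree comparison.

NJ follows Saitou & Nei's agglomeration, minimizing
``Q(i,j) = (r-2) d(i,j) - R_i - R_j`` with branch lengths from the standard
three-point formulas.  BioNJ replaces the plain reduction step with the
variance-weighted reduction (weight chosen to minimize the variance of the
reduced distances, clamped to [0, 1]).  Both are consistent: on an additive
matrix they return the generating topology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Tuple, Union

import numpy as np

from .io_formats import TreeNode


class SaturationError(ValueError):
    """A p-distance too close to 1 for the requested correction."""


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: list
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(self.d < 0):
            raise ValueError("distance matrix entries must be non-negative")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal must be zero")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class GammaConfig:
    """Shape parameter of the gamma law of among-site rate variation."""

    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and np.isfinite(self.alpha)):
            raise ValueError("alpha must be positive and finite")


def _rows(msa) -> list:
    """Accept a MultipleAlignment or a bare list of (id, aligned) rows."""
    return list(getattr(msa, "rows", msa))


_MISSING = {"-", "X"}


def p_distance_matrix(msa) -> DistanceMatrix:
    """Observed proportion of differing residues, pairwise deletion.

    Columns where either row has a gap or an unknown residue ('X') are
    excluded for that pair.  A pair with no comparable column is an error.
    """
    rows = _rows(msa)
    if len(rows) < 2:
        raise ValueError("p_distance_matrix: need at least 2 rows")
    labels = [rid for rid, _ in rows]
    arrs = [np.frombuffer(s.encode(), dtype="S1") for _, s in rows]
    ok = [~np.isin(a, [b"-", b"X"]) for a in arrs]
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                raise SaturationError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            diff = int((arrs[i][both] != arrs[j][both]).sum())
            d[i, j] = d[j, i] = diff / m
    return DistanceMatrix(labels, d)


def correct_distance(p: float, model: str = "poisson",
                     gamma_cfg: Optional[GammaConfig] = None,
                     cap: Optional[float] = None) -> float:
    """Convert an observed p-distance to substitutions/site.

    poisson: ``d = -ln(1 - p)``; gamma: ``d = alpha ((1-p)^(-1/alpha) - 1)``.
    Distances with p > 0.99 are saturated: an error by default, or capped
    at ``cap`` when given.
    """
    if model == "p":
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-distance {p} outside [0, 1]")
        return p
    if not 0.0 <= p < 1.0:
        if p >= 1.0 and cap is not None:
            return cap
        raise SaturationError(f"p-distance {p} is saturated (>= 1)")
    if p > 0.99:
        if cap is not None:
            return cap
        raise SaturationError(f"p-distance {p} exceeds the saturation threshold 0.99")
    if model == "poisson":
        d = -np.log1p(-p)
    elif model == "gamma":
        alpha = (gamma_cfg or GammaConfig()).alpha
        d = alpha * ((1.0 - p) ** (-1.0 / alpha) - 1.0)
    else:
        raise ValueError(f"unknown correction model {model!r}")
    return float(min(d, cap) if cap is not None else d)


def correct_matrix(dm: DistanceMatrix, model: str = "poisson",
                   gamma_cfg: Optional[GammaConfig] = None,
                   cap: Optional[float] = None) -> DistanceMatrix:
    n = len(dm)
    out = np.zeros_like(dm.d)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = correct_distance(dm.d[i, j], model,
                                                     gamma_cfg, cap)
    return DistanceMatrix(list(dm.labels), out)


# ---------------------------------------------------------------------------
# Agglomeration
# ---------------------------------------------------------------------------

def _validate_matrix(D: DistanceMatrix) -> None:
    # DistanceMatrix.__post_init__ already enforces symmetry/non-negativity;
    # re-check here so raw arrays routed around the dataclass fail too.
    if not np.allclose(D.d, D.d.T) or np.any(D.d < 0):
        raise ValueError("distance matrix must be symmetric and non-negative")


def _best_pair(Q: np.ndarray, reps: list) -> Tuple[int, int]:
    """Q-minimizing pair; ties broken by smallest (label_i, label_j)."""
    r = Q.shape[0]
    iu = np.triu_indices(r, k=1)
    vals = Q[iu]
    best = vals.min()
    cand = np.flatnonzero(vals == best)
    pairs = [(iu[0][k], iu[1][k]) for k in cand]
    return min(pairs, key=lambda ij: tuple(sorted((reps[ij[0]], reps[ij[1]]))))


def _three_point_root(nodes, reps, D: np.ndarray) -> TreeNode:
    root = TreeNode()
    (a, b, c) = (0, 1, 2)
    la = (D[a, b] + D[a, c] - D[b, c]) / 2.0
    lb = (D[a, b] + D[b, c] - D[a, c]) / 2.0
    lc = (D[a, c] + D[b, c] - D[a, b]) / 2.0
    for node, ln in zip(nodes, (la, lb, lc)):
        node.length = max(ln, 0.0)
        root.add_child(node)
    return root


def _agglomerate(D0: DistanceMatrix, bionj_mode: bool,
                 V0: Optional[np.ndarray]) -> TreeNode:
    _validate_matrix(D0)
    n = len(D0)
    nodes = [TreeNode(name=lab) for lab in D0.labels]
    if n == 1:
        return nodes[0]
    if n == 2:
        root = TreeNode()
        for node in nodes:
            node.length = D0.d[0, 1] / 2.0
            root.add_child(node)
        return root
    D = D0.d.copy()
    V = (D.copy() if V0 is None else np.asarray(V0, dtype=float).copy())
    reps = list(map(str, D0.labels))

    while len(nodes) > 3:
        r = len(nodes)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = _best_pair(Q, reps)
        dij = D[i, j]
        li = dij / 2.0 + (R[i] - R[j]) / (2.0 * (r - 2))
        lj = dij - li
        # raw lengths feed the BioNJ reduction; clamped lengths go on edges,
        # with the deficit moved to the sibling edge (PHYLIP convention)
        cli, clj = li, lj
        if cli < 0:
            clj += -cli
            cli = 0.0
        if clj < 0:
            cli += -clj
            clj = 0.0
        parent = TreeNode()
        nodes[i].length = cli
        nodes[j].length = clj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])

        keep = [k for k in range(r) if k not in (i, j)]
        if bionj_mode:
            vij = V[i, j]
            if vij > 0:
                lam = 0.5 + (V[j, keep].sum() - V[i, keep].sum()) / (2.0 * (r - 2) * vij)
                lam = float(min(1.0, max(0.0, lam)))
            else:
                lam = 0.5
            new_d = lam * (D[i, keep] - li) + (1 - lam) * (D[j, keep] - lj)
            new_v = lam * V[i, keep] + (1 - lam) * V[j, keep] - lam * (1 - lam) * vij
        else:
            new_d = (D[i, keep] + D[j, keep] - dij) / 2.0
            new_v = None

        D = D[np.ix_(keep, keep)]
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_d
        D[:-1, -1] = new_d
        if bionj_mode:
            V = V[np.ix_(keep, keep)]
            V = np.pad(V, ((0, 1), (0, 1)))
            V[-1, :-1] = np.maximum(new_v, 0.0)
            V[:-1, -1] = np.maximum(new_v, 0.0)
        new_rep = min(reps[i], reps[j])
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [new_rep]

    return _three_point_root(nodes, reps, D)


def neighbor_joining(D: DistanceMatrix) -> TreeNode:
    """Saitou–Nei Neighbor-Joining; returns an unrooted tree
    (trifurcating root node)."""
    return _agglomerate(D, bionj_mode=False, V0=None)


def bionj(D: DistanceMatrix, V: Optional[np.ndarray] = None) -> TreeNode:
    """BioNJ: NJ agglomeration with the variance-weighted reduction step.

    ``V`` is the matrix of distance-estimate variances; by default the
    distances themselves (first-order proportionality).
    """
    return _agglomerate(D, bionj_mode=True, V0=V)


# ---------------------------------------------------------------------------
# Tree comparison, rooting, bootstrap
# ---------------------------------------------------------------------------

def bipartitions(tree: TreeNode, nontrivial_only: bool = True) -> set:
    """Unrooted bipartitions as canonical frozensets of leaf names.

    Each edge splits the leaves in two; the side not containing the
    lexicographically smallest leaf is the canonical representative.
    """
    all_leaves = frozenset(tree.leaf_names())
    anchor = min(all_leaves)
    parts = set()
    for node in tree.preorder():
        if node is tree or node.is_leaf():
            continue
        side = frozenset(node.leaf_names())
        if anchor in side:
            side = all_leaves - side
        if nontrivial_only and not (1 < len(side) < len(all_leaves) - 1):
            continue
        if len(side) >= 1 and len(side) < len(all_leaves):
            parts.add(side)
    return parts


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> int:
    """Symmetric difference of the trees' non-trivial bipartition sets."""
    l1, l2 = set(t1.leaf_names()), set(t2.leaf_names())
    if l1 != l2:
        raise ValueError("robinson_foulds: trees have different leaf sets")
    return len(bipartitions(t1) ^ bipartitions(t2))


def root_with_outgroup(tree: TreeNode, outgroup: Union[str, Iterable[str]]) -> TreeNode:
    """Root on the edge separating the outgroup from the rest, at its midpoint.

    The outgroup must be monophyletic in the unrooted sense; supports are
    carried over on the inverted edges.  The input tree is not modified.
    """
    out = {outgroup} if isinstance(outgroup, str) else set(outgroup)
    t = tree.copy()
    leaves = set(t.leaf_names())
    if not out <= leaves:
        raise ValueError(f"outgroup taxa {sorted(out - leaves)} not in tree")
    if out == leaves:
        raise ValueError("outgroup cannot contain every leaf")
    target = None
    for node in t.preorder():
        if node is t:
            continue
        side = set(node.leaf_names())
        if side == out:
            target = node
            break
        if side == leaves - out:
            target = node
            break
    if target is None:
        raise ValueError("outgroup is not monophyletic (unrooted sense)")

    parent = target.parent
    parent.children.remove(target)
    target.parent = None
    half = None if target.length is None else target.length / 2.0
    edge_support = target.support if not target.is_leaf() else None

    new_root = TreeNode()
    target.length = half
    new_root.add_child(target)

    # invert the path from the attachment point up to the old root
    path = []
    node = parent
    while node is not None:
        path.append(node)
        node = node.parent
    old = [(n.length, n.support) for n in path]
    for idx in range(len(path) - 1):
        path[idx + 1].children.remove(path[idx])
    for n in path:
        n.parent = None
    new_root.add_child(path[0])
    path[0].length = half
    path[0].support = edge_support
    for idx in range(len(path) - 1):
        path[idx].add_child(path[idx + 1])
        path[idx + 1].length, path[idx + 1].support = old[idx]
    # the old root may have become unary: suppress it
    old_root = path[-1]
    if len(old_root.children) == 1 and old_root.parent is not None:
        child = old_root.children[0]
        grand = old_root.parent
        grand.children.remove(old_root)
        if child.length is not None or old_root.length is not None:
            child.length = (child.length or 0.0) + (old_root.length or 0.0)
        if child.support is None:
            child.support = old_root.support
        grand.add_child(child)
    if target.parent is not new_root:  # pragma: no cover - sanity
        raise RuntimeError("rerooting failed")
    return new_root


def unroot(tree: TreeNode) -> TreeNode:
    """Collapse a bifurcating root into the conventional trifurcation."""
    t = tree.copy()
    if len(t.children) != 2:
        return t
    a, b = t.children
    donor, keeper = (a, b) if not a.is_leaf() else (b, a)
    if donor.is_leaf():
        return t
    t.children.remove(donor)
    keeper.length = (keeper.length or 0.0) + (donor.length or 0.0)
    for c in list(donor.children):
        c.parent = None
        t.add_child(c)
    return t


@dataclass
class BootstrapResult:
    main_tree: TreeNode
    n_replicates: int
    n_failed: int = 0
    replicate_trees: Optional[list] = None


def bootstrap_support(msa, builder: str = "nj", n_replicates: int = 100,
                      seed: int = 0, correction: str = "p",
                      gamma_cfg: Optional[GammaConfig] = None,
                      keep_replicates: bool = False) -> BootstrapResult:
    """Column-resampling bootstrap support for a distance tree.

    Columns are resampled with replacement to the original alignment length;
    the builder ('nj' or 'bionj') is applied to each replicate's distance
    matrix, and the support of each internal bipartition of the main tree is
    the percentage of successful replicates containing it.  Replicates whose
    distances are saturated are skipped and counted in ``n_failed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    build = {"nj": neighbor_joining, "bionj": bionj}[builder]
    rows = _rows(msa)
    ids = [rid for rid, _ in rows]
    mat = np.array([list(s) for _, s in rows])
    n_cols = mat.shape[1]

    def tree_from_columns(cols) -> TreeNode:
        sub = mat[:, cols]
        sub_rows = [(rid, "".join(row)) for rid, row in zip(ids, sub)]
        dm = p_distance_matrix(sub_rows)
        dm = correct_matrix(dm, correction, gamma_cfg)
        return build(dm)

    main = tree_from_columns(np.arange(n_cols))
    counts: dict = {bp: 0 for bp in bipartitions(main)}
    rng = np.random.default_rng(seed)
    reps = [] if keep_replicates else None
    failed = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        try:
            rep = tree_from_columns(cols)
        except (SaturationError, ValueError) as exc:
            failed += 1
            warnings.warn(f"bootstrap replicate skipped: {exc}")
            continue
        for bp in bipartitions(rep):
            if bp in counts:
                counts[bp] += 1
        if reps is not None:
            reps.append(rep)
    effective = n_replicates - failed
    all_leaves = frozenset(main.leaf_names())
    anchor = min(all_leaves)
    for node in main.preorder():
        if node is main or node.is_leaf():
            continue
        side = frozenset(node.leaf_names())
        if anchor in side:
            side = all_leaves - side
        if not (1 < len(side) < len(all_leaves) - 1):
            node.support = 100.0  # trivial bipartition, by convention
        elif effective > 0:
            node.support = 100.0 * counts.get(side, 0) / effective
        else:
            node.support = 0.0
    return BootstrapResult(main, n_replicates, failed, reps)
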