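"""Independent oracles used by the test suite.

These deliberately re-derive expected values by routes independent of the
implementation under test: exhaustive enumeration for alignment scores and
reconciliation costs, regular expressions for motif scanning, and direct
path-length computations for tree distances.
"""

from __future__ import annotations

import itertools
import re

import numpy as np

from jenscape.io_formats import TreeNode
from jenscape.motif import ANY, FIXED


def brute_force_align_score(a: str, b: str, scheme, mode: str = "global") -> float:
    """Enumerate every affine-gap alignment; exponential, tiny inputs only."""
    best = [-np.inf]

    def rec(i: int, j: int, score: float, last: str) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + scheme.score(a[i], b[j]), "M")
        if i < len(a):
            pen = scheme.gap_extend if last == "A" else scheme.gap_open
            rec(i + 1, j, score - pen, "A")
        if j < len(b):
            pen = scheme.gap_extend if last == "B" else scheme.gap_open
            rec(i, j + 1, score - pen, "B")

    if mode == "global":
        rec(0, 0, 0.0, "")
        return best[0]
    # local: best over all substring pairs, floored at the empty alignment
    best_local = 0.0
    for i0 in range(len(a) + 1):
        for i1 in range(i0 + 1, len(a) + 1):
            for j0 in range(len(b) + 1):
                for j1 in range(j0 + 1, len(b) + 1):
                    best[0] = -np.inf
                    a_sub, b_sub = a[i0:i1], b[j0:j1]
                    sub = brute_force_align_score(a_sub, b_sub, scheme, "global")
                    best_local = max(best_local, sub)
    return best_local


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def random_binary_tree(labels, rng, min_len: float = 0.05,
                       max_len: float = 1.0) -> TreeNode:
    """Random rooted binary tree with positive branch lengths."""
    nodes = [TreeNode(name=lab) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode()
        for k in (i, j):
            child = nodes[k]
            child.length = float(rng.uniform(min_len, max_len))
            parent.add_child(child)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return nodes[0]


def path_distance_matrix(tree: TreeNode):
    """Leaf-to-leaf path distances computed by explicit root paths."""
    leaves = tree.leaves()
    labels = [l.name for l in leaves]

    def root_path(node):
        path = []
        while node is not None:
            path.append(node)
            node = node.parent
        return path

    n = len(leaves)
    d = np.zeros((n, n))
    for i in range(n):
        anc = {id(x): k for k, x in enumerate(root_path(leaves[i]))}
        for j in range(i + 1, n):
            total = 0.0
            node = leaves[j]
            while id(node) not in anc:
                total += node.length
                node = node.parent
            stop = node
            node = leaves[i]
            while node is not stop:
                total += node.length
                node = node.parent
            d[i, j] = d[j, i] = total
    return labels, d


# ---------------------------------------------------------------------------
# Duplication-loss reconciliation by exhaustive search
# ---------------------------------------------------------------------------

def brute_force_dl(gene_tree: TreeNode, species_tree: TreeNode, leaf_map):
    """Minimum (total events, duplications) over all valid reconciliations.

    Every internal gene node may map to any ancestor-or-equal of the LCA of
    its children's images; a node is a speciation only when its children's
    images lie in distinct child subtrees of its own image, and losses are
    charged per skipped species branch.  Returns
    (min_total, min_duplications).
    """
    s_leaves = {l.name: l for l in species_tree.leaves()}
    depth = {}
    for node in species_tree.preorder():
        depth[id(node)] = 0 if node.parent is None else depth[id(node.parent)] + 1

    def lca(a, b):
        da, db = depth[id(a)], depth[id(b)]
        while da > db:
            a, da = a.parent, da - 1
        while db > da:
            b, db = b.parent, db - 1
        while a is not b:
            a, b = a.parent, b.parent
        return a

    def ancestors_or_self(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    def dist(anc, desc):
        d = 0
        node = desc
        while node is not anc:
            node = node.parent
            d += 1
        return d

    def in_subtree(node, root):
        while node is not None:
            if node is root:
                return True
            node = node.parent
        return False

    gene_internal = [n for n in gene_tree.postorder() if not n.is_leaf()]
    image = {id(l): s_leaves[leaf_map[l.name]] for l in gene_tree.leaves()}

    best = [np.inf, np.inf]

    def assign(idx: int, current):
        if idx == len(gene_internal):
            total = dups = 0
            for v in gene_internal:
                mv = current[id(v)]
                c1, c2 = v.children
                m1, m2 = current[id(c1)], current[id(c2)]
                spec = (mv is lca(m1, m2) and mv is not m1 and mv is not m2
                        and not mv.is_leaf()
                        and in_subtree(m1, mv.children[0]) != in_subtree(m2, mv.children[0]))
                if spec:
                    total += dist(mv, m1) - 1 + dist(mv, m2) - 1
                else:
                    dups += 1
                    total += 1 + dist(mv, m1) + dist(mv, m2)
            best[0] = min(best[0], total)
            best[1] = min(best[1], dups)
            return
        v = gene_internal[idx]
        c1, c2 = v.children
        low = lca(current[id(c1)], current[id(c2)])
        for cand in ancestors_or_self(low):
            current[id(v)] = cand
            assign(idx + 1, current)
        del current[id(v)]

    assign(0, dict(image))
    return int(best[0]), int(best[1])


# ---------------------------------------------------------------------------
# Motif regex oracle
# ---------------------------------------------------------------------------

def motif_regex(pattern) -> re.Pattern:
    parts = []
    for kind, value in pattern.elements:
        if kind == FIXED:
            parts.append(value)
        elif kind == ANY:
            parts.append("[A-Z]")
        else:
            parts.append("[" + "".join(sorted(value)) + "]")
    return re.compile("(?=(" + "".join(parts) + "))")


def regex_match_starts(seq: str, pattern) -> list:
    """1-based start positions of all (overlapping) matches."""
    rx = motif_regex(pattern)
    return [m.start() + 1 for m in rx.finditer(seq)]
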