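"""Progressive multiple alignment and conserved-block filtering.

The aligner is a standard progressive scheme: a Neighbor-Joining guide tree
is built on pairwise global-alignment distances (1 - identity/100), and
profiles are merged bottom-up with profile-profile Needleman-Wunsch whose
column score is the arithmetic mean of substitution scores over all
residue-residue pairs, under the same affine gap penalties as the pairwise
module.  Block filtering keeps maximal runs of columns that satisfy a gap
fraction and a residue conservation threshold, in the spirit of Gblocks'
conserved-block editing (whose exact flank/anchor semantics are a non-goal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .io_formats import SeqRecord
from .pairwise import ScoringScheme, _default_scheme, global_align, identity_similarity
from .phylo import DistanceMatrix, neighbor_joining


@dataclass
class MultipleAlignment:
    """Aligned rows of (sequence id, gapped string)."""

    rows: list  # list[(id, aligned string)]

    def __post_init__(self) -> None:
        if self.rows:
            lengths = {len(s) for _, s in self.rows}
            if len(lengths) != 1:
                raise ValueError("alignment rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def column(self, j: int) -> str:
        return "".join(s[j] for _, s in self.rows)

    def ungapped(self, i: int) -> str:
        return self.rows[i][1].replace("-", "")


@dataclass
class BlockFilterConfig:
    max_gap_fraction: float = 0.5
    min_conserved_fraction: float = 0.5
    min_block_length: int = 3

    def __post_init__(self) -> None:
        if not (0 <= self.max_gap_fraction <= 1 and
                0 <= self.min_conserved_fraction <= 1):
            raise ValueError("fractions must be in [0, 1]")
        if self.min_block_length < 1:
            raise ValueError("min_block_length must be >= 1")


# ---------------------------------------------------------------------------
# Profile-profile Needleman-Wunsch
# ---------------------------------------------------------------------------

_NEG = -1e300


def _column_counts(rows: Sequence[str], alphabet_index: dict) -> Tuple[np.ndarray, np.ndarray]:
    L = len(rows[0])
    counts = np.zeros((L, len(alphabet_index)))
    for s in rows:
        for j, ch in enumerate(s):
            if ch != "-":
                counts[j, alphabet_index[ch]] += 1
    return counts, counts.sum(axis=1)


def _profile_align(rows_a: list, rows_b: list, scheme: ScoringScheme):
    """Merge two profiles; returns the gapped expansions of each profile."""
    alphabet = scheme.matrix.alphabet
    index = {ch: k for k, ch in enumerate(alphabet)}
    S = np.asarray(scheme.matrix, dtype=float)
    ca, na = _column_counts(rows_a, index)
    cb, nb = _column_counts(rows_b, index)
    col_score = (ca @ S @ cb.T) / np.outer(na, nb)
    La, Lb = len(na), len(nb)
    go, ge = scheme.gap_open, scheme.gap_extend

    M = np.full((La + 1, Lb + 1), _NEG)
    X = np.full((La + 1, Lb + 1), _NEG)  # consume a column of A, gap in B
    Y = np.full((La + 1, Lb + 1), _NEG)  # consume a column of B, gap in A
    M[0, 0] = 0.0
    for i in range(1, La + 1):
        X[i, 0] = -(go + (i - 1) * ge)
    for j in range(1, Lb + 1):
        Y[0, j] = -(go + (j - 1) * ge)
    for i in range(1, La + 1):
        prev_best = np.maximum(np.maximum(M[i - 1, :-1], X[i - 1, :-1]), Y[i - 1, :-1])
        M[i, 1:] = prev_best + col_score[i - 1, :]
        X[i, :] = np.maximum(np.maximum(M[i - 1, :] - go, Y[i - 1, :] - go),
                             X[i - 1, :] - ge)
        X[i, 0] = -(go + (i - 1) * ge)
        row_m, row_x, row_y = M[i], X[i], Y[i]
        for j in range(1, Lb + 1):
            row_y[j] = max(row_m[j - 1] - go, row_x[j - 1] - go,
                           row_y[j - 1] - ge)

    # traceback, preferring column-column over gap-in-B over gap-in-A
    i, j = La, Lb
    state = max(("M", "X", "Y"), key=lambda s: {"M": M, "X": X, "Y": Y}[s][i, j])
    ops = []
    while i > 0 or j > 0:
        ops.append(state)
        if state == "M":
            score = M[i, j] - col_score[i - 1, j - 1]
            i, j = i - 1, j - 1
            for cand, mat, pen in (("M", M, 0.0), ("X", X, 0.0), ("Y", Y, 0.0)):
                if np.isclose(mat[i, j], score):
                    state = cand
                    break
        elif state == "X":
            score = X[i, j]
            i -= 1
            if np.isclose(M[i, j] - go, score):
                state = "M"
            elif np.isclose(Y[i, j] - go, score):
                state = "Y"
            else:
                state = "X"
        else:
            score = Y[i, j]
            j -= 1
            if np.isclose(M[i, j] - go, score):
                state = "M"
            elif np.isclose(X[i, j] - go, score):
                state = "X"
            else:
                state = "Y"
    ops.reverse()

    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("M", "X"):
            for k, s in enumerate(rows_a):
                out_a[k] += s[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
        if op in ("M", "Y"):
            for k, s in enumerate(rows_b):
                out_b[k] += s[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += "-"
    return out_a, out_b


def progressive_align(seqs: Sequence[SeqRecord],
                      scheme: Optional[ScoringScheme] = None) -> MultipleAlignment:
    """Progressive multiple alignment guided by an NJ tree on pairwise
    global-alignment identity distances.  Row order equals input order."""
    scheme = scheme or _default_scheme()
    seqs = list(seqs)
    if len(seqs) == 0:
        raise ValueError("progressive_align: no sequences")
    if len(seqs) == 1:
        return MultipleAlignment([(seqs[0].id, seqs[0].residues)])
    if len(seqs) == 2:
        aln = global_align(seqs[0], seqs[1], scheme)
        return MultipleAlignment([(seqs[0].id, aln.aligned_a),
                                  (seqs[1].id, aln.aligned_b)])

    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(seqs[i], seqs[j], scheme)
            ident, _ = identity_similarity(aln, scheme)
            d[i, j] = d[j, i] = 1.0 - ident / 100.0
    labels = [f"{k:06d}" for k in range(n)]
    guide = neighbor_joining(DistanceMatrix(labels, d))

    def merge(node):
        if node.is_leaf():
            k = int(node.name)
            return [k], [seqs[k].residues]
        ids, rows = merge(node.children[0])
        for child in node.children[1:]:
            ids_b, rows_b = merge(child)
            out_a, out_b = _profile_align(rows, rows_b, scheme)
            ids, rows = ids + ids_b, out_a + out_b
        return ids, rows

    ids, rows = merge(guide)
    order = np.argsort(ids)
    return MultipleAlignment([(seqs[ids[k]].id, rows[k]) for k in order])


def filter_blocks(msa: MultipleAlignment,
                  config: Optional[BlockFilterConfig] = None
                  ) -> Tuple[MultipleAlignment, list]:
    """Keep maximal runs (>= min_block_length) of eligible columns.

    A column is eligible iff its gap fraction is <= max_gap_fraction and the
    most frequent residue (gaps excluded) accounts for at least
    min_conserved_fraction of its residues.  ``kept_columns`` maps output
    columns to 1-based input coordinates.
    """
    config = config or BlockFilterConfig()
    n_rows = len(msa.rows)
    eligible = []
    for j in range(msa.n_columns):
        col = msa.column(j)
        gaps = col.count("-")
        residues = [c for c in col if c != "-"]
        gap_frac = gaps / n_rows
        if not residues:
            eligible.append(False)
            continue
        top = max(residues.count(c) for c in set(residues))
        eligible.append(gap_frac <= config.max_gap_fraction and
                        top / len(residues) >= config.min_conserved_fraction)
    kept = []
    run = []
    for j, ok in enumerate(eligible):
        if ok:
            run.append(j)
        else:
            if len(run) >= config.min_block_length:
                kept.extend(run)
            run = []
    if len(run) >= config.min_block_length:
        kept.extend(run)
    rows = [(rid, "".join(s[j] for j in kept)) for rid, s in msa.rows]
    return MultipleAlignment(rows), [j + 1 for j in kept]
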