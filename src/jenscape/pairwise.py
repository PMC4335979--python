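"""Pairwise protein alignment, percent identity/similarity and E-values.

Global (Needleman–Wunsch, end gaps penalized) and local (Smith–Waterman)
alignment under an affine gap model: a gap of length L costs
``gap_open + (L - 1) * gap_extend``.  The dynamic programming engine is
Bio.Align.PairwiseAligner, whose gap convention matches this definition.
Hit significance uses Karlin–Altschul statistics,
``E = K * m * n * exp(-lambda * S)``, with the standard gapped BLOSUM62
parameters as defaults so that an E-value cutoff such as 1e-10 has its
conventional meaning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Tuple, Union

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .io_formats import SeqRecord

SeqLike = Union[SeqRecord, str]

#: Gapped Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1.
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041


def _residues(seq: SeqLike) -> str:
    return seq.residues if isinstance(seq, SeqRecord) else str(seq)


@dataclass
class ScoringScheme:
    """A substitution matrix plus affine gap penalties (positive costs)."""

    matrix: substitution_matrices.Array
    gap_open: float
    gap_extend: float
    name: str = "custom"

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend > 0):
            raise ValueError("require gap_open >= gap_extend > 0")
        arr = np.asarray(self.matrix)
        if not np.allclose(arr, arr.T):
            raise ValueError("substitution matrix must be symmetric")

    def score(self, a: str, b: str) -> float:
        return float(self.matrix[a, b])

    @classmethod
    def blosum62(cls, gap_open: float = 11.0, gap_extend: float = 1.0) -> "ScoringScheme":
        """BLASTp default scoring: BLOSUM62, gap open 11, extend 1."""
        return cls(substitution_matrices.load("BLOSUM62"), gap_open, gap_extend,
                   name="BLOSUM62")

    @classmethod
    def from_ncbi_file(cls, path, gap_open: float = 11.0,
                       gap_extend: float = 1.0) -> "ScoringScheme":
        """Read an NCBI-format substitution matrix text file."""
        with open(path) as fh:
            matrix = substitution_matrices.read(fh)
        return cls(matrix, gap_open, gap_extend, name=str(path))


@lru_cache(maxsize=8)
def _default_scheme() -> ScoringScheme:
    return ScoringScheme.blosum62()


@dataclass
class PairwiseAlignment:
    """A scored pairwise alignment; spans are 1-based inclusive."""

    aligned_a: str
    aligned_b: str
    raw_score: float
    mode: str  # "global" | "local"
    a_span: Optional[Tuple[int, int]] = None
    b_span: Optional[Tuple[int, int]] = None

    def __len__(self) -> int:
        return len(self.aligned_a)


def _make_aligner(scheme: ScoringScheme, mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = scheme.matrix
    aligner.open_gap_score = -scheme.gap_open
    aligner.extend_gap_score = -scheme.gap_extend
    aligner.mode = mode
    return aligner


def _gapped_strings(alignment, a: str, b: str, mode: str):
    """Build gapped row strings from a biopython alignment's aligned blocks."""
    blocks_a, blocks_b = alignment.aligned
    rows_a, rows_b = [], []
    if mode == "global":
        prev_a, prev_b = 0, 0
        end_a, end_b = len(a), len(b)
    else:
        prev_a, prev_b = int(blocks_a[0][0]), int(blocks_b[0][0])
        end_a, end_b = int(blocks_a[-1][1]), int(blocks_b[-1][1])
    for (sa, ea), (sb, eb) in zip(blocks_a.tolist(), blocks_b.tolist()):
        if sa > prev_a:  # residues of a against gaps in b
            rows_a.append(a[prev_a:sa])
            rows_b.append("-" * (sa - prev_a))
        if sb > prev_b:
            rows_a.append("-" * (sb - prev_b))
            rows_b.append(b[prev_b:sb])
        rows_a.append(a[sa:ea])
        rows_b.append(b[sb:eb])
        prev_a, prev_b = ea, eb
    if mode == "global":
        if end_a > prev_a:
            rows_a.append(a[prev_a:end_a])
            rows_b.append("-" * (end_a - prev_a))
        if end_b > prev_b:
            rows_a.append("-" * (end_b - prev_b))
            rows_b.append(b[prev_b:end_b])
    span_a = (int(blocks_a[0][0]) + 1, int(blocks_a[-1][1]))
    span_b = (int(blocks_b[0][0]) + 1, int(blocks_b[-1][1]))
    return "".join(rows_a), "".join(rows_b), span_a, span_b


def global_align(a: SeqLike, b: SeqLike,
                 scheme: Optional[ScoringScheme] = None) -> PairwiseAlignment:
    """Maximum-score global alignment with affine gaps; end gaps penalized."""
    scheme = scheme or _default_scheme()
    sa, sb = _residues(a), _residues(b)
    if not sa or not sb:
        raise ValueError("global_align: empty sequence")
    aligner = _make_aligner(scheme, "global")
    aln = aligner.align(sa, sb)[0]
    rows_a, rows_b, _, _ = _gapped_strings(aln, sa, sb, "global")
    return PairwiseAlignment(rows_a, rows_b, float(aln.score), "global",
                             (1, len(sa)), (1, len(sb)))


def local_align(a: SeqLike, b: SeqLike,
                scheme: Optional[ScoringScheme] = None) -> PairwiseAlignment:
    """Maximum-score local alignment; the empty alignment (score 0) is
    returned when no positive-scoring residue pairing exists."""
    scheme = scheme or _default_scheme()
    sa, sb = _residues(a), _residues(b)
    if not sa or not sb:
        raise ValueError("local_align: empty sequence")
    aligner = _make_aligner(scheme, "local")
    score = aligner.score(sa, sb)
    if score <= 0:
        return PairwiseAlignment("", "", 0.0, "local", None, None)
    aln = aligner.align(sa, sb)[0]
    rows_a, rows_b, span_a, span_b = _gapped_strings(aln, sa, sb, "local")
    return PairwiseAlignment(rows_a, rows_b, float(aln.score), "local",
                             span_a, span_b)


def align_score(a: SeqLike, b: SeqLike, scheme: Optional[ScoringScheme] = None,
                mode: str = "local") -> float:
    """Alignment score without traceback (fast path for database scans)."""
    scheme = scheme or _default_scheme()
    sa, sb = _residues(a), _residues(b)
    if not sa or not sb:
        raise ValueError("align_score: empty sequence")
    score = float(_make_aligner(scheme, mode).score(sa, sb))
    if mode == "local":
        score = max(score, 0.0)
    return score


def identity_similarity(aln: PairwiseAlignment,
                        scheme: Optional[ScoringScheme] = None) -> Tuple[float, float]:
    """Percent identity and percent similarity over the full alignment length.

    Identity counts identical residue columns; similarity counts columns
    whose substitution score is positive (EMBOSS convention).  Gap columns
    count in the denominator of both.
    """
    scheme = scheme or _default_scheme()
    n = len(aln)
    if n == 0:
        raise ValueError("identity_similarity: zero-length alignment")
    ident = simil = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x == "-" or y == "-":
            continue
        if x == y:
            ident += 1
        if scheme.score(x, y) > 0:
            simil += 1
    return 100.0 * ident / n, 100.0 * simil / n


@dataclass
class KarlinAltschulParams:
    """Parameters of the extreme-value law for local alignment scores."""

    lambda_: float = DEFAULT_LAMBDA
    K: float = DEFAULT_K
    m: int = 1
    n: int = 1

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or self.K <= 0:
            raise ValueError("lambda_ and K must be positive")
        if self.m < 1 or self.n < 1:
            raise ValueError("m and n must be >= 1")


def evalue(raw_score: float, params: KarlinAltschulParams) -> float:
    """Expected number of chance hits: ``K * m * n * exp(-lambda * S)``."""
    return params.K * params.m * params.n * math.exp(-params.lambda_ * raw_score)
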