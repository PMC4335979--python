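"""Degenerate protein-motif scanning and near-miss diagnosis.

Patterns are ordered lists of elements: a fixed residue (``N``), the
any-residue wildcard (``X``), or a residue class (``(S/T)`` or ``[ST]``),
optionally separated by dashes.  The canonical use case is the
mono/dicarboxylate-transporter signature of the seventh transmembrane
helix, ``NXX(S/T)HX(S/T)QDXXXT``, whose fixed positions correspond to
functionally critical residues (N379, H383, Q386, D387, T391 in the
S. cerevisiae lactate transporter numbering).

An unknown residue 'X' in a *sequence* satisfies wildcards but fails fixed
and class elements: unknowns never certify a motif.  All coordinates are
1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

from .io_formats import AMINO_ACIDS, SeqRecord

FIXED = "fixed"
ANY = "any"
CLASS = "class"


@dataclass
class MotifPattern:
    elements: list  # [(FIXED, 'N') | (ANY, None) | (CLASS, frozenset)]
    source_text: str

    def __len__(self) -> int:
        return len(self.elements)

    def element_repr(self, k: int) -> str:
        """Human-readable form of element k (0-based)."""
        kind, value = self.elements[k]
        if kind == FIXED:
            return value
        if kind == ANY:
            return "X"
        return "(" + "/".join(sorted(value)) + ")"


@dataclass
class MotifMatch:
    seq_id: str
    start: int  # 1-based inclusive
    end: int
    matched: str
    anchor_positions: Dict[int, int] = field(default_factory=dict)
    # element index (1-based) -> absolute residue coordinate, for fixed
    # and class elements only


def parse_pattern(text: str) -> MotifPattern:
    """Parse a degenerate pattern string into its element list."""
    elements = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "-" or ch.isspace():
            i += 1
            continue
        if ch in ("X", "x"):
            elements.append((ANY, None))
            i += 1
        elif ch.upper() in AMINO_ACIDS:
            elements.append((FIXED, ch.upper()))
            i += 1
        elif ch == "(":
            j = text.find(")", i)
            if j == -1:
                raise ValueError(f"pattern parse error at position {i + 1}: "
                                 "unclosed '('")
            members = [m.strip().upper() for m in text[i + 1:j].split("/")]
            if not members or any(m not in AMINO_ACIDS for m in members) or \
                    any(len(m) != 1 for m in members):
                raise ValueError(
                    f"pattern parse error at position {i + 1}: invalid "
                    f"residue class {text[i:j + 1]!r}")
            elements.append((CLASS, frozenset(members)))
            i = j + 1
        elif ch == "[":
            j = text.find("]", i)
            if j == -1:
                raise ValueError(f"pattern parse error at position {i + 1}: "
                                 "unclosed '['")
            members = [m.upper() for m in text[i + 1:j]]
            if not members or any(m not in AMINO_ACIDS for m in members):
                raise ValueError(
                    f"pattern parse error at position {i + 1}: invalid "
                    f"residue class {text[i:j + 1]!r}")
            elements.append((CLASS, frozenset(members)))
            i = j + 1
        else:
            raise ValueError(
                f"pattern parse error at position {i + 1}: unknown token {ch!r}")
    if not elements:
        raise ValueError("pattern parse error: empty pattern")
    return MotifPattern(elements, text)


def _element_ok(kind: str, value, residue: str) -> bool:
    if kind == ANY:
        return True
    if residue == "X":
        return False  # unknown residues never certify fixed/class elements
    if kind == FIXED:
        return residue == value
    return residue in value


def scan(seq: SeqRecord, pattern: MotifPattern) -> List[MotifMatch]:
    """All (possibly overlapping) windows satisfying every element."""
    s = seq.residues if isinstance(seq, SeqRecord) else str(seq)
    sid = seq.id if isinstance(seq, SeqRecord) else ""
    k = len(pattern)
    matches = []
    for start in range(len(s) - k + 1):
        window = s[start:start + k]
        anchors = {}
        for off, (kind, value) in enumerate(pattern.elements):
            if not _element_ok(kind, value, window[off]):
                break
            if kind != ANY:
                anchors[off + 1] = start + off + 1
        else:
            matches.append(MotifMatch(sid, start + 1, start + k, window, anchors))
    return matches


def diagnose(seq: SeqRecord, pattern: MotifPattern,
             max_mismatches: int = 1) -> List[Tuple[int, List[Tuple[int, str, str]]]]:
    """Near-miss windows with 1..max_mismatches violated elements.

    Returns ``(window start, [(element index, expected, observed), ...])``
    per window, 1-based; exact matches are excluded.
    """
    if max_mismatches < 1:
        raise ValueError("max_mismatches must be >= 1")
    s = seq.residues if isinstance(seq, SeqRecord) else str(seq)
    k = len(pattern)
    out = []
    for start in range(len(s) - k + 1):
        window = s[start:start + k]
        mismatches = []
        for off, (kind, value) in enumerate(pattern.elements):
            if not _element_ok(kind, value, window[off]):
                mismatches.append((off + 1, pattern.element_repr(off), window[off]))
                if len(mismatches) > max_mismatches:
                    break
        if 1 <= len(mismatches) <= max_mismatches:
            out.append((start + 1, mismatches))
    return out
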