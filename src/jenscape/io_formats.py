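"""Core containers and file formats: protein records, trees, FASTA and Newick.

The :class:`TreeNode` class is the tree container used throughout the
package (species trees, gene trees, guide trees).  All user-facing sequence
coordinates are 1-based inclusive, matching conventional residue numbering
such as N379; internal Python indices are 0-based.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: The 20 canonical amino acids.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Residue alphabet accepted in proteome input: canonical residues plus 'X'
#: for an unknown residue.  '*' and gap characters are rejected.
ALPHABET = frozenset(AMINO_ACIDS + "X")


class ParseError(ValueError):
    """Raised when a FASTA or Newick document is malformed."""


@dataclass
class SeqRecord:
    """An amino-acid sequence belonging to a species proteome."""

    id: str
    residues: str
    description: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ParseError(
                f"record {self.id!r}: illegal residue character(s) "
                f"{sorted(bad)!r}; allowed alphabet is the 20 amino acids plus 'X'"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path, species: str = "") -> list[SeqRecord]:
    """Read a FASTA proteome, attaching ``species`` to every record.

    Residues are uppercased and validated against the 20+X alphabet.
    A sequence line before the first header is a parse error.
    """
    with open(path) as fh:
        text = fh.read()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        for lineno, line in enumerate(text.splitlines(), start=1):
            if line.strip():
                raise ParseError(
                    f"{path}: sequence before first '>' header at line {lineno}"
                )
    records = []
    seen = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SeqRecord(id=rec.id, residues=str(rec.seq), description=desc,
                      species=species)
        )
    return records


def write_fasta(records: list[SeqRecord], path, width: int = 60) -> None:
    """Write records as wrapped multi-FASTA.  Duplicate ids are an error."""
    if not records:
        raise ValueError("write_fasta: no records to write")
    if width < 1:
        raise ValueError("write_fasta: width must be positive")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("write_fasta: duplicate record ids")
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

_NEWICK_FORBIDDEN = set("(),:;[]")


@dataclass
class TreeNode:
    """A node of a rooted or unrooted-representation tree.

    ``support`` values live in [0, 100] (bootstrap percentages).  An
    "unrooted" tree is represented with a trifurcating root, as is
    conventional for Newick.
    """

    name: Optional[str] = None
    length: Optional[float] = None
    support: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: Optional["TreeNode"] = field(default=None, repr=False, compare=False)

    # -- construction -------------------------------------------------
    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    # -- traversal ----------------------------------------------------
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["TreeNode"]:
        out = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.preorder() if n.is_leaf()]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def find(self, name: str) -> Optional["TreeNode"]:
        for n in self.preorder():
            if n.name == name:
                return n
        return None

    def copy(self) -> "TreeNode":
        node = TreeNode(name=self.name, length=self.length, support=self.support)
        for c in self.children:
            node.add_child(c.copy())
        return node

    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self.preorder() if n is not self)

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.preorder())

    # -- serialization ------------------------------------------------
    def newick(self) -> str:
        return write_newick(self)

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return self.newick()


Tree = TreeNode  # domain alias


def read_newick(text: str) -> TreeNode:
    """Parse a Newick string into a :class:`TreeNode`.

    Branch lengths follow ':'.  An internal label that parses as a number
    in [0, 100] is interpreted as bootstrap support; other internal labels
    are node names.  Quoted labels are not supported.
    """
    text = text.strip()
    if not text:
        raise ParseError("empty Newick string")
    if not text.endswith(";"):
        raise ParseError(
            f"Newick string missing terminating ';' (position {len(text)})"
        )
    body = text[:-1]
    pos = 0

    def error(msg: str) -> ParseError:
        return ParseError(f"Newick parse error at position {pos}: {msg}")

    def parse_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(body) and body[pos] not in _NEWICK_FORBIDDEN:
            pos += 1
        return body[start:pos].strip()

    def parse_length() -> Optional[float]:
        nonlocal pos
        if pos < len(body) and body[pos] == ":":
            pos += 1
            start = pos
            while pos < len(body) and body[pos] not in _NEWICK_FORBIDDEN:
                pos += 1
            try:
                value = float(body[start:pos])
            except ValueError:
                raise error(f"invalid branch length {body[start:pos]!r}") from None
            if value < 0:
                raise error("negative branch length")
            return value
        return None

    def parse_subtree() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(body) and body[pos] == "(":
            pos += 1
            while True:
                node.add_child(parse_subtree())
                if pos >= len(body):
                    raise error("unbalanced parentheses: unexpected end of input")
                if body[pos] == ",":
                    pos += 1
                    continue
                if body[pos] == ")":
                    pos += 1
                    break
                raise error(f"unexpected character {body[pos]!r}")
            label = parse_label()
            if label:
                try:
                    value = float(label)
                except ValueError:
                    node.name = label
                else:
                    if 0.0 <= value <= 100.0:
                        node.support = value
                    else:
                        node.name = label
        else:
            label = parse_label()
            if not label:
                raise error("expected a leaf label")
            node.name = label
        node.length = parse_length()
        return node

    root = parse_subtree()
    if pos != len(body):
        raise ParseError(
            f"Newick parse error at position {pos}: trailing characters "
            f"{body[pos:]!r} (unbalanced parentheses?)"
        )
    return root


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree; inverse of :func:`read_newick` up to child order."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf():
            if node.name is None:
                raise ValueError("leaf without a name cannot be serialized")
            if set(node.name) & _NEWICK_FORBIDDEN or any(c.isspace() for c in node.name):
                raise ValueError(
                    f"leaf name {node.name!r} contains characters reserved "
                    "by the Newick format"
                )
            label = node.name
        else:
            inner = ",".join(fmt(c) for c in node.children)
            if node.support is not None:
                label = f"({inner}){node.support:g}"
            elif node.name:
                label = f"({inner}){node.name}"
            else:
                label = f"({inner})"
        if node.length is not None:
            label += f":{node.length:g}"
        return label

    return fmt(tree) + ";"
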