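"""Reading and writing of the external formats the pipeline touches.

Sequences travel as FASTA (DNA or RNA alphabet), structural alignments as
Stockholm with a consensus-structure line, and predictions leave as a TSV
hit table, plain FASTA, or FASTA with a dot-bracket structure line.

The internal canonical alphabet is DNA: ``U`` is folded into ``T`` on input
and pairing logic downstream treats ``T`` as ``U``.  Coordinates are 0-based
half-open internally; every emitted coordinate is 1-based inclusive with an
explicit strand column.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

from Bio import AlignIO, SeqIO

__all__ = [
    "FormatError",
    "SequenceRecord",
    "StructuredAlignment",
    "IUPAC_CODES",
    "normalize_residues",
    "read_fasta",
    "write_fasta",
    "read_stockholm",
    "write_calls",
    "HIT_TSV_COLUMNS",
]


class FormatError(ValueError):
    """A file does not conform to the expected external format."""


#: IUPAC nucleotide one-letter codes mapped to the set of canonical (DNA)
#: bases they expand to.  ``N`` expands to all four.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_VALID_RESIDUES = frozenset(IUPAC_CODES)


def normalize_residues(raw: str, *, context: str = "sequence") -> str:
    """Uppercase, fold U onto T, and validate against the IUPAC alphabet.

    Raises :class:`FormatError` naming the 1-based position of the first
    offending symbol.  Idempotent.
    """
    out = raw.upper().replace("U", "T")
    for i, ch in enumerate(out):
        if ch not in _VALID_RESIDUES:
            raise FormatError(
                f"{context}: non-IUPAC symbol {ch!r} at position {i + 1}"
            )
    return out


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide sequence over the canonical DNA alphabet."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class StructuredAlignment:
    """A gapped alignment plus one consensus-structure line.

    The structure string uses ``<``/``>`` for the nested helix tier,
    uppercase/lowercase letter pairs (``Aa``, ``Bb``, ...) for pseudoknot
    tiers, and ``.`` for unpaired columns.  All rows and the structure have
    identical length.
    """

    rows: list[tuple[str, str]]
    consensus_structure: str

    def __post_init__(self) -> None:
        cols = self.columns
        for rid, seq in self.rows:
            if len(seq) != cols:
                raise FormatError(
                    f"alignment row {rid!r} has length {len(seq)}, expected {cols}"
                )
        if len(self.consensus_structure) != cols:
            raise FormatError(
                "consensus structure length "
                f"{len(self.consensus_structure)} != alignment columns {cols}"
            )
        _check_balanced(self.consensus_structure)

    @property
    def columns(self) -> int:
        if self.rows:
            return len(self.rows[0][1])
        return len(self.consensus_structure)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def column(self, j: int) -> list[str]:
        return [seq[j] for _, seq in self.rows]


# -- structure-string handling ------------------------------------------------

_WUSS_OPEN = "<([{"
_WUSS_CLOSE = ">)]}"
_WUSS_UNPAIRED = ":_-,.~"


def normalize_structure(wuss: str) -> str:
    """Map a WUSS-style consensus structure onto the internal alphabet.

    All nested-bracket flavours collapse onto ``<``/``>`` (they annotate one
    tier); letter pairs are kept as pseudoknot tiers; every unpaired symbol
    becomes ``.``.
    """
    out = []
    for ch in wuss:
        if ch in _WUSS_OPEN:
            out.append("<")
        elif ch in _WUSS_CLOSE:
            out.append(">")
        elif ch in _WUSS_UNPAIRED:
            out.append(".")
        elif ch.isalpha():
            out.append(ch)
        else:
            raise FormatError(f"unrecognized structure symbol {ch!r}")
    return "".join(out)


def _check_balanced(structure: str) -> None:
    tiers: dict[str, int] = {}
    depth = 0
    for ch in structure:
        if ch == "<":
            depth += 1
        elif ch == ">":
            depth -= 1
            if depth < 0:
                raise FormatError("unbalanced brackets in nested tier")
        elif ch.isalpha():
            key = ch.upper()
            tiers[key] = tiers.get(key, 0) + (1 if ch.isupper() else -1)
            if tiers[key] < 0:
                raise FormatError(f"unbalanced brackets in pseudoknot tier {key}")
    if depth != 0:
        raise FormatError("unbalanced brackets in nested tier")
    for key, d in tiers.items():
        if d != 0:
            raise FormatError(f"unbalanced brackets in pseudoknot tier {key}")


def structure_pairs(structure: str) -> list[tuple[int, int]]:
    """All (i, j) column pairs of a normalized structure, every tier."""
    pairs: list[tuple[int, int]] = []
    stack: list[int] = []
    tier_stacks: dict[str, list[int]] = {}
    for i, ch in enumerate(structure):
        if ch == "<":
            stack.append(i)
        elif ch == ">":
            pairs.append((stack.pop(), i))
        elif ch.isalpha():
            if ch.isupper():
                tier_stacks.setdefault(ch, []).append(i)
            else:
                pairs.append((tier_stacks[ch.upper()].pop(), i))
    return sorted(pairs)


def nested_pairs(structure: str) -> list[tuple[int, int]]:
    """Pairs of the nested ``<``/``>`` tier only (pseudoknot tiers dropped)."""
    pairs: list[tuple[int, int]] = []
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "<":
            stack.append(i)
        elif ch == ">":
            pairs.append((stack.pop(), i))
    return sorted(pairs)


# -- FASTA --------------------------------------------------------------------

def read_fasta(path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into normalized records.

    Order is preserved.  Duplicate ids are made unique with a numeric
    suffix and reported as a warning; an empty file is a format error.
    """
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            seen[rid] += 1
            new_id = f"{rid}.{seen[rid]}"
            warnings.warn(f"duplicate FASTA id {rid!r}; renamed to {new_id!r}")
            rid = new_id
        else:
            seen[rid] = 1
        residues = normalize_residues(str(rec.seq), context=f"record {rid!r}")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rid, residues=residues, description=desc))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], handle_or_path, width: int = 70) -> None:
    own = isinstance(handle_or_path, (str, bytes)) or hasattr(handle_or_path, "__fspath__")
    fh: TextIO = open(handle_or_path, "w") if own else handle_or_path
    try:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")
    finally:
        if own:
            fh.close()


# -- Stockholm ----------------------------------------------------------------

def read_stockholm(path) -> StructuredAlignment:
    """Read one Stockholm alignment carrying a consensus-structure line.

    The ``#=GC SS_cons`` annotation is mandatory; its WUSS symbols are
    normalized onto the internal bracket alphabet.
    """
    try:
        aln = AlignIO.read(str(path), "stockholm")
    except ValueError as exc:
        raise FormatError(f"could not parse Stockholm file {path}: {exc}") from exc
    ss = aln.column_annotations.get("secondary_structure")
    if not ss:
        raise FormatError(f"{path}: missing #=GC SS_cons consensus-structure line")
    rows = []
    for rec in aln:
        gapped = str(rec.seq).upper().replace("U", "T").replace(".", "-")
        rows.append((rec.id, gapped))
    return StructuredAlignment(rows=rows, consensus_structure=normalize_structure(ss))


def write_stockholm(aln: StructuredAlignment, handle_or_path) -> None:
    own = isinstance(handle_or_path, (str, bytes)) or hasattr(handle_or_path, "__fspath__")
    fh: TextIO = open(handle_or_path, "w") if own else handle_or_path
    try:
        fh.write("# STOCKHOLM 1.0\n")
        name_w = max((len(rid) for rid, _ in aln.rows), default=10)
        name_w = max(name_w, len("#=GC SS_cons"))
        for rid, seq in aln.rows:
            fh.write(f"{rid:<{name_w}} {seq}\n")
        fh.write(f"{'#=GC SS_cons':<{name_w}} {aln.consensus_structure}\n")
        fh.write("//\n")
    finally:
        if own:
            fh.close()


# -- hit tables / annotated output --------------------------------------------

HIT_TSV_COLUMNS = (
    "seq_id",
    "strand",
    "start_1based",
    "end_1based",
    "subfamily",
    "dm_variant",
    "local_score_bits",
    "global_score_bits",
    "evalue",
    "length",
)


def write_calls(calls: Sequence, style: str = "tsv") -> str:
    """Render gene calls as ``tsv``, ``fasta`` or ``fasta+structure`` text.

    TSV columns are fixed (see :data:`HIT_TSV_COLUMNS`); coordinates are
    1-based inclusive.  ``fasta+structure`` adds a dot-bracket line whose
    length must equal the sequence line.
    """
    buf = io.StringIO()
    if style == "tsv":
        buf.write("\t".join(HIT_TSV_COLUMNS) + "\n")
        for c in calls:
            buf.write(
                "\t".join(
                    [
                        c.seq_id,
                        c.strand,
                        str(c.start + 1),
                        str(c.end),
                        c.subfamily,
                        c.dm_variant,
                        f"{c.local_score:.2f}",
                        f"{c.global_score:.2f}",
                        f"{c.evalue:.3e}",
                        str(c.end - c.start),
                    ]
                )
                + "\n"
            )
    elif style in ("fasta", "fasta+structure"):
        for c in calls:
            header = (
                f"{c.seq_id}/{c.start + 1}-{c.end}({c.strand}) "
                f"subfamily={c.subfamily} evalue={c.evalue:.3e}"
            )
            buf.write(f">{header}\n{c.sequence}\n")
            if style == "fasta+structure":
                if len(c.structure) != len(c.sequence):
                    raise ValueError(
                        f"call {c.seq_id}:{c.start}-{c.end}: structure length "
                        f"{len(c.structure)} != sequence length {len(c.sequence)}"
                    )
                buf.write(c.structure + "\n")
    else:
        raise ValueError(f"unknown output style {style!r}")
    return buf.getvalue()
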