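"""Descriptor-model construction from annotated structural alignments.

Each alignment column is summarized into a single IUPAC symbol covering
*every* base observed in it, or into the gap character as soon as the
column contains at least one gap.  Well-conserved regions — chosen by the
curator, not inferred — are then turned into descriptor elements: fixed
single-strand patterns, helices (5'/3' column-range pairs), and run tokens
for the variable stretches in between, whose bounds are the observed
ungapped stretch lengths across the training rows.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .descriptor_engine import (
    DescriptorModel,
    HelixElement,
    RunToken,
    SSElement,
)
from .io_formats import IUPAC_CODES, FormatError, StructuredAlignment

__all__ = [
    "GAP",
    "ConsensusAnnotation",
    "Region",
    "column_consensus",
    "alignment_consensus",
    "column_entropy",
    "build_descriptor",
    "read_region_table",
]

GAP = "-"

# inverse IUPAC map: set of observed bases -> degenerate symbol
_SET_TO_CODE = {bases: code for code, bases in IUPAC_CODES.items()}


def column_consensus(column: Iterable[str]) -> str:
    """Summarize one alignment column into an IUPAC symbol or the gap char.

    The gap character wins whenever the column contains at least one gap;
    otherwise the result is the unique IUPAC code whose expansion equals
    the set of bases observed in the column.
    """
    observed: set[str] = set()
    n = 0
    for ch in column:
        n += 1
        if ch in (GAP, "."):
            return GAP
        if ch not in IUPAC_CODES:
            raise ValueError(f"invalid residue {ch!r} in column")
        observed |= IUPAC_CODES[ch]
    if n == 0:
        raise ValueError("empty column")
    return _SET_TO_CODE[frozenset(observed)]


@dataclass
class ConsensusAnnotation:
    """Column-wise consensus of a structural alignment."""

    consensus_sequence: str
    alignment: StructuredAlignment
    column_counts: list[Counter]

    def __post_init__(self) -> None:
        if len(self.consensus_sequence) != self.alignment.columns:
            raise ValueError("consensus length != alignment columns")


def alignment_consensus(aln: StructuredAlignment) -> ConsensusAnnotation:
    """Apply :func:`column_consensus` to every column of the alignment."""
    symbols = []
    counts = []
    for j in range(aln.columns):
        col = aln.column(j)
        symbols.append(column_consensus(col))
        counts.append(Counter(col))
    return ConsensusAnnotation("".join(symbols), aln, counts)


def column_entropy(annotation: ConsensusAnnotation) -> list[float]:
    """Per-column Shannon entropy (bits) over observed residues, gaps included.

    A reporting aid for choosing descriptor regions; it carries no authority
    over region selection, which stays a curator input.
    """
    out = []
    for cnt in annotation.column_counts:
        total = sum(cnt.values())
        h = 0.0
        for v in cnt.values():
            p = v / total
            h -= p * math.log2(p)
        out.append(h)
    return out


@dataclass(frozen=True)
class Region:
    """One selected region: 0-based half-open column range.

    ``kind`` is ``ss`` for single-strand regions or ``helix5``/``helix3``
    for the two strands of a helix (paired by sharing ``label``).  For
    ``ss`` the budget is the mismatch budget; for helices the ``helix5``
    row's budget is the mispair budget.
    """

    label: str
    kind: str
    col_start: int
    col_end: int
    budget: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("ss", "helix5", "helix3"):
            raise ValueError(f"unknown region kind {self.kind!r}")
        if not (0 <= self.col_start < self.col_end):
            raise ValueError(f"bad column range in region {self.label!r}")


def read_region_table(path) -> list[Region]:
    """Read the TSV region table (element_label, kind, col_start, col_end, budget)."""
    regions = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "element_label":  # header
                continue
            if len(parts) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            regions.append(
                Region(parts[0], parts[1], int(parts[2]), int(parts[3]), int(parts[4]))
            )
    return regions


def _stretch_bounds(
    aln: StructuredAlignment, col_start: int, col_end: int, slack: int
) -> RunToken:
    """Observed ungapped lengths of rows across a column stretch, +- slack."""
    lengths = [
        sum(1 for ch in seq[col_start:col_end] if ch not in (GAP, "."))
        for _, seq in aln.rows
    ]
    lo = max(0, min(lengths) - slack)
    hi = max(lengths) + slack
    return RunToken(lo, hi)


def _ss_tokens(
    annotation: ConsensusAnnotation, region: Region, slack: int
) -> tuple:
    """Fixed consensus symbols; gap-consensus blocks become run tokens."""
    cons = annotation.consensus_sequence
    aln = annotation.alignment
    tokens = []
    j = region.col_start
    while j < region.col_end:
        if cons[j] == GAP:
            k = j
            while k < region.col_end and cons[k] == GAP:
                k += 1
            run = _stretch_bounds(aln, j, k, slack)
            if run.max > 0:
                tokens.append(run)
            j = k
        else:
            tokens.append(cons[j])
            j += 1
    return tuple(tokens)


def build_descriptor(
    annotation: ConsensusAnnotation,
    regions: Sequence[Region],
    name: str,
    subfamily: str,
    variant: str = "general",
    run_slack: int = 0,
) -> DescriptorModel:
    """Emit a descriptor model from a consensus annotation and a region table.

    Regions must be non-overlapping; helix regions come as ``helix5``/
    ``helix3`` pairs of equal width sharing a label and must contain no
    gap-consensus columns.  The stretches between consecutive regions become
    auto-labelled single-strand elements holding one run token whose bounds
    are the min/max observed ungapped stretch lengths, widened by
    ``run_slack``.
    """
    aln = annotation.alignment
    cons = annotation.consensus_sequence
    ordered = sorted(regions, key=lambda r: r.col_start)
    for a, b in zip(ordered, ordered[1:]):
        if a.col_end > b.col_start:
            raise ValueError(f"regions {a.label!r} and {b.label!r} overlap")

    helix5: dict[str, Region] = {}
    helix3: dict[str, Region] = {}
    for r in ordered:
        if r.kind == "helix5":
            helix5[r.label] = r
        elif r.kind == "helix3":
            helix3[r.label] = r
    if set(helix5) != set(helix3):
        missing = set(helix5) ^ set(helix3)
        raise ValueError(f"unpaired helix region label(s): {sorted(missing)}")
    for lab in helix5:
        w5 = helix5[lab].col_end - helix5[lab].col_start
        w3 = helix3[lab].col_end - helix3[lab].col_start
        if w5 != w3:
            raise ValueError(f"helix {lab!r}: 5'/3' widths differ ({w5} vs {w3})")

    used_s = [int(r.label[1:]) for r in ordered if r.label.startswith("s")]
    next_s = max(used_s, default=0) + 1

    elements: dict = {}
    topology: list[str] = []

    def add_spacer(col_a: int, col_b: int) -> None:
        nonlocal next_s
        if col_b <= col_a:
            return
        run = _stretch_bounds(aln, col_a, col_b, run_slack)
        if run.max == 0:
            return
        label = f"s{next_s}"
        next_s += 1
        elements[label] = SSElement(label, (run,), 0)
        topology.append(label)

    prev_end = ordered[0].col_start if ordered else 0
    for r in ordered:
        add_spacer(prev_end, r.col_start)
        seg = cons[r.col_start:r.col_end]
        if r.kind == "ss":
            elements[r.label] = SSElement(
                r.label, _ss_tokens(annotation, r, run_slack), r.budget
            )
            topology.append(r.label)
        elif r.kind == "helix5":
            if GAP in seg:
                raise ValueError(
                    f"helix region {r.label!r} contains gap-consensus columns"
                )
            other = cons[helix3[r.label].col_start:helix3[r.label].col_end]
            if GAP in other:
                raise ValueError(
                    f"helix region {r.label!r} (3') contains gap-consensus columns"
                )
            elements[r.label] = HelixElement(r.label, seg, other, r.budget)
            topology.append(r.label)
        else:  # helix3: closing strand in topology order
            topology.append(r.label + "'")
        prev_end = r.col_end

    return DescriptorModel(
        name=name,
        subfamily=subfamily,
        variant=variant,
        topology=tuple(topology),
        elements=elements,
    )
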