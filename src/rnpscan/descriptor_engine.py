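"""Descriptor models and the fast structural-pattern scanner.

A descriptor model (DM) is an ordered pattern of single-strand elements
(IUPAC symbols plus variable-length runs, with a mismatch budget) and helix
elements (two complementary strands with a mispair budget).  Crossed helix
topologies express pseudoknots — e.g. the P4 pseudoknot of RNase P RNA —
which profile SCFGs cannot represent.  The scanner performs a depth-first
walk over the topology at every anchor position and reports the first match
per anchor, so output is deterministic.

Descriptor files use the "BDM v1" dialect::

    # comment
    name: toy-bacA
    subfamily: bacA
    variant: general
    topology: s1 h1 s2 h1' s3
    s1 0:GGN(2,5)RA
    h1 1:GGGC:GCCC pairs=AU,UA,GC,CG,GU,UG

Single-strand patterns mix IUPAC symbols with run tokens ``N(min,max)``;
helix strands are written 5'->3' on both sides.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Union

from .io_formats import IUPAC_CODES, FormatError, SequenceRecord

__all__ = [
    "SSElement",
    "HelixElement",
    "DescriptorModel",
    "DescriptorHit",
    "RunToken",
    "DEFAULT_PAIR_SET",
    "iupac_match",
    "pairs_ok",
    "reverse_complement",
    "parse_descriptor",
    "parse_descriptor_text",
    "format_descriptor",
    "match_at",
    "scan",
]

#: Watson-Crick plus wobble, on the internal DNA alphabet (T stands for U).
DEFAULT_PAIR_SET: frozenset[tuple[str, str]] = frozenset(
    [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")]
)

_COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def iupac_match(pattern_symbol: str, base: str) -> bool:
    """True iff *base* lies in the expansion of the IUPAC *pattern_symbol*."""
    try:
        return base in IUPAC_CODES[pattern_symbol]
    except KeyError:
        raise ValueError(f"invalid IUPAC code {pattern_symbol!r}") from None


def pairs_ok(b5: str, b3: str, pair_set: frozenset = DEFAULT_PAIR_SET) -> bool:
    """True iff (b5, b3) is an allowed base pair."""
    return (b5, b3) in pair_set


def reverse_complement(residues: str) -> str:
    """Reverse complement with IUPAC codes mapped to their complements."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(residues))
    except KeyError as exc:
        raise ValueError(f"cannot complement symbol {exc.args[0]!r}") from None


@dataclass(frozen=True)
class RunToken:
    """A variable-length run of arbitrary residues, ``min <= length <= max``."""

    min: int
    max: int

    def __post_init__(self) -> None:
        if not (0 <= self.min <= self.max):
            raise ValueError(f"run token requires 0 <= min <= max, got {self}")


Token = Union[str, RunToken]


@dataclass(frozen=True)
class SSElement:
    """A single-strand element: fixed IUPAC tokens and/or run tokens.

    The mismatch budget applies to the fixed IUPAC tokens only; run tokens
    consume arbitrary residues.
    """

    label: str
    tokens: tuple[Token, ...]
    mismatch_budget: int = 0

    def __post_init__(self) -> None:
        if self.mismatch_budget < 0:
            raise ValueError("mismatch_budget must be >= 0")
        for t in self.tokens:
            if isinstance(t, str) and t not in IUPAC_CODES:
                raise ValueError(f"invalid IUPAC token {t!r} in element {self.label}")

    @property
    def min_span(self) -> int:
        return sum(t.min if isinstance(t, RunToken) else 1 for t in self.tokens)


@dataclass(frozen=True)
class HelixElement:
    """A fixed-length helix: 5' and 3' strands (both written 5'->3').

    Strand residues must satisfy their IUPAC symbols exactly; the mispair
    budget counts pairing violations between the two strands.  ``N`` in the
    subject satisfies any symbol but always counts as a mispair.
    """

    label: str
    strand5: str
    strand3: str
    mispair_budget: int = 0
    pair_set: frozenset = DEFAULT_PAIR_SET

    def __post_init__(self) -> None:
        if len(self.strand5) != len(self.strand3):
            raise FormatError(
                f"helix {self.label}: strand lengths differ "
                f"({len(self.strand5)} vs {len(self.strand3)})"
            )
        if self.mispair_budget < 0:
            raise ValueError("mispair_budget must be >= 0")

    def __len__(self) -> int:
        return len(self.strand5)


SUBFAMILIES = ("arcA", "arcM", "bacA", "bacB", "nucA", "fugA", "fugB")


@dataclass(frozen=True)
class DescriptorModel:
    """An ordered descriptor: topology over SS and helix elements."""

    name: str
    subfamily: str
    variant: str
    topology: tuple[str, ...]
    elements: dict

    def __post_init__(self) -> None:
        if self.subfamily not in SUBFAMILIES:
            raise ValueError(f"unknown subfamily {self.subfamily!r}")
        if self.variant not in ("selective", "general"):
            raise ValueError(f"variant must be selective|general, got {self.variant!r}")
        opened: set[str] = set()
        helix_refs: dict[str, int] = {}
        for lab in self.topology:
            base = lab.rstrip("'")
            if base not in self.elements:
                raise FormatError(f"topology label {lab!r} does not resolve")
            el = self.elements[base]
            if isinstance(el, HelixElement):
                helix_refs[base] = helix_refs.get(base, 0) + 1
                if lab.endswith("'"):
                    if base not in opened:
                        raise FormatError(
                            f"helix closing strand {lab!r} appears before its opening"
                        )
                else:
                    opened.add(base)
        for base, el in self.elements.items():
            if isinstance(el, HelixElement) and helix_refs.get(base, 0) != 2:
                raise FormatError(
                    f"helix {base!r} must appear exactly twice in topology "
                    f"(found {helix_refs.get(base, 0)})"
                )

    @property
    def min_span(self) -> int:
        total = 0
        for lab in self.topology:
            el = self.elements[lab.rstrip("'")]
            total += len(el) if isinstance(el, HelixElement) else el.min_span
        return total


@dataclass(frozen=True)
class DescriptorHit:
    """One descriptor match.

    ``start``/``end`` are forward-strand 0-based half-open coordinates.
    ``element_spans`` are coordinates on the *matched* strand (for minus
    hits: on the reverse complement of the record).
    """

    seq_id: str
    strand: str
    start: int
    end: int
    element_spans: dict
    mismatches_used: int
    mispairs_used: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


# -- BDM v1 parsing -----------------------------------------------------------

_RUN_RE = re.compile(r"N\((\d+),(\d+)\)")


def _parse_ss_pattern(pattern: str, label: str) -> tuple[Token, ...]:
    tokens: list[Token] = []
    i = 0
    while i < len(pattern):
        m = _RUN_RE.match(pattern, i)
        if m:
            tokens.append(RunToken(int(m.group(1)), int(m.group(2))))
            i = m.end()
        else:
            ch = pattern[i]
            if ch not in IUPAC_CODES:
                raise FormatError(
                    f"element {label}: invalid pattern symbol {ch!r}"
                )
            tokens.append(ch)
            i += 1
    return tuple(tokens)


def _parse_pair_set(text: str) -> frozenset:
    pairs = set()
    for item in text.split(","):
        item = item.strip().upper().replace("U", "T")
        if len(item) != 2:
            raise FormatError(f"malformed pair {item!r} in pairs= clause")
        pairs.add((item[0], item[1]))
    return frozenset(pairs)


def parse_descriptor_text(text: str, source: str = "<string>") -> DescriptorModel:
    """Parse a BDM v1 descriptor from a string."""
    headers: dict[str, str] = {}
    topology: Optional[tuple[str, ...]] = None
    elements: dict = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, rest = line.partition(":")
        key = key.strip()
        if key in ("name", "subfamily", "variant"):
            headers[key] = rest.strip()
            continue
        if key == "topology":
            topology = tuple(rest.split())
            continue
        # element line: "<label> <budget>:<pattern>[:<strand3>][ pairs=...]"
        m = re.match(r"^([sh]\d+)\s+(\d+):(\S+?)(?:\s+pairs=(\S+))?$", line)
        if not m:
            raise FormatError(f"{source}:{lineno}: cannot parse element line {raw!r}")
        label, budget, body, pairs_clause = m.groups()
        budget = int(budget)
        if label.startswith("h"):
            parts = body.split(":")
            if len(parts) != 2:
                raise FormatError(
                    f"{source}:{lineno}: helix line needs strand5:strand3"
                )
            s5 = parts[0].upper().replace("U", "T")
            s3 = parts[1].upper().replace("U", "T")
            pair_set = _parse_pair_set(pairs_clause) if pairs_clause else DEFAULT_PAIR_SET
            elements[label] = HelixElement(label, s5, s3, budget, pair_set)
        else:
            pattern = body.upper().replace("U", "T")
            elements[label] = SSElement(label, _parse_ss_pattern(pattern, label), budget)
    if topology is None:
        raise FormatError(f"{source}: missing topology line")
    for h in ("name", "subfamily", "variant"):
        if h not in headers:
            raise FormatError(f"{source}: missing header line {h!r}")
    return DescriptorModel(
        name=headers["name"],
        subfamily=headers["subfamily"],
        variant=headers["variant"],
        topology=topology,
        elements=elements,
    )


def parse_descriptor(path) -> DescriptorModel:
    """Parse a BDM v1 descriptor file into a validated model."""
    with open(path) as fh:
        return parse_descriptor_text(fh.read(), source=str(path))


def format_descriptor(model: DescriptorModel) -> str:
    """Serialize a model back to BDM v1 text."""
    lines = [
        f"name: {model.name}",
        f"subfamily: {model.subfamily}",
        f"variant: {model.variant}",
        f"topology: {' '.join(model.topology)}",
    ]
    for label in sorted(model.elements, key=lambda s: (s[0], int(s[1:]))):
        el = model.elements[label]
        if isinstance(el, HelixElement):
            line = f"{label} {el.mispair_budget}:{el.strand5}:{el.strand3}"
            if el.pair_set != DEFAULT_PAIR_SET:
                line += " pairs=" + ",".join(sorted(a + b for a, b in el.pair_set))
        else:
            pat = "".join(
                t if isinstance(t, str) else f"N({t.min},{t.max})" for t in el.tokens
            )
            line = f"{label} {el.mismatch_budget}:{pat}"
        lines.append(line)
    return "\n".join(lines) + "\n"


# -- matching -----------------------------------------------------------------

def match_at(record: SequenceRecord, pos: int, model: DescriptorModel):
    """First descriptor match anchored at *pos*, or ``None``.

    Depth-first over topology order; run tokens try shorter lengths first;
    the first complete match wins.  ``N`` in the subject satisfies any
    single-strand symbol (without spending budget) but counts as a mispair
    when it sits in a helix.
    """
    seq = record.residues
    n = len(seq)
    if not (0 <= pos <= n):
        raise ValueError(f"anchor {pos} outside [0, {n}]")
    topology = model.topology
    spans: dict = {}
    mm_used: dict = {}
    mp_used: dict = {}

    def walk(ti: int, p: int) -> bool:
        if ti == len(topology):
            return True
        lab = topology[ti]
        base = lab.rstrip("'")
        el = model.elements[base]
        if isinstance(el, SSElement):
            return match_ss(el, lab, ti, p)
        L = len(el)
        if p + L > n:
            return False
        segment = seq[p:p + L]
        if lab.endswith("'"):
            sym = el.strand3
            for i, ch in enumerate(segment):
                if ch != "N" and not iupac_match(sym[i], ch):
                    return False
            o_start, o_end = spans[base]
            open_seg = seq[o_start:o_end]
            mis = 0
            for i in range(L):
                b5 = open_seg[L - 1 - i]
                b3 = segment[i]
                if b5 == "N" or b3 == "N" or not pairs_ok(b5, b3, el.pair_set):
                    mis += 1
            if mis > el.mispair_budget:
                return False
            spans[lab] = (p, p + L)
            mp_used[base] = mis
            if walk(ti + 1, p + L):
                return True
            del spans[lab]
            del mp_used[base]
            return False
        else:
            for i, ch in enumerate(segment):
                if ch != "N" and not iupac_match(el.strand5[i], ch):
                    return False
            spans[lab] = (p, p + L)
            if walk(ti + 1, p + L):
                return True
            del spans[lab]
            return False

    def match_ss(el: SSElement, lab: str, ti: int, p: int) -> bool:
        tokens = el.tokens

        def go(k: int, q: int, mm: int) -> bool:
            if k == len(tokens):
                spans[lab] = (p, q)
                mm_used[lab] = mm
                if walk(ti + 1, q):
                    return True
                del spans[lab]
                del mm_used[lab]
                return False
            tok = tokens[k]
            if isinstance(tok, RunToken):
                for L in range(tok.min, tok.max + 1):
                    if q + L > n:
                        break
                    if go(k + 1, q + L, mm):
                        return True
                return False
            if q >= n:
                return False
            ch = seq[q]
            if ch == "N" or iupac_match(tok, ch):
                return go(k + 1, q + 1, mm)
            if mm < el.mismatch_budget:
                return go(k + 1, q + 1, mm + 1)
            return False

        return go(0, p, 0)

    if walk(0, pos):
        end = max((e for _, e in spans.values()), default=pos)
        return DescriptorHit(
            seq_id=record.id,
            strand="+",
            start=pos,
            end=end,
            element_spans=dict(spans),
            mismatches_used=sum(mm_used.values()),
            mispairs_used=sum(mp_used.values()),
        )
    return None


def _anchor_prefilter(model: DescriptorModel) -> Optional[re.Pattern]:
    """A regex matching a necessary prefix of any match, or None.

    Only derived from leading tokens whose match is exact: a leading helix
    strand (strand symbols admit no budget) or the fixed prefix of a
    zero-budget SS element.  Subject ``N`` is always admitted.
    """
    first = model.topology[0]
    el = model.elements[first.rstrip("'")]
    if isinstance(el, HelixElement):
        syms: Iterable[str] = el.strand5
    elif el.mismatch_budget == 0:
        syms = []
        for t in el.tokens:
            if isinstance(t, RunToken):
                break
            syms.append(t)
    else:
        return None
    classes = []
    for s in syms:
        bases = sorted(IUPAC_CODES[s] | {"N"})
        classes.append("[" + "".join(bases) + "]")
    if len(classes) < 3:  # too unspecific to pay off
        return None
    return re.compile("(?=" + "".join(classes) + ")")


def _scan_one_strand(record: SequenceRecord, model: DescriptorModel) -> list[DescriptorHit]:
    pre = _anchor_prefilter(model)
    n = len(record.residues)
    if pre is None:
        anchors: Iterable[int] = range(n + 1)
    else:
        anchors = (m.start() for m in pre.finditer(record.residues))
    hits = []
    for pos in anchors:
        h = match_at(record, pos, model)
        if h is not None:
            hits.append(h)
    return hits


def scan(
    record: SequenceRecord, model: DescriptorModel, strands: str = "both"
) -> list[DescriptorHit]:
    """All first-per-anchor descriptor matches on the requested strands.

    Minus-strand hits are found on the reverse complement and reported in
    forward coordinates with strand ``-`` (element spans stay on the matched
    strand).  Output is sorted by (start, strand); overlapping hits are all
    reported — deduplication happens downstream.
    """
    if strands not in ("+", "-", "both"):
        raise ValueError(f"strands must be +|-|both, got {strands!r}")
    n = len(record.residues)
    hits: list[DescriptorHit] = []
    if strands in ("+", "both"):
        hits.extend(_scan_one_strand(record, model))
    if strands in ("-", "both"):
        rc = SequenceRecord(id=record.id, residues=reverse_complement(record.residues))
        for h in _scan_one_strand(rc, model):
            hits.append(
                DescriptorHit(
                    seq_id=record.id,
                    strand="-",
                    start=n - h.end,
                    end=n - h.start,
                    element_spans=h.element_spans,
                    mismatches_used=h.mismatches_used,
                    mispairs_used=h.mispairs_used,
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand, h.end))
    return hits
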