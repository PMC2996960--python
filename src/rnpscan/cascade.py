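"""The wrapping algorithm: local to global, selective to general.

Per subfamily, a tight "selective" descriptor (when one exists) filters the
sequence first; its hits are validated by the covariance model in free-flank
(local) mode.  Only if the selective stage yields **zero validated hits**
does the relaxed "general" descriptor run.  Every validated candidate window
is extended (150 nt at the 5' end, 300 nt at the 3' end, in transcript
orientation), re-aligned with the whole model to refine the gene boundaries,
and re-thresholded: at both phases the E-value must reach the configured
threshold (default 1e-10).  Overlapping calls from different subfamilies are
resolved by E-value.

A CM-only mode slides windows over the sequence without any descriptor
filter; it is far slower but rescues genes whose local quirks defeat the
descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from . import cm_lite
from .cm_lite import CovarianceModel
from .descriptor_engine import (
    DescriptorHit,
    DescriptorModel,
    format_descriptor,
    parse_descriptor,
    reverse_complement,
    scan,
)
from .io_formats import SequenceRecord

__all__ = [
    "GeneCall",
    "ScanConfig",
    "SubfamilyModels",
    "ModelLibrary",
    "StageLog",
    "extend_window",
    "validate_candidate",
    "scan_subfamily",
    "scan_all",
    "scan_cm_only",
    "resolve_overlaps",
    "load_library",
    "save_library",
]


@dataclass(frozen=True)
class GeneCall:
    """A validated, boundary-refined gene prediction.

    ``start``/``end`` are forward 0-based half-open; ``sequence`` and
    ``structure`` are in transcript orientation (reverse-complemented for
    minus-strand calls).
    """

    seq_id: str
    strand: str
    start: int
    end: int
    subfamily: str
    dm_variant: str
    local_score: float
    global_score: float
    evalue: float
    sequence: str
    structure: str
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.sequence):
            raise ValueError("structure/sequence length mismatch")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class ScanConfig:
    """Pipeline knobs; the defaults are the production settings."""

    evalue_threshold: float = 1e-10
    extension_5prime: int = 150
    extension_3prime: int = 300
    strands: str = "both"
    seed: int = 0
    run_selective: bool = True
    run_general: bool = True
    report_partials: bool = False

    def __post_init__(self) -> None:
        if self.extension_5prime < 0 or self.extension_3prime < 0:
            raise ValueError("extensions must be >= 0")
        if self.evalue_threshold <= 0:
            raise ValueError("evalue threshold must be > 0")

    @property
    def strand_count(self) -> int:
        return 2 if self.strands == "both" else 1


@dataclass
class SubfamilyModels:
    """One subfamily's bundle: optional selective DM, general DM, CM.

    Builder provenance (training alignment, held-out members) may ride
    along for fixtures; it is optional and not needed for scanning.
    """

    general: DescriptorModel
    cm: CovarianceModel
    selective: Optional[DescriptorModel] = None
    alignment: Optional[object] = None
    members: Optional[list] = None
    aberrant_member: Optional[str] = None
    template: Optional[object] = None
    regions: Optional[list] = None
    annotation: Optional[object] = None


@dataclass
class ModelLibrary:
    """Per-subfamily model bundles, keyed by subfamily name."""

    entries: dict

    def __post_init__(self) -> None:
        for sub, entry in self.entries.items():
            if entry.general is None or entry.cm is None:
                raise ValueError(f"subfamily {sub}: general DM and CM are required")

    def subfamilies(self) -> list[str]:
        return sorted(self.entries)

    def __getitem__(self, sub: str) -> SubfamilyModels:
        return self.entries[sub]


class StageLog:
    """Chronological record of which pipeline stages ran and what they saw."""

    def __init__(self) -> None:
        self.events: list[dict] = []

    def add(self, **kw) -> None:
        self.events.append(kw)

    def stages_run(self, seq_id: str, subfamily: str) -> list[str]:
        return [
            e["stage"]
            for e in self.events
            if e.get("seq_id") == seq_id and e.get("subfamily") == subfamily
        ]


def extend_window(
    span: tuple[int, int],
    record_length: int,
    config: ScanConfig,
    strand: str = "+",
) -> tuple[int, int, frozenset]:
    """Extend a candidate span 150/300 nt at its 5'/3' ends (transcript
    orientation), clipped to the record bounds.

    On the minus strand the 5' extension grows the forward-coordinate end.
    Returns (start, end, flags) with clip flags when a boundary was hit.
    """
    start, end = span
    if strand == "+":
        ws = start - config.extension_5prime
        we = end + config.extension_3prime
        clip5_low, clip3_high = True, True  # which forward bound maps to which end
    else:
        ws = start - config.extension_3prime
        we = end + config.extension_5prime
        clip5_low, clip3_high = False, False
    flags = set()
    if ws < 0:
        flags.add("clipped_5prime" if strand == "+" else "clipped_3prime")
        ws = 0
    if we > record_length:
        flags.add("clipped_3prime" if strand == "+" else "clipped_5prime")
        we = record_length
    return ws, we, frozenset(flags)


def _window_residues(record: SequenceRecord, start: int, end: int, strand: str) -> str:
    seg = record.residues[start:end]
    return seg if strand == "+" else reverse_complement(seg)


def validate_candidate(
    hit: DescriptorHit,
    record: SequenceRecord,
    cm: CovarianceModel,
    config: ScanConfig,
):
    """Score a descriptor hit window with the free-flank CM; accept iff
    the E-value (search space = record length) reaches the threshold."""
    if cm.evd is None:
        raise ValueError("model is not calibrated")
    window = _window_residues(record, hit.start, hit.end, hit.strand)
    if not window:
        return None
    sa = cm_lite.score_local(cm, window)
    ev = cm_lite.evalue(cm, sa.score, len(record), strands=config.strand_count)
    if ev <= config.evalue_threshold:
        return sa, ev
    return None


def _refine(
    record: SequenceRecord,
    hit_span: tuple[int, int],
    strand: str,
    cm: CovarianceModel,
    config: ScanConfig,
    subfamily: str,
    dm_variant: str,
    local_score: float,
) -> Optional[GeneCall]:
    """Extend the window, re-align the whole model (free flanks), map the
    matched span back to forward coordinates, and re-threshold."""
    ws, we, flags = extend_window(hit_span, len(record), config, strand)
    wseq = _window_residues(record, ws, we, strand)
    if not wseq:
        return None
    sa = cm_lite.score_local(cm, wseq)
    ev = cm_lite.evalue(cm, sa.score, len(record), strands=config.strand_count)
    emit_flags = set(flags)
    if ev > config.evalue_threshold:
        if not config.report_partials:
            return None
        emit_flags.add("low_confidence")
    wlen = we - ws
    if strand == "+":
        f_start, f_end = ws + sa.start, ws + sa.end
    else:
        f_start, f_end = ws + wlen - sa.end, ws + wlen - sa.start
    return GeneCall(
        seq_id=record.id,
        strand=strand,
        start=f_start,
        end=f_end,
        subfamily=subfamily,
        dm_variant=dm_variant,
        local_score=local_score,
        global_score=sa.score,
        evalue=ev,
        sequence=wseq[sa.start:sa.end],
        structure=sa.structure,
        flags=frozenset(emit_flags),
    )


def scan_subfamily(
    record: SequenceRecord,
    models: SubfamilyModels,
    config: ScanConfig = ScanConfig(),
    log: Optional[StageLog] = None,
) -> list[GeneCall]:
    """Run one subfamily's cascade on one record.

    Selective first; the general descriptor runs only when the selective
    stage produced zero CM-validated hits.  Every validated hit is extended
    and refined; calls overlapping within the subfamily collapse to the
    best E-value.
    """
    sub = models.cm.subfamily
    stages: list[tuple[str, Optional[DescriptorModel]]] = []
    if config.run_selective and models.selective is not None:
        stages.append(("selective", models.selective))
    if config.run_general:
        stages.append(("general", models.general))

    for variant, dm in stages:
        hits = scan(record, dm, config.strands)
        if log is not None:
            log.add(seq_id=record.id, subfamily=sub, stage=variant, n_hits=len(hits))
        validated = []
        for hit in hits:
            v = validate_candidate(hit, record, models.cm, config)
            if v is not None:
                validated.append((hit, v))
        if log is not None:
            log.add(
                seq_id=record.id, subfamily=sub,
                stage=f"{variant}-validated", n_hits=len(validated),
            )
        if not validated:
            continue
        calls = []
        for hit, (local_sa, _local_ev) in validated:
            call = _refine(
                record, hit.span, hit.strand, models.cm, config,
                sub, variant, local_sa.score,
            )
            if call is not None:
                calls.append(call)
        return resolve_overlaps(calls)
    return []


def scan_all(
    records: Iterable[SequenceRecord],
    library: ModelLibrary,
    config: ScanConfig = ScanConfig(),
    log: Optional[StageLog] = None,
) -> list[GeneCall]:
    """Cascade over all records and subfamilies; cross-subfamily overlaps
    resolved by E-value; output sorted by (seq_id, start)."""
    calls: list[GeneCall] = []
    for record in records:
        per_record: list[GeneCall] = []
        for sub in library.subfamilies():
            per_record.extend(scan_subfamily(record, library[sub], config, log))
        calls.extend(resolve_overlaps(per_record))
    calls.sort(key=lambda c: (c.seq_id, c.start, c.end, c.strand))
    return calls


def resolve_overlaps(calls: Sequence[GeneCall]) -> list[GeneCall]:
    """Among calls overlapping on the same record and strand keep the lowest
    E-value; ties break by higher global score, then subfamily name."""
    chosen: list[GeneCall] = []
    rank = lambda c: (c.evalue, -c.global_score, c.subfamily)
    for call in sorted(calls, key=lambda c: (c.seq_id, c.strand) + rank(c)):
        conflict = any(
            c.seq_id == call.seq_id
            and c.strand == call.strand
            and c.start < call.end
            and call.start < c.end
            for c in chosen
        )
        if not conflict:
            chosen.append(call)
    chosen.sort(key=lambda c: (c.seq_id, c.start, c.end, c.strand))
    return chosen


def scan_cm_only(
    records: Iterable[SequenceRecord],
    cm: CovarianceModel,
    config: ScanConfig = ScanConfig(),
) -> list[GeneCall]:
    """Slide 2M-length windows (50% overlap), score each with the free-flank
    CM, merge overlapping passing windows, and refine each merged window.

    No descriptor filter is involved; ``dm_variant`` is ``cm-only``.
    """
    if cm.evd is None:
        raise ValueError("model is not calibrated")
    out: list[GeneCall] = []
    wlen = 2 * cm.M
    step = max(1, wlen // 2)
    strand_list = ["+", "-"] if config.strands == "both" else [config.strands]
    for record in records:
        n = len(record)
        per_record: list[GeneCall] = []
        for strand in strand_list:
            passing: list[tuple[int, int, float]] = []
            starts = list(range(0, max(1, n - wlen + 1), step))
            if starts and starts[-1] + wlen < n:
                starts.append(n - wlen)
            for ws in starts:
                we = min(n, ws + wlen)
                wseq = _window_residues(record, ws, we, strand)
                if not wseq:
                    continue
                sa = cm_lite.score_local(cm, wseq)
                ev = cm_lite.evalue(cm, sa.score, n, strands=config.strand_count)
                if ev <= config.evalue_threshold:
                    passing.append((ws, we, sa.score))
            # union of overlapping passing windows
            merged: list[list] = []
            for ws, we, s in sorted(passing):
                if merged and ws <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], we)
                    merged[-1][2] = max(merged[-1][2], s)
                else:
                    merged.append([ws, we, s])
            for ws, we, best_local in merged:
                call = _refine(
                    record, (ws, we), strand, cm,
                    replace(config, extension_5prime=0, extension_3prime=0),
                    cm.subfamily, "cm-only", best_local,
                )
                if call is not None:
                    per_record.append(call)
        out.extend(resolve_overlaps(per_record))
    out.sort(key=lambda c: (c.seq_id, c.start, c.end, c.strand))
    return out


# -- model-archive persistence ------------------------------------------------

def save_library(library: ModelLibrary, directory) -> None:
    """One directory per subfamily: descriptor files, alignment, CM file."""
    from .io_formats import write_stockholm

    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    for sub in library.subfamilies():
        entry = library[sub]
        d = root / sub
        d.mkdir(exist_ok=True)
        (d / "general.dm").write_text(format_descriptor(entry.general))
        if entry.selective is not None:
            (d / "selective.dm").write_text(format_descriptor(entry.selective))
        cm_lite.write_cm(entry.cm, d / "cm.txt")
        aln = getattr(entry, "alignment", None)
        if aln is not None:
            write_stockholm(aln, d / "align.sto")


def load_library(directory) -> ModelLibrary:
    root = Path(directory)
    entries = {}
    for d in sorted(p for p in root.iterdir() if p.is_dir()):
        general = parse_descriptor(d / "general.dm")
        selective = None
        if (d / "selective.dm").exists():
            selective = parse_descriptor(d / "selective.dm")
        cm = cm_lite.read_cm(d / "cm.txt")
        entries[d.name] = SubfamilyModels(general=general, cm=cm, selective=selective)
    if not entries:
        raise FileNotFoundError(f"no subfamily directories under {directory}")
    return ModelLibrary(entries=entries)
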