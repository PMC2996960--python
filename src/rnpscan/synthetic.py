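"""Synthetic fixtures: random backgrounds, planted genes, and toy models.

Every pipeline stage is testable without external data.  A toy "gene
family" is generated from a declarative template — nested helices with
covarying pairs, conserved sequence boxes with rare substitutions, and
variable-length spacers — which yields, by construction, a gap-free truth:
the structural alignment, the selective and general descriptors, the
covariance model, and held-out aberrant members that exercise the
selective-to-general fallback.

The toy genes are deliberately small (roughly 130-145 nt consensus) so that
covariance-model dynamic programming over planted genomes runs in seconds;
they emulate the *structure* of the detection problem (conserved stems and
boxes separated by variable spacers, embedded in random background), not
RNase P sequence evolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import cm_lite
from .cascade import ModelLibrary, SubfamilyModels
from .consensus_builder import Region, alignment_consensus, build_descriptor
from .descriptor_engine import (
    DEFAULT_PAIR_SET,
    DescriptorModel,
    RunToken,
    SSElement,
    reverse_complement,
)
from .io_formats import IUPAC_CODES, SequenceRecord, StructuredAlignment

__all__ = [
    "PlantedGenome",
    "random_background",
    "sample_from_descriptor",
    "plant",
    "make_toy_library",
    "make_planted_genomes",
    "make_strict_models",
    "sample_member",
]

_CANONICAL_PAIRS = sorted(DEFAULT_PAIR_SET)


@dataclass
class PlantedGenome:
    """A background record with known planted gene loci."""

    record: SequenceRecord
    truth: list  # (start, end, strand, subfamily)
    gc: float
    seed: int


def random_background(length: int, gc: float, seed: int) -> SequenceRecord:
    """I.i.d. background with P(G) = P(C) = gc/2; deterministic per seed."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.array(list("ACGT")), size=length, p=p)
    return SequenceRecord(id=f"bg{seed}", residues="".join(bases))


def sample_from_descriptor(model: DescriptorModel, seed) -> str:
    """Draw one residue string the model accepts with zero budget usage.

    IUPAC tokens sample uniformly from their expansion; run tokens sample a
    uniform length and i.i.d. residues; helix columns sample an allowed
    base pair compatible with both strand symbols (error if the symbol
    constraints admit none).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parts: dict[str, str] = {}
    for lab in model.topology:
        base = lab.rstrip("'")
        el = model.elements[base]
        if isinstance(el, SSElement):
            chars = []
            for tok in el.tokens:
                if isinstance(tok, RunToken):
                    L = int(rng.integers(tok.min, tok.max + 1))
                    chars.extend(rng.choice(list("ACGT")) for _ in range(L))
                else:
                    chars.append(str(rng.choice(sorted(IUPAC_CODES[tok]))))
            parts[lab] = "".join(chars)
        elif not lab.endswith("'"):
            L = len(el)
            open_chars = [""] * L
            close_chars = [""] * L
            for i in range(L):
                tok5 = el.strand5[i]
                tok3 = el.strand3[L - 1 - i]
                candidates = [
                    (a, b)
                    for a, b in sorted(el.pair_set)
                    if a in IUPAC_CODES[tok5] and b in IUPAC_CODES[tok3]
                ]
                if not candidates:
                    raise ValueError(
                        f"helix {base}: no allowed pair satisfies symbols "
                        f"{tok5}/{tok3}"
                    )
                a, b = candidates[int(rng.integers(len(candidates)))]
                open_chars[i] = a
                close_chars[L - 1 - i] = b
            parts[base] = "".join(open_chars)
            parts[base + "'"] = "".join(close_chars)
    return "".join(parts[lab] for lab in model.topology)


def plant(
    background,
    insert: str,
    position: int,
    strand: str = "+",
    subfamily: str = "bacA",
) -> PlantedGenome:
    """Overwrite a span of the background with the insert (reverse
    complemented for minus-strand planting); coordinates stay stable.

    Accepts either a :class:`SequenceRecord` or an existing
    :class:`PlantedGenome` (for multiple plants)."""
    if isinstance(background, PlantedGenome):
        genome = background
    else:
        genome = PlantedGenome(record=background, truth=[], gc=float("nan"), seed=-1)
    rec = genome.record
    if position < 0 or position + len(insert) > len(rec):
        raise ValueError("plant span outside the background record")
    payload = insert if strand == "+" else reverse_complement(insert)
    residues = rec.residues[:position] + payload + rec.residues[position + len(insert):]
    new_rec = SequenceRecord(id=rec.id, residues=residues, description=rec.description)
    truth = list(genome.truth) + [(position, position + len(insert), strand, subfamily)]
    return PlantedGenome(record=new_rec, truth=truth, gc=genome.gc, seed=genome.seed)


# -- toy family templates ------------------------------------------------------


@dataclass
class _Template:
    subfamily: str
    layout: list          # ordered ("h_open"|"h_close"|"box"|"spacer", label, ...)
    helix_pairs: dict     # label -> list of (b5, b3) per column
    boxes: dict           # label -> conserved string
    spacers: dict         # label -> (min_len, max_len)
    cov_site: tuple       # (helix label, column): the designated covarying column

    #: pair types alternating at the covarying column; their cross
    #: combinations (G-A, T-C) violate pairing while still satisfying the
    #: column's consensus symbols — the raw material for aberrant members.
    COV_TYPES = (("G", "C"), ("T", "A"))


def _make_template(subfamily: str, rng: np.random.Generator) -> _Template:
    """A nested toy architecture: a terminal helix enclosing conserved boxes,
    inner stem-loops, and variable spacers.  Helix pair identities and box
    sequences are drawn once per template."""
    if subfamily == "bacA":
        plan = [
            ("h_open", "h1", 12),
            ("box", "s1", 18),
            ("spacer", "sp1", 3, 6),
            ("h_open", "h2", 7),
            ("box", "s2", 6),
            ("h_close", "h2"),
            ("spacer", "sp2", 2, 5),
            ("box", "s3", 18),
            ("h_open", "h3", 6),
            ("box", "s4", 4),
            ("h_close", "h3"),
            ("spacer", "sp3", 2, 4),
            ("h_open", "h4", 6),
            ("box", "s5", 8),
            ("h_close", "h4"),
            ("box", "s6", 16),
            ("h_close", "h1"),
        ]
        cov_site = ("h2", 3)
    elif subfamily == "arcA":
        plan = [
            ("h_open", "h1", 10),
            ("box", "s1", 16),
            ("h_open", "h2", 6),
            ("box", "s2", 5),
            ("h_close", "h2"),
            ("spacer", "sp1", 4, 8),
            ("box", "s3", 17),
            ("spacer", "sp2", 2, 4),
            ("h_open", "h3", 7),
            ("box", "s4", 6),
            ("h_close", "h3"),
            ("box", "s5", 14),
            ("h_open", "h4", 5),
            ("box", "s6", 4),
            ("h_close", "h4"),
            ("box", "s7", 8),
            ("h_close", "h1"),
        ]
        cov_site = ("h3", 2)
    else:
        raise ValueError(f"no toy template for subfamily {subfamily!r}")

    helix_pairs = {}
    boxes = {}
    spacers = {}
    wc = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]
    for item in plan:
        if item[0] == "h_open":
            _, lab, length = item
            helix_pairs[lab] = [wc[int(rng.integers(4))] for _ in range(length)]
        elif item[0] == "box":
            _, lab, length = item
            boxes[lab] = "".join(str(rng.choice(list("ACGT"))) for _ in range(length))
        elif item[0] == "spacer":
            _, lab, lo, hi = item
            spacers[lab] = (lo, hi)
    helix_pairs[cov_site[0]][cov_site[1]] = _Template.COV_TYPES[0]
    return _Template(subfamily, plan, helix_pairs, boxes, spacers, cov_site)


def _sample_member(
    tpl: _Template,
    rng: np.random.Generator,
    box_sub_prob: float = 0.35,
    aberrant: bool = False,
) -> dict:
    """One family member as a dict of element-label -> residues.

    Each box carries at most one substitution.  Helix columns are fixed
    except the template's designated covarying column, which alternates
    between two pair types.  An aberrant member carries no substitutions but
    places a non-pairing cross combination (still satisfying the column's
    consensus symbols) at the covarying column: exactly one mispair.
    """
    parts: dict[str, str] = {}
    for item in tpl.layout:
        kind, lab = item[0], item[1]
        if kind == "h_open":
            cols = []
            for i, (a, b) in enumerate(tpl.helix_pairs[lab]):
                if (lab, i) == tpl.cov_site:
                    if aberrant:
                        # cross the two pair types: G-A violates pairing but
                        # each base is seen in its column across members
                        a, b = tpl.COV_TYPES[0][0], tpl.COV_TYPES[1][1]
                    else:
                        a, b = tpl.COV_TYPES[int(rng.integers(2))]
                cols.append((a, b))
            L = len(cols)
            parts[lab] = "".join(c[0] for c in cols)
            parts[lab + "'"] = "".join(cols[L - 1 - j][1] for j in range(L))
        elif kind == "h_close":
            continue  # emitted with its opening strand
        elif kind == "box":
            s = list(tpl.boxes[lab])
            if not aberrant and rng.random() < box_sub_prob:
                pos = int(rng.integers(len(s)))
                s[pos] = str(rng.choice([b for b in "ACGT" if b != s[pos]]))
            parts[lab] = "".join(s)
        else:  # spacer
            lo, hi = tpl.spacers[lab]
            L = int(rng.integers(lo, hi + 1))
            parts[lab] = "".join(str(rng.choice(list("ACGT"))) for _ in range(L))
    return parts


def _member_sequence(tpl: _Template, parts: dict) -> str:
    out = []
    for item in tpl.layout:
        kind, lab = item[0], item[1]
        out.append(parts[lab + "'"] if kind == "h_close" else parts[lab])
    return "".join(out)


def _build_alignment(tpl: _Template, members: list) -> tuple[StructuredAlignment, list]:
    """Column layout: fixed-width elements as-is, spacers left-justified and
    gap-padded to their maximum length.  Returns the alignment and the
    region table (0-based half-open column ranges)."""
    widths = {}
    for item in tpl.layout:
        kind, lab = item[0], item[1]
        if kind == "spacer":
            widths[lab] = max(len(p[lab]) for p in members)
        elif kind == "h_close":
            widths[lab + "'"] = len(tpl.helix_pairs[lab])
        elif kind == "h_open":
            widths[lab] = len(tpl.helix_pairs[lab])
        else:
            widths[lab] = len(tpl.boxes[lab])

    col = 0
    ranges = {}
    ss_chars = []
    for item in tpl.layout:
        kind, lab = item[0], item[1]
        key = lab + "'" if kind == "h_close" else lab
        w = widths[key]
        ranges[key] = (col, col + w)
        if kind == "h_open":
            ss_chars.append("<" * w)
        elif kind == "h_close":
            ss_chars.append(">" * w)
        else:
            ss_chars.append("." * w)
        col += w

    rows = []
    for k, parts in enumerate(members):
        chunks = []
        for item in tpl.layout:
            kind, lab = item[0], item[1]
            key = lab + "'" if kind == "h_close" else lab
            s = parts[key] if kind == "h_close" else parts[lab]
            chunks.append(s + "-" * (widths[key] - len(s)))
        rows.append((f"{tpl.subfamily}_m{k}", "".join(chunks)))

    aln = StructuredAlignment(rows=rows, consensus_structure="".join(ss_chars))

    regions = []
    for item in tpl.layout:
        kind, lab = item[0], item[1]
        if kind == "h_open":
            a, b = ranges[lab]
            regions.append(Region(lab, "helix5", a, b, 0))
        elif kind == "h_close":
            a, b = ranges[lab + "'"]
            regions.append(Region(lab, "helix3", a, b, 0))
        elif kind == "box":
            a, b = ranges[lab]
            regions.append(Region(lab, "ss", a, b, 0))
    return aln, regions


def _with_budgets(regions: list, ss_budget: int, helix_budget: int) -> list:
    out = []
    for r in regions:
        budget = ss_budget if r.kind == "ss" else helix_budget
        out.append(Region(r.label, r.kind, r.col_start, r.col_end, budget))
    return out


def make_toy_library(
    seed: int,
    n_members: int = 12,
    n_decoys: int = 300,
    subfamilies: Sequence[str] = ("bacA", "arcA"),
) -> ModelLibrary:
    """A deterministic toy model library for fixtures and acceptance runs.

    Each subfamily gets a selective DM (tight budgets), a general DM
    (relaxed budgets and widened run ranges), a structural alignment of the
    sampled members, a calibrated CM, and one held-out "aberrant" member
    carrying a helix mispair — it fails the selective DM (mispair budget 0)
    but matches the general one (budget 1), exercising the fallback.
    """
    rng = np.random.default_rng(seed)
    entries = {}
    for subfamily in subfamilies:
        sub_rng = np.random.default_rng(rng.integers(2**31))
        tpl = _make_template(subfamily, sub_rng)
        members = [_sample_member(tpl, sub_rng) for _ in range(n_members)]
        # both covarying pair types must appear in training, else the
        # column's consensus cannot admit the aberrant cross combination
        h, c = tpl.cov_site
        while len({p[h][c] for p in members}) < 2:
            members[-1] = _sample_member(tpl, sub_rng)
        aberrant = _member_sequence(tpl, _sample_member(tpl, sub_rng, aberrant=True))

        aln, base_regions = _build_alignment(tpl, members)
        annotation = alignment_consensus(aln)

        selective = build_descriptor(
            annotation, _with_budgets(base_regions, 1, 0),
            name=f"toy-{subfamily}-sel", subfamily=subfamily,
            variant="selective", run_slack=0,
        )
        general = build_descriptor(
            annotation, _with_budgets(base_regions, 2, 1),
            name=f"toy-{subfamily}-gen", subfamily=subfamily,
            variant="general", run_slack=1,
        )

        cm = cm_lite.build_cm(
            aln, gap_threshold=0.5, pseudocount=0.5,
            name=f"toy-{subfamily}", subfamily=subfamily,
        )
        cm_lite.calibrate(cm, n_decoys=n_decoys, seed=int(rng.integers(2**31)))

        entry = SubfamilyModels(
            general=general,
            cm=cm,
            selective=selective,
            alignment=aln,
            members=[_member_sequence(tpl, p) for p in members],
            aberrant_member=aberrant,
        )
        entry.template = tpl  # sampler for fresh held-out members
        entry.regions = base_regions
        entry.annotation = annotation
        entries[subfamily] = entry
    return ModelLibrary(entries=entries)


def make_strict_models(entry: SubfamilyModels) -> SubfamilyModels:
    """A deliberately over-tight descriptor variant of a toy entry.

    Zero mismatch and mispair budgets and exact-length runs for both
    descriptor roles: aberrant members slip through this filter entirely,
    which is what the CM-only search mode exists to rescue.
    """
    annotation = entry.annotation
    regions = _with_budgets(entry.regions, 0, 0)
    sub = entry.cm.subfamily
    strict_sel = build_descriptor(
        annotation, regions, name=f"toy-{sub}-strict-sel", subfamily=sub,
        variant="selective", run_slack=0,
    )
    strict_gen = build_descriptor(
        annotation, regions, name=f"toy-{sub}-strict-gen", subfamily=sub,
        variant="general", run_slack=0,
    )
    return SubfamilyModels(
        general=strict_gen, cm=entry.cm, selective=strict_sel,
        alignment=entry.alignment, members=entry.members,
        aberrant_member=entry.aberrant_member, template=entry.template,
    )


def sample_member(entry: SubfamilyModels, rng: np.random.Generator) -> str:
    """A fresh held-out family member for planting (descriptor-consistent)."""
    tpl = getattr(entry, "template", None)
    if tpl is None:
        return sample_from_descriptor(entry.general, rng)
    return _member_sequence(tpl, _sample_member(tpl, rng))


def make_planted_genomes(
    library: ModelLibrary,
    n_genomes: int,
    genome_length: int = 50_000,
    gc: float = 0.5,
    seed: int = 0,
) -> list[PlantedGenome]:
    """One descriptor-consistent plant per genome; subfamilies round-robin,
    strands alternating (half the plants on the minus strand)."""
    subs = library.subfamilies()
    genomes = []
    for k in range(n_genomes):
        g_seed = seed * 1_000_003 % (2**31 - 1) + k
        rng = np.random.default_rng(g_seed)
        sub = subs[k % len(subs)]
        insert = sample_member(library[sub], rng)
        bg = random_background(genome_length, gc, g_seed)
        bg = SequenceRecord(id=f"genome{k}", residues=bg.residues)
        pos = int(rng.integers(1000, genome_length - len(insert) - 1000))
        strand = "+" if k % 2 == 0 else "-"
        genome = plant(bg, insert, pos, strand, sub)
        genome.gc = gc
        genome.seed = g_seed
        genomes.append(genome)
    return genomes
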