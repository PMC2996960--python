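"""Downstream analyses over gene calls.

Deduplication to unique genes, per-subfamily tallies, GC-content summaries,
nearest-homolog assignment by local alignment with Karlin-Altschul-style
E-values, and the rank correlation between gene size and genome size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy import optimize, stats

from .descriptor_engine import SUBFAMILIES
from .io_formats import SequenceRecord

__all__ = [
    "UniqueGeneSet",
    "HomologAssignment",
    "CorrelationResult",
    "AlignerConfig",
    "dedup",
    "gc_content",
    "assign_homolog",
    "subfamily_summary",
    "size_correlation",
]


@dataclass
class UniqueGeneSet:
    """Representative calls after exact-sequence deduplication."""

    representatives: list
    multiplicity: dict  # representative index -> member count

    @property
    def total(self) -> int:
        return sum(self.multiplicity.values())


def dedup(calls: Sequence) -> UniqueGeneSet:
    """Group calls by exact sequence identity (strand-normalized).

    Call sequences are stored in transcript orientation, so a plus-strand
    gene and its minus-strand reverse-complement twin collapse naturally.
    The representative is the first call in input order; idempotent.
    """
    reps: list = []
    index: dict[str, int] = {}
    multiplicity: dict[int, int] = {}
    for call in calls:
        key = call.sequence
        if key in index:
            multiplicity[index[key]] += 1
        else:
            index[key] = len(reps)
            multiplicity[len(reps)] = 1
            reps.append(call)
    return UniqueGeneSet(representatives=reps, multiplicity=multiplicity)


def gc_content(residues: str) -> float:
    """(G+C) / (length - N count); undefined (error) for all-N input."""
    if not residues:
        raise ValueError("empty sequence")
    n_count = residues.count("N")
    denom = len(residues) - n_count
    if denom == 0:
        raise ValueError("gc_content undefined for all-N sequence")
    return (residues.count("G") + residues.count("C")) / denom


# -- homolog assignment --------------------------------------------------------


@dataclass(frozen=True)
class AlignerConfig:
    """Local-alignment scoring for the built-in homology search."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -10.0
    gap_extend: float = -1.0
    K: float = 0.1  # Karlin-Altschul prefactor


def _ungapped_lambda(cfg: AlignerConfig) -> float:
    """Karlin-Altschul lambda for the match/mismatch scores under uniform
    base composition: the root of sum_ij p_i p_j exp(lambda s_ij) = 1."""

    def f(lam: float) -> float:
        return 0.25 * np.exp(lam * cfg.match) + 0.75 * np.exp(lam * cfg.mismatch) - 1.0

    return optimize.brentq(f, 1e-6, 10.0)


@dataclass
class HomologAssignment:
    """Closest-homolog call for one query against a reference set."""

    query_id: str
    hit_ids: list
    level: str            # "species" | "genus" | "none"
    best_score: float
    best_evalue: float
    multi_genus: bool = False


def assign_homolog(
    query,
    references: Sequence[tuple],
    evalue_cutoff: float = 1e-50,
    config: AlignerConfig = AlignerConfig(),
) -> HomologAssignment:
    """Assign a query gene to its nearest reference homolog(s).

    ``references`` is a sequence of (SequenceRecord, species, genus).
    Every reference is locally aligned (match +5, mismatch -4, gap open
    -10, extend -1 by default); the E-value is Karlin-Altschul style,
    ``K * m * n * exp(-lambda * S)`` with m the query length and n the total
    reference length.  Exactly one passing reference gives a species-level
    assignment; several passing references from one genus give genus level;
    spanning genera gives none with a ``multi_genus`` flag.
    """
    if not references:
        raise ValueError("references must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = config.match
    aligner.mismatch_score = config.mismatch
    aligner.open_gap_score = config.gap_open
    aligner.extend_gap_score = config.gap_extend
    lam = _ungapped_lambda(config)
    qseq = query.sequence if hasattr(query, "sequence") else query.residues
    m = len(qseq)
    n_total = sum(len(ref.residues) for ref, _, _ in references)

    passing: list[tuple[str, str, float, float]] = []
    best_score, best_ev = float("-inf"), float("inf")
    for ref, species, genus in references:
        score = float(aligner.score(qseq, ref.residues))
        ev = config.K * m * n_total * float(np.exp(-lam * score))
        if score > best_score:
            best_score, best_ev = score, ev
        if ev < evalue_cutoff:
            passing.append((ref.id, genus, score, ev))

    qid = getattr(query, "seq_id", None) or getattr(query, "id", "query")
    if not passing:
        return HomologAssignment(qid, [], "none", best_score, best_ev)
    if len(passing) == 1:
        return HomologAssignment(
            qid, [passing[0][0]], "species", best_score, best_ev
        )
    genera = {g for _, g, _, _ in passing}
    if len(genera) == 1:
        return HomologAssignment(
            qid, [p[0] for p in passing], "genus", best_score, best_ev
        )
    return HomologAssignment(
        qid, [p[0] for p in passing], "none", best_score, best_ev, multi_genus=True
    )


# -- summaries ----------------------------------------------------------------


def subfamily_summary(unique: UniqueGeneSet) -> pd.Series:
    """Representative counts per subfamily (all seven subfamilies listed)."""
    counts = {sub: 0 for sub in SUBFAMILIES}
    for rep in unique.representatives:
        counts[rep.subfamily] = counts.get(rep.subfamily, 0) + 1
    return pd.Series(counts, name="n_genes")


def gc_summary(sequences_by_label: dict) -> pd.DataFrame:
    """Per-dataset GC statistics: n, median and quartiles."""
    rows = []
    for label, seqs in sequences_by_label.items():
        vals = np.array([gc_content(s) for s in seqs])
        rows.append(
            {
                "dataset": label,
                "n": len(vals),
                "gc_q1": float(np.percentile(vals, 25)),
                "gc_median": float(np.median(vals)),
                "gc_q3": float(np.percentile(vals, 75)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CorrelationResult:
    """Spearman rank correlation of gene size vs genome size for one group."""

    subfamily: str
    rho: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0 and not np.isnan(self.rho):
            raise ValueError("|rho| must be <= 1")


def size_correlation(pairs_by_subfamily: dict) -> list:
    """Spearman rho per subfamily over (gene length, genome length) pairs.

    Groups with fewer than 3 pairs are skipped with a warning.
    """
    import warnings

    out = []
    for sub in sorted(pairs_by_subfamily):
        pairs = pairs_by_subfamily[sub]
        if len(pairs) < 3:
            warnings.warn(f"subfamily {sub}: fewer than 3 pairs, skipped")
            continue
        gene, genome = zip(*pairs)
        rho = float(stats.spearmanr(gene, genome).statistic)
        out.append(CorrelationResult(subfamily=sub, rho=rho, n=len(pairs)))
    return out
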