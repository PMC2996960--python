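# Methods

## The detection problem

RNase P RNA is the catalytic subunit of ribonuclease P, the ribozyme that
removes 5' leaders from pre-tRNAs.  Its gene (*rnpB* in bacteria) is 250–550
nt long, present in nearly every genome, and structurally conserved — up to
19 stems P1–P19, five conserved regions CR-I–CR-V, and the long-range P4
pseudoknot formed by CR-I/CR-V — yet poorly conserved in primary sequence.
That combination defeats BLAST-style prefilters and makes a single covariance
model (CM) search over a large genome expensive.  `rnpscan` implements the
classic two-stage answer: a fast structural *descriptor model* (DM) acts as a
filter, and a profile-SCFG covariance model validates each candidate and
refines its boundaries.  Models are organized by structural subfamily
(arcA, arcM, bacA, bacB, nucA, fugA, fugB); subfamilies with high internal
variation carry two descriptor variants, a tight "selective" one and a
relaxed "general" fallback.

## Descriptor models

A DM is an ordered topology of elements:

* **single-strand elements** — fixed IUPAC symbols mixed with run tokens
  `N(min,max)` (arbitrary residues, variable length), with a per-element
  *mismatch budget* that applies to the fixed symbols only;
* **helix elements** — two equal-length strands written 5'→3', whose residues
  must satisfy their IUPAC symbols exactly and whose cross-strand pairing
  violations (pair not in `{AU, UA, GC, CG, GU, UG}` by default) are counted
  against a *mispair budget*.

Matching is a depth-first walk over the topology anchored at each position:
run tokens try shorter lengths first and the first complete match per anchor
wins, so output is deterministic.  Helix labels may cross
(`s1 h1 s2 h2 s3 h1' s4 h2' s5`), which expresses pseudoknots such as P4 —
something the context-free CM cannot represent.  `N` in the subject is
treated conservatively: it satisfies any single-strand symbol for free but
always counts as a mispair inside a helix, so assembly gaps cannot
manufacture helices.  The scanner is checked against a brute-force
enumerator (every anchor, every run-length combination) on ≥1000 random
model/sequence cases.

Descriptor construction follows the column-consensus rule: each alignment
column is summarized as the unique IUPAC code covering *every* base observed
in it, or as the gap character as soon as one gap appears.  Which columns
become descriptor elements is a curator decision supplied as a region table
(0-based half-open column ranges); the package reports per-column entropy as
an aid but deliberately does not automate region selection.  Stretches
between selected regions become run tokens bounded by the min/max ungapped
stretch lengths observed across training rows, widened by a configurable
slack (default 0) — the knob that trades false-positive rate against
sensitivity.

## The covariance model

`cm_lite` is a simplified profile SCFG, not an Infernal reimplementation.
From a structural alignment, columns with gap fraction below a threshold
(default 0.5) become match columns; paired match columns (nested tier only —
pseudoknot tiers are dropped, an inherent context-free limitation) become
MATP nodes with 16-entry log-odds tables, unpaired ones MATL nodes with
4-entry tables:

    e = log2( (count + pc) / (total + k·pc) / background ),

with background 1/4 (singles) or 1/16 (pairs), k = 4 or 16, and pseudocount
`pc > 0`.  Multi-stem structures introduce BIF nodes; consuming intervals
left-first makes MATR nodes unnecessary.  There are no learned transitions:
insertions and deletions are charged fixed affine penalties (insert open −3,
extend −1; delete open −3, extend −1 bits; configurable), and insert states
emit at background (0 bits).  A structure pair joining a match and a
gap-majority column is demoted to unpaired with a warning.  Subject `N`
residues emit 0 bits (background-neutral).

Scoring is CYK over (state, subsequence) with states laid out per node in
the Infernal manner (MP/ML/D/IL/IR plus S/B/E bookkeeping states); the
kernel is a numba-compiled float32 dynamic program, O(states·L²) plus
O(L³) per bifurcation.  Two modes:

* **global** — whole model against the whole input (used by the parse-oracle
  tests, which compare it to exhaustive enumeration for M ≤ 8);
* **local** — whole model, free subject flanks: flanking residues cost
  nothing and the matched span excludes them.  Model truncation is *not*
  supported; the DM has already localized the candidate, so "local" only
  needs to find the gene inside a window.  This free-flank mode is what the
  cascade uses both for validation and for boundary refinement — aligning
  the full model across a 450 nt extended window under strict global rules
  would charge hundreds of insert bits to the flanks and destroy both the
  score and the boundary estimate.

Ties in the local-mode span (scores within 1e-6) break to the smallest,
leftmost span, keeping output deterministic under float32 rounding.

## E-values

Significance is calibrated per model on dinucleotide-shuffled decoys.  The
shuffler is the Euler-path construction: the sequence is a walk on the
digraph whose edges are its dinucleotides; sampling a random final-exit edge
per vertex that forms an arborescence toward the last symbol, shuffling the
remaining edge lists, and re-walking yields a sequence with *exactly* the
original dinucleotide counts, deterministically per seed.  Decoy windows are
2·M nt (matching the scan geometry); their local scores are fitted with a
Gumbel by maximum likelihood (method of moments on non-convergence), giving
λ (1/bits) and μ (bits).  Then

    E(s) = W · (1 − exp(−exp(−λ(s − μ)))),   W = strands · search_space / M,

with search space equal to the scanned record length (record-local E-values,
matching per-organism reporting).  E is strictly decreasing in s and linear
in W.  Because this calibration is not Infernal's, absolute E-values are not
comparable to Infernal's; the default acceptance threshold E ≤ 1e-10 plays
the same role in the pipeline, and λ recovery is verified on simulated
Gumbel scores (within 15% at n = 500).

## The cascade

Per record and subfamily, *selective to general, local to global*:

1. the selective DM (if the subfamily has one) scans both strands;
2. each hit window is scored with the free-flank CM; hits with
   E ≤ threshold are *validated*;
3. if the selective stage produced **zero validated hits**, the general DM
   runs and its hits are validated the same way — a definition chosen so a
   spurious selective match cannot mask a real gene, since validation sits
   downstream of both stages;
4. every validated hit is extended 150 nt at the 5' end and 300 nt at the
   3' end (transcript orientation: on the minus strand the 5' extension
   grows the forward-coordinate end), clipped to the record;
5. the extended window is re-aligned with the whole model (free flanks);
   the matched span becomes the reported gene, the structure string is
   projected from MATP/MATL usage (deleted columns omitted, inserted
   residues unpaired), and the E-value must again reach the threshold.

Calls overlapping on the same strand are resolved to the lowest E-value
(ties: higher score, then lexicographic subfamily).  Minus-strand candidates
are scored on the reverse complement and reported in forward coordinates
with transcript-oriented sequence and structure.  A stage log records which
stages ran, making the fallback contract testable.  Sub-threshold refined
calls can be emitted with a `low_confidence` flag under `report_partials`
(off by default).

**CM-only mode** slides 2·M windows at 50% overlap (so any gene of ≤ M
consensus length lies wholly inside some window), merges overlapping
passing windows, and refines each merged window as above.  It needs no
descriptor and rescues genes whose local quirks — an unusual bulge, a point
mutation in a descriptor block — defeat the pattern filter, at roughly two
orders of magnitude more CM work.

## Post-processing

* **dedup** — exact-sequence identity on transcript-oriented sequences
  (so strand is normalized automatically); the representative is the first
  call in input order.  The multiplicities always sum to the input count.
* **GC content** — (G+C)/(length − N), with quartile summaries per dataset.
* **homolog assignment** — a built-in local aligner (Biopython
  `PairwiseAligner`; match +5, mismatch −4, gap open −10, extend −1) against
  a labelled reference set; E = K·m·n·exp(−λS) with λ solved from the score
  matrix under uniform composition and K = 0.1.  One passing reference at
  E < 1e-50 gives a species-level assignment, several from one genus give
  genus level, several spanning genera give none with a `multi_genus` flag.
* **size correlation** — Spearman's ρ (average ranks on ties) of gene
  length against genome length per subfamily; groups under 3 pairs are
  skipped with a warning.

## Synthetic fixtures

The generator emulates the *structure* of the detection problem, not RNase P
sequence evolution.  A toy family template is a nested architecture of
helices (pair identities drawn once per template), conserved boxes, and
variable-length spacers; members are sampled with at most one substitution
per box and fixed helices except one designated covarying column that
alternates between G–C and U–A.  That column is the hinge of the fixture
design: its consensus symbols (K/M) admit the cross combinations G–A and
U–C, which satisfy the symbols but violate pairing — so an "aberrant"
member carrying exactly one such mispair fails the selective DM (mispair
budget 0) yet matches the general one (budget 1), exercising the fallback
exactly once.  Alignments are exact by construction (fixed-width elements,
spacers left-justified and gap-padded), so descriptors, CMs, and truth
coordinates all derive from the same ground truth.

Toy consensus lengths are ~130–145 nt — large enough that a true gene
carries ~200 bits against the model (clearing E ≤ 1e-10 in a 50 kb genome
with orders of magnitude to spare across calibration seeds) and small
enough that scanning a 50 kb genome takes about a second.  Planting
*replaces* a background span rather than inserting, keeping truth
coordinates stable; minus-strand plants insert the reverse complement.
Backgrounds are i.i.d. with configurable GC.  What passing these fixtures
does **not** show: robustness to the sequence divergence, length range
(250–550 nt), and genomic context of real *rnpB* genes, nor parity with
expert-curated production descriptors — the builders are general, but the
shipped toy models are fixtures, not a curated library.

## Numerical and design notes

* Internal alphabet is DNA (U→T on input, one conversion point); pairing
  logic treats T as U.  Internal coordinates are 0-based half-open; all
  emitted coordinates are 1-based inclusive with a strand column.
* The float32 CYK kernel introduces ≤ ~1e-3 bits of rounding at toy scale;
  oracle comparisons use that tolerance.
* Descriptor scanning uses an exact anchor prefilter (a regex over the
  leading helix strand or a zero-budget leading pattern) only where the
  leading element admits no budget, so it can never lose a match.
* Problem sizes in the test and acceptance runs — 100 genomes of 50 kb, 300
  calibration decoys, 1000 matcher-oracle and 200 parse-oracle cases — were
  chosen so the full property suite completes on a single CPU at desk scale.
* Helices in the descriptor dialect are fixed-length; helix length variation
  must be expressed by flanking run tokens.  This keeps the pairing check
  linear in helix length but is a known divergence from richer descriptor
  languages.
* `rnabob`-style relational elements, Infernal file compatibility, Inside
  (sum) scoring, and banded DP are out of scope.
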