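"""A simplified covariance model (profile SCFG) for RNA family scoring.

The model is built from a structural alignment: columns whose gap fraction
stays below a threshold become match columns; paired match columns (nested
tier of the consensus structure — pseudoknot tiers are dropped, a
context-free limitation) become MATP nodes emitting base pairs, unpaired
ones MATL nodes.  Multi-stem structures introduce BIF nodes.  There is no
MATR node and no learned transition table: insertions and deletions are
charged fixed affine penalties, which keeps the CYK dynamic program small
enough to check against exhaustive parse enumeration.

Scoring modes:

* :func:`score_global` aligns the whole model to the whole input.
* :func:`score_local` aligns the whole model but leaves any prefix/suffix
  of the subject free (score 0 per flanking residue); the matched span
  excludes the free flanks.  Model truncation is not supported — the
  candidate window is already localized by the descriptor filter.

Significance comes from a Gumbel fit to the local scores of
dinucleotide-shuffled decoys: ``E = W * (1 - exp(-exp(-lambda (s - mu))))``
with ``W = strands * search_space / M`` windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
from numba import njit
from scipy import stats

from .io_formats import (
    FormatError,
    StructuredAlignment,
    nested_pairs,
)

__all__ = [
    "GapPenalties",
    "EVDParams",
    "ScoredAlignment",
    "CovarianceModel",
    "CalibrationError",
    "build_cm",
    "score_global",
    "score_local",
    "dinucleotide_shuffle",
    "calibrate",
    "fit_gumbel",
    "evalue",
    "write_cm",
    "read_cm",
]

NEG = -1.0e30

# state type codes shared with the numba kernel
ST_NOEMIT = 0  # S, D
ST_LEFT = 1    # ML, IL
ST_RIGHT = 2   # IR
ST_PAIR = 3    # MP
ST_BIF = 4
ST_END = 5

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class CalibrationError(RuntimeError):
    """Raised when the decoy score distribution cannot support a Gumbel fit."""


@dataclass(frozen=True)
class GapPenalties:
    """Fixed affine gap costs in bits (all <= 0)."""

    insert_open: float = -3.0
    insert_extend: float = -1.0
    delete_open: float = -3.0
    delete_extend: float = -1.0


@dataclass(frozen=True)
class EVDParams:
    """Gumbel parameters fitted to decoy scores (lambda in 1/bits, mu in bits)."""

    lam: float
    mu: float
    n_decoys: int
    decoy_length: int
    seed: int

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")


@dataclass
class ScoredAlignment:
    """A CYK parse result: bit score, matched subject span, structure."""

    score: float
    start: int
    end: int
    structure: str
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if len(self.structure) != self.end - self.start:
            raise ValueError("structure length != matched span length")


@dataclass
class _Node:
    kind: str            # ROOT MATP MATL BIF BEGL BEGR END
    col1: int = -1       # match-column indices (model coordinates)
    col2: int = -1
    emission: Optional[np.ndarray] = None  # 4 (MATL) or 16 (MATP) log-odds
    bif_right: int = -1  # node index of BEGR subtree head (BIF only)


@dataclass
class CovarianceModel:
    """A built (and optionally calibrated) simplified covariance model."""

    name: str
    subfamily: str
    nodes: list
    consensus_structure: str          # over match columns, nested tier
    consensus_residues: str           # majority residue per match column
    gaps: GapPenalties = field(default_factory=GapPenalties)
    evd: Optional[EVDParams] = None

    # compiled state machine (built lazily, not serialized)
    _states: Optional[dict] = field(default=None, repr=False, compare=False)

    @property
    def M(self) -> int:
        return len(self.consensus_structure)

    def states(self) -> dict:
        if self._states is None:
            self._states = _compile_states(self)
        return self._states


# -- model construction -------------------------------------------------------

def _guide_nodes(pairmap: dict, lo: int, hi: int) -> list:
    """Flatten the guide tree for match columns [lo, hi] in preorder.

    Left-first consumption: an unpaired leftmost column becomes MATL; a
    column paired with the rightmost becomes MATP; a pair closing inside
    the interval forces a BIF.  This needs no MATR node.
    """
    nodes: list[_Node] = []
    while True:
        if lo > hi:
            nodes.append(_Node("END"))
            return nodes
        j = pairmap.get(lo, -1)
        if j < 0:
            nodes.append(_Node("MATL", lo))
            lo += 1
        elif j == hi:
            nodes.append(_Node("MATP", lo, hi))
            lo += 1
            hi -= 1
        else:
            bif = _Node("BIF")
            nodes.append(bif)
            nodes.append(_Node("BEGL"))
            left = _guide_nodes(pairmap, lo, j)
            nodes.extend(left)
            bif.bif_right = -2  # fixed up by caller via index arithmetic
            right_head = len(nodes)
            nodes.append(_Node("BEGR"))
            nodes.extend(_guide_nodes(pairmap, j + 1, hi))
            # record BEGR head relative to this sublist; caller offsets
            bif.bif_right = right_head
            return nodes


def _build_guide(pairmap: dict, m: int) -> list:
    nodes = [_Node("ROOT")] + _guide_nodes(pairmap, 0, m - 1)
    # fix up BIF right-child indices: _guide_nodes recorded them relative to
    # the sublist it returned; recompute absolutely by re-walking.
    _fix_bif(nodes)
    return nodes


def _fix_bif(nodes: list) -> None:
    """Recompute absolute BEGR head indices for every BIF node."""

    def subtree_end(i: int) -> int:
        # returns index one past the subtree rooted at nodes[i]
        kind = nodes[i].kind
        if kind == "END":
            return i + 1
        if kind == "BIF":
            left_end = subtree_end(i + 1)  # BEGL subtree
            nodes[i].bif_right = left_end
            return subtree_end(left_end)   # BEGR subtree
        if kind in ("BEGL", "BEGR"):
            return subtree_end(i + 1)
        return subtree_end(i + 1)  # ROOT, MATL, MATP: chain

    subtree_end(0)


def build_cm(
    aln: StructuredAlignment,
    gap_threshold: float = 0.5,
    pseudocount: float = 1.0,
    name: str = "cm",
    subfamily: str = "bacA",
    gaps: GapPenalties = GapPenalties(),
) -> CovarianceModel:
    """Build a simplified covariance model from a structural alignment.

    Columns with gap fraction < ``gap_threshold`` are match columns.
    Emissions are ``log2((count + pc) / (total + k*pc) / background)`` with
    background 1/4 for singles, 1/16 for pairs (k = 4 or 16).  A structure
    pair joining a match column with a gap-majority column is demoted to
    MATL with a warning.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    nrows = len(aln.rows)
    if nrows == 0:
        raise FormatError("alignment has no rows")
    ncols = aln.columns

    gap_frac = []
    for j in range(ncols):
        col = aln.column(j)
        gap_frac.append(sum(1 for c in col if c in ("-", ".")) / nrows)
    is_match = [f < gap_threshold for f in gap_frac]
    match_cols = [j for j in range(ncols) if is_match[j]]
    if not match_cols:
        raise FormatError("no match columns at this gap threshold")
    col_to_m = {j: k for k, j in enumerate(match_cols)}

    pairmap: dict[int, int] = {}
    for a, b in nested_pairs(aln.consensus_structure):
        if is_match[a] and is_match[b]:
            pairmap[col_to_m[a]] = col_to_m[b]
        elif is_match[a] != is_match[b]:
            warnings.warn(
                f"structure pair ({a},{b}) joins a match and a gap-majority "
                "column; demoted to unpaired"
            )

    m = len(match_cols)
    structure = []
    for k in range(m):
        if k in pairmap:
            structure.append("<")
        elif k in {v for v in pairmap.values()}:
            structure.append(">")
        else:
            structure.append(".")
    structure = "".join(structure)

    nodes = _build_guide(pairmap, m)

    # emission counts
    consensus_residues = []
    for k in range(m):
        col = aln.column(match_cols[k])
        counts = {b: 0 for b in "ACGT"}
        for c in col:
            if c in counts:
                counts[c] += 1
        consensus_residues.append(max("ACGT", key=lambda b: (counts[b], b)))
    consensus_residues = "".join(consensus_residues)

    for node in nodes:
        if node.kind == "MATL":
            col = aln.column(match_cols[node.col1])
            counts = np.zeros(4)
            for c in col:
                if c in _BASE_CODE:
                    counts[_BASE_CODE[c]] += 1
            total = counts.sum()
            probs = (counts + pseudocount) / (total + 4 * pseudocount)
            node.emission = np.log2(probs / 0.25)
        elif node.kind == "MATP":
            c1 = aln.column(match_cols[node.col1])
            c2 = aln.column(match_cols[node.col2])
            counts = np.zeros(16)
            for x, y in zip(c1, c2):
                if x in _BASE_CODE and y in _BASE_CODE:
                    counts[_BASE_CODE[x] * 4 + _BASE_CODE[y]] += 1
            total = counts.sum()
            probs = (counts + pseudocount) / (total + 16 * pseudocount)
            node.emission = np.log2(probs / (1.0 / 16.0))

    return CovarianceModel(
        name=name,
        subfamily=subfamily,
        nodes=nodes,
        consensus_structure=structure,
        consensus_residues=consensus_residues,
        gaps=gaps,
    )


# -- state machine compilation ------------------------------------------------

def _compile_states(cm: CovarianceModel) -> dict:
    """Expand guide nodes into a CYK-ready state table.

    States per node: ROOT -> S, IL, IR; MATL -> ML, D, IL; MATP -> MP, D,
    IL, IR; BIF -> B; BEGL/BEGR -> S; END -> E.  Insert states self-loop
    with the extend cost and are entered with the open cost; delete states
    chain with open/extend; all other transitions are free.  Insert
    emissions score 0 (background).
    """
    g = cm.gaps
    nodes = cm.nodes
    n_nodes = len(nodes)

    # state bookkeeping
    stype: list[int] = []
    srole: list[str] = []
    snode: list[int] = []
    eml: list[np.ndarray] = []
    emp: list[np.ndarray] = []

    node_states: list[dict] = [dict() for _ in range(n_nodes)]

    def add_state(node_i: int, role: str, t: int) -> int:
        idx = len(stype)
        stype.append(t)
        srole.append(role)
        snode.append(node_i)
        e4 = np.zeros(4)
        e16 = np.zeros(16)
        node = nodes[node_i]
        if role == "ML":
            e4 = node.emission
        elif role == "MP":
            e16 = node.emission
        eml.append(np.asarray(e4, dtype=np.float64))
        emp.append(np.asarray(e16, dtype=np.float64))
        node_states[node_i][role] = idx
        return idx

    for i, node in enumerate(nodes):
        if node.kind == "ROOT":
            add_state(i, "S", ST_NOEMIT)
            add_state(i, "IL", ST_LEFT)
            add_state(i, "IR", ST_RIGHT)
        elif node.kind == "MATL":
            add_state(i, "ML", ST_LEFT)
            add_state(i, "D", ST_NOEMIT)
            add_state(i, "IL", ST_LEFT)
        elif node.kind == "MATP":
            add_state(i, "MP", ST_PAIR)
            add_state(i, "D", ST_NOEMIT)
            add_state(i, "IL", ST_LEFT)
            add_state(i, "IR", ST_RIGHT)
        elif node.kind == "BIF":
            add_state(i, "B", ST_BIF)
        elif node.kind in ("BEGL", "BEGR"):
            add_state(i, "S", ST_NOEMIT)
        elif node.kind == "END":
            add_state(i, "E", ST_END)
        else:  # pragma: no cover
            raise AssertionError(node.kind)

    def main_states(node_i: int) -> list[int]:
        kind = nodes[node_i].kind
        ns = node_states[node_i]
        if kind == "MATL":
            return [ns["ML"], ns["D"]]
        if kind == "MATP":
            return [ns["MP"], ns["D"]]
        if kind == "BIF":
            return [ns["B"]]
        if kind == "END":
            return [ns["E"]]
        if kind in ("BEGL", "BEGR"):
            return [ns["S"]]
        raise AssertionError(kind)

    children: list[list[tuple[int, float]]] = [[] for _ in stype]
    bifl = np.full(len(stype), -1, dtype=np.int64)
    bifr = np.full(len(stype), -1, dtype=np.int64)

    def tcost(parent: int, child: int) -> float:
        pr, cr = srole[parent], srole[child]
        if cr in ("IL", "IR"):
            if pr == cr and snode[parent] == snode[child]:
                return g.insert_extend
            return g.insert_open
        if cr == "D":
            return g.delete_extend if pr == "D" else g.delete_open
        return 0.0

    for i, node in enumerate(nodes):
        ns = node_states[i]
        if node.kind == "BIF":
            b = ns["B"]
            bifl[b] = node_states[i + 1]["S"]          # BEGL head
            bifr[b] = node_states[node.bif_right]["S"]  # BEGR head
            continue
        if node.kind == "END":
            continue
        nxt = i + 1  # chain successor (BEGL/BEGR head their own chains)
        nxt_main = main_states(nxt)
        if node.kind == "ROOT":
            order = [ns["S"], ns["IL"], ns["IR"]]
            conn = {
                ns["S"]: [ns["IL"], ns["IR"]] + nxt_main,
                ns["IL"]: [ns["IL"], ns["IR"]] + nxt_main,
                ns["IR"]: [ns["IR"]] + nxt_main,
            }
        elif node.kind == "MATL":
            conn = {
                ns["ML"]: [ns["IL"]] + nxt_main,
                ns["D"]: [ns["IL"]] + nxt_main,
                ns["IL"]: [ns["IL"]] + nxt_main,
            }
        elif node.kind == "MATP":
            conn = {
                ns["MP"]: [ns["IL"], ns["IR"]] + nxt_main,
                ns["D"]: [ns["IL"], ns["IR"]] + nxt_main,
                ns["IL"]: [ns["IL"], ns["IR"]] + nxt_main,
                ns["IR"]: [ns["IR"]] + nxt_main,
            }
        else:  # BEGL / BEGR
            conn = {ns["S"]: nxt_main}
        for parent, childs in conn.items():
            for c in childs:
                children[parent].append((c, tcost(parent, c)))

    coff = np.zeros(len(stype), dtype=np.int64)
    cnum = np.zeros(len(stype), dtype=np.int64)
    cstate: list[int] = []
    ccost: list[float] = []
    for s, childs in enumerate(children):
        coff[s] = len(cstate)
        cnum[s] = len(childs)
        for c, t in childs:
            cstate.append(c)
            ccost.append(t)

    return {
        "stype": np.asarray(stype, dtype=np.int64),
        "srole": srole,
        "snode": np.asarray(snode, dtype=np.int64),
        "coff": coff,
        "cnum": cnum,
        "cstate": np.asarray(cstate, dtype=np.int64),
        "ccost": np.asarray(ccost, dtype=np.float64),
        "bifl": bifl,
        "bifr": bifr,
        "eml": np.vstack(eml),
        "emp": np.vstack(emp),
    }


# -- CYK kernel ---------------------------------------------------------------

@njit(cache=False)
def _cyk_fill(stype, coff, cnum, cstate, ccost, bifl, bifr, eml, emp, seqcode):
    L = seqcode.shape[0]
    ns = stype.shape[0]
    M = np.full((ns, L + 1, L + 1), np.float32(NEG), dtype=np.float32)
    for v in range(ns - 1, -1, -1):
        t = stype[v]
        if t == 5:  # END
            for i in range(L + 1):
                M[v, i, i] = 0.0
        elif t == 4:  # BIF
            l = bifl[v]
            r = bifr[v]
            for i in range(L, -1, -1):
                for j in range(i, L + 1):
                    best = np.float32(NEG)
                    for k in range(i, j + 1):
                        s = M[l, i, k] + M[r, k, j]
                        if s > best:
                            best = s
                    M[v, i, j] = best
        else:
            c0 = coff[v]
            nc = cnum[v]
            for i in range(L, -1, -1):
                for j in range(i, L + 1):
                    ii = i
                    jj = j
                    e = np.float32(0.0)
                    ok = True
                    if t == 1:  # left emit
                        if i >= j:
                            ok = False
                        else:
                            ii = i + 1
                            c = seqcode[i]
                            if c < 4:
                                e = np.float32(eml[v, c])
                    elif t == 2:  # right emit
                        if i >= j:
                            ok = False
                        else:
                            jj = j - 1
                            c = seqcode[j - 1]
                            if c < 4:
                                e = np.float32(eml[v, c])
                    elif t == 3:  # pair emit
                        if j - i < 2:
                            ok = False
                        else:
                            ii = i + 1
                            jj = j - 1
                            a = seqcode[i]
                            b = seqcode[j - 1]
                            if a < 4 and b < 4:
                                e = np.float32(emp[v, a * 4 + b])
                    if not ok:
                        continue
                    best = np.float32(NEG)
                    for q in range(c0, c0 + nc):
                        s = np.float32(ccost[q]) + M[cstate[q], ii, jj]
                        if s > best:
                            best = s
                    if best > np.float32(NEG) / 2:
                        M[v, i, j] = e + best
    return M


def _encode(residues: str) -> np.ndarray:
    return np.array([_BASE_CODE.get(c, 4) for c in residues], dtype=np.int64)


def _fill(cm: CovarianceModel, residues: str) -> np.ndarray:
    st = cm.states()
    return _cyk_fill(
        st["stype"], st["coff"], st["cnum"], st["cstate"], st["ccost"],
        st["bifl"], st["bifr"], st["eml"], st["emp"], _encode(residues),
    )


def _traceback(cm: CovarianceModel, residues: str, M: np.ndarray,
               i0: int, j0: int) -> str:
    """Recover the structure string over subject positions [i0, j0)."""
    st = cm.states()
    stype = st["stype"]
    coff, cnum, cstate, ccost = st["coff"], st["cnum"], st["cstate"], st["ccost"]
    bifl, bifr = st["bifl"], st["bifr"]
    srole = st["srole"]
    chars = ["."] * (j0 - i0)
    stack = [(0, i0, j0)]
    while stack:
        v, i, j = stack.pop()
        t = stype[v]
        if t == ST_END:
            continue
        if t == ST_BIF:
            l, r = bifl[v], bifr[v]
            best, bk = None, i
            for k in range(i, j + 1):
                s = M[l, i, k] + M[r, k, j]
                if best is None or s > best:
                    best, bk = s, k
            stack.append((l, i, bk))
            stack.append((r, bk, j))
            continue
        ii, jj = i, j
        if t == ST_LEFT:
            ii = i + 1
        elif t == ST_RIGHT:
            jj = j - 1
        elif t == ST_PAIR:
            ii, jj = i + 1, j - 1
        if srole[v] == "MP":
            chars[i - i0] = "<"
            chars[j - 1 - i0] = ">"
        # choose best child
        best, bc, bcost = None, -1, 0.0
        for q in range(coff[v], coff[v] + cnum[v]):
            s = ccost[q] + M[cstate[q], ii, jj]
            if best is None or s > best:
                best, bc = s, cstate[q]
        stack.append((bc, ii, jj))
    return "".join(chars)


def score_global(cm: CovarianceModel, residues: str,
                 min_len_frac: float = 0.5) -> ScoredAlignment:
    """Best whole-model/whole-input parse (CYK maximum score, bits).

    Inputs shorter than ``min_len_frac * M`` still score (an all-delete
    parse always exists) but the result carries a ``short_input`` flag.
    """
    if not residues:
        raise ValueError("residues must be non-empty")
    if cm.M == 0:
        raise ValueError("empty model")
    M = _fill(cm, residues)
    L = len(residues)
    score = float(M[0, 0, L])
    structure = _traceback(cm, residues, M, 0, L)
    flags = frozenset(["short_input"]) if L < min_len_frac * cm.M else frozenset()
    return ScoredAlignment(score=score, start=0, end=L, structure=structure,
                           flags=flags)


def score_local(cm: CovarianceModel, residues: str) -> ScoredAlignment:
    """Whole model, free subject flanks: best parse of any subsequence.

    Flanking residues outside the matched span contribute 0 bits; the
    matched span excludes them.
    """
    if not residues:
        raise ValueError("residues must be non-empty")
    if cm.M == 0:
        raise ValueError("empty model")
    M = _fill(cm, residues)
    L = len(residues)
    root = np.asarray(M[0], dtype=np.float64)
    iu, ju = np.triu_indices(L + 1)
    vals = root[iu, ju]
    best = float(vals.max())
    # deterministic tie-break among near-maxima: smallest span, then leftmost
    cand = np.where(vals >= best - 1e-6)[0]
    order = np.lexsort((iu[cand], ju[cand] - iu[cand]))
    pick = cand[order[0]]
    bi, bj = int(iu[pick]), int(ju[pick])
    structure = _traceback(cm, residues, M, bi, bj)
    return ScoredAlignment(
        score=float(root[bi, bj]), start=bi, end=bj, structure=structure
    )


# -- dinucleotide shuffling ---------------------------------------------------

def dinucleotide_shuffle(residues: str, seed: Union[int, np.random.Generator]) -> str:
    """Uniform shuffle preserving all 16 dinucleotide counts exactly.

    Euler-path construction: the sequence is a walk on the digraph whose
    edges are its dinucleotides; a random final-exit edge per vertex that
    forms an arborescence toward the last symbol guarantees the shuffled
    edge lists still admit a complete walk.  Deterministic given the seed;
    the first and last residues are invariants of the method.
    """
    if len(residues) < 2:
        raise ValueError("need at least 2 residues to shuffle")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    out_edges: dict[str, list[str]] = {}
    for a, b in zip(residues, residues[1:]):
        out_edges.setdefault(a, []).append(b)
    last = residues[-1]
    vertices = sorted(out_edges.keys() | {last})

    if all(len(set(v)) <= 1 for v in out_edges.values()) and len(vertices) <= 1:
        return residues  # single-symbol sequence: unique arrangement

    non_last = [v for v in vertices if v != last and out_edges.get(v)]
    for _ in range(10000):
        final_exit = {v: out_edges[v][rng.integers(len(out_edges[v]))] for v in non_last}
        # check: following final exits from every vertex reaches `last`
        ok = True
        for v in non_last:
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in final_exit:
                    ok = False
                    break
                seen.add(cur)
                cur = final_exit[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover
        raise RuntimeError("could not sample a connecting arborescence")

    shuffled: dict[str, list[str]] = {}
    for v, targets in out_edges.items():
        pool = list(targets)
        if v in final_exit:
            pool.remove(final_exit[v])
        idx = rng.permutation(len(pool))
        lst = [pool[k] for k in idx]
        if v in final_exit:
            lst.append(final_exit[v])
        shuffled[v] = lst

    pos = {v: 0 for v in shuffled}
    out = [residues[0]]
    cur = residues[0]
    for _ in range(len(residues) - 1):
        nxt = shuffled[cur][pos[cur]]
        pos[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


# -- calibration and E-values -------------------------------------------------

DecoySource = Union[str, Callable[[np.random.Generator], str], None]


def calibrate(
    cm: CovarianceModel,
    n_decoys: int,
    decoy_source: DecoySource = None,
    seed: int = 0,
) -> EVDParams:
    """Fit Gumbel (lambda, mu) to local scores of dinucleotide-shuffled decoys.

    Decoy windows are ``2 * M`` nt.  ``decoy_source`` may be a residue
    string (windows are drawn from it, then shuffled), a callable
    ``f(rng) -> residues`` providing windows, or ``None`` for uniform
    random windows.  The fit is maximum likelihood with a
    method-of-moments fallback; the parameters are stored on the model.
    """
    if n_decoys < 50:
        raise ValueError("n_decoys must be >= 50")
    rng = np.random.default_rng(seed)
    wlen = 2 * cm.M
    scores = np.empty(n_decoys)
    for k in range(n_decoys):
        if decoy_source is None:
            window = "".join(rng.choice(list("ACGT"), size=wlen))
        elif callable(decoy_source):
            window = decoy_source(rng)
        else:
            src = decoy_source
            if len(src) < wlen:
                raise ValueError("decoy_source shorter than the decoy window")
            off = int(rng.integers(0, len(src) - wlen + 1))
            window = src[off:off + wlen]
        window = dinucleotide_shuffle(window, rng)
        scores[k] = score_local(cm, window).score

    lam, mu = fit_gumbel(scores)
    params = EVDParams(
        lam=lam, mu=mu, n_decoys=n_decoys, decoy_length=wlen, seed=seed,
    )
    cm.evd = params
    return params


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Gumbel (lambda, mu) by maximum likelihood; method of moments on
    non-convergence.  Raises :class:`CalibrationError` on zero variance."""
    scores = np.asarray(scores, dtype=float)
    if np.std(scores) < 1e-9:
        raise CalibrationError("degenerate (zero-variance) score distribution")
    try:
        loc, scale = stats.gumbel_r.fit(scores)
        if not (np.isfinite(loc) and np.isfinite(scale) and scale > 0):
            raise RuntimeError("non-finite MLE")
    except Exception:
        # method of moments: scale = sqrt(6)*sd/pi, loc = mean - gamma*scale
        scale = np.sqrt(6.0) * np.std(scores, ddof=1) / np.pi
        loc = np.mean(scores) - np.euler_gamma * scale
    return 1.0 / scale, float(loc)


def evalue(
    cm: CovarianceModel,
    score: float,
    search_space: int,
    strands: int = 2,
) -> float:
    """Expected hit count at or above *score* in the searched space.

    ``E = W * (1 - exp(-exp(-lambda (s - mu))))`` with
    ``W = strands * search_space / M`` independent windows.  Strictly
    decreasing in the score; linear in W.
    """
    if cm.evd is None:
        raise ValueError("model is not calibrated")
    W = strands * search_space / cm.M
    x = cm.evd.lam * (score - cm.evd.mu)
    # p = 1 - exp(-exp(-x)), computed stably for large x
    with np.errstate(over="ignore"):
        p = float(-np.expm1(-np.exp(-x)))
    return W * p


# -- plain-text serialization -------------------------------------------------

CM_FORMAT_VERSION = "CMv1"


def write_cm(cm: CovarianceModel, path) -> None:
    """Write the model as a versioned plain-text parameter file."""
    with open(path, "w") as fh:
        fh.write(f"# {CM_FORMAT_VERSION}\n")
        fh.write(f"name: {cm.name}\n")
        fh.write(f"subfamily: {cm.subfamily}\n")
        fh.write(f"structure: {cm.consensus_structure}\n")
        fh.write(f"consensus: {cm.consensus_residues}\n")
        g = cm.gaps
        fh.write(
            f"gap_penalties: {g.insert_open} {g.insert_extend} "
            f"{g.delete_open} {g.delete_extend}\n"
        )
        for node in cm.nodes:
            if node.emission is None:
                fh.write(f"node {node.kind}\n")
            else:
                vals = " ".join(f"{x:.6f}" for x in node.emission)
                fh.write(f"node {node.kind} {node.col1} {node.col2} {vals}\n")
        if cm.evd is not None:
            e = cm.evd
            fh.write(
                f"evd: {e.lam:.8f} {e.mu:.6f} {e.n_decoys} {e.decoy_length} {e.seed}\n"
            )


def read_cm(path) -> CovarianceModel:
    """Read a model written by :func:`write_cm`."""
    headers: dict[str, str] = {}
    node_lines: list[str] = []
    evd = None
    gaps = GapPenalties()
    with open(path) as fh:
        first = fh.readline().strip()
        if first != f"# {CM_FORMAT_VERSION}":
            raise FormatError(f"{path}: not a {CM_FORMAT_VERSION} file")
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("node "):
                node_lines.append(line[5:])
            elif line.startswith("evd:"):
                lam, mu, nd, dl, sd = line[4:].split()
                evd = EVDParams(float(lam), float(mu), int(nd), int(dl), int(sd))
            elif line.startswith("gap_penalties:"):
                io_, ie, do, de = map(float, line[len("gap_penalties:"):].split())
                gaps = GapPenalties(io_, ie, do, de)
            else:
                key, _, val = line.partition(":")
                headers[key.strip()] = val.strip()

    structure = headers.get("structure", "")
    # rebuild the guide tree deterministically from the structure and check
    pairmap = {}
    stack: list[int] = []
    for k, ch in enumerate(structure):
        if ch == "<":
            stack.append(k)
        elif ch == ">":
            pairmap[stack.pop()] = k
    nodes = _build_guide(pairmap, len(structure))
    stored = []
    for line in node_lines:
        parts = line.split()
        if len(parts) == 1:
            stored.append((parts[0], None, -1, -1))
        else:
            kind, c1, c2 = parts[0], int(parts[1]), int(parts[2])
            stored.append((kind, np.array([float(x) for x in parts[3:]]), c1, c2))
    if len(stored) != len(nodes):
        raise FormatError(f"{path}: node count does not match structure")
    for node, (kind, em, c1, c2) in zip(nodes, stored):
        if node.kind != kind:
            raise FormatError(f"{path}: node kind mismatch ({node.kind} vs {kind})")
        if em is not None:
            node.emission = em
    return CovarianceModel(
        name=headers.get("name", "cm"),
        subfamily=headers.get("subfamily", "bacA"),
        nodes=nodes,
        consensus_structure=structure,
        consensus_residues=headers.get("consensus", ""),
        gaps=gaps,
        evd=evd,
    )
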