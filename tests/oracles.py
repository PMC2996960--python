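"""Independent reference implementations used only by the test suite.

These deliberately avoid the production code paths: the descriptor oracle
enumerates every run-length combination with plain itertools, and the parse
oracle evaluates the SCFG by memoized recursion in pure Python (float64),
so agreement with the iterative float32 kernel is meaningful.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

from rnpscan.descriptor_engine import RunToken, SSElement
from rnpscan.io_formats import IUPAC_CODES

NEG_INF = float("-inf")


def brute_match_at(seq: str, pos: int, model):
    """First valid placement anchored at pos, enumerating run lengths
    lexicographically (shortest first, topology order).

    Returns (start, end, element_spans, mismatches, mispairs) or None.
    """
    n = len(seq)
    slots = []
    for lab in model.topology:
        el = model.elements[lab.rstrip("'")]
        if isinstance(el, SSElement):
            for ti, t in enumerate(el.tokens):
                if isinstance(t, RunToken):
                    slots.append((lab, ti, t.min, t.max))

    for combo in itertools.product(*[range(mn, mx + 1) for _, _, mn, mx in slots]):
        runlen = {(lab, ti): L for (lab, ti, _, _), L in zip(slots, combo)}
        p = pos
        spans = {}
        mm_total = 0
        mp_total = 0
        ok = True
        for lab in model.topology:
            base = lab.rstrip("'")
            el = model.elements[base]
            if isinstance(el, SSElement):
                q = p
                e_mm = 0
                for ti, t in enumerate(el.tokens):
                    if isinstance(t, RunToken):
                        L = runlen[(lab, ti)]
                        if q + L > n:
                            ok = False
                            break
                        q += L
                    else:
                        if q >= n:
                            ok = False
                            break
                        ch = seq[q]
                        if not (ch == "N" or ch in IUPAC_CODES[t]):
                            e_mm += 1
                        q += 1
                if not ok or e_mm > el.mismatch_budget:
                    ok = False
                    break
                spans[lab] = (p, q)
                mm_total += e_mm
                p = q
            else:
                L = len(el)
                if p + L > n:
                    ok = False
                    break
                segment = seq[p:p + L]
                strand = el.strand3 if lab.endswith("'") else el.strand5
                for i, ch in enumerate(segment):
                    if ch != "N" and ch not in IUPAC_CODES[strand[i]]:
                        ok = False
                        break
                if not ok:
                    break
                if lab.endswith("'"):
                    o_start, o_end = spans[base]
                    oseg = seq[o_start:o_end]
                    e_mp = sum(
                        1
                        for i in range(L)
                        if oseg[L - 1 - i] == "N"
                        or segment[i] == "N"
                        or (oseg[L - 1 - i], segment[i]) not in el.pair_set
                    )
                    if e_mp > el.mispair_budget:
                        ok = False
                        break
                    mp_total += e_mp
                spans[lab] = (p, p + L)
                p += L
        if ok:
            return (pos, p, spans, mm_total, mp_total)
    return None


def brute_scan(seq: str, model):
    """First-match-per-anchor hits over every anchor of the plus strand."""
    hits = []
    for pos in range(len(seq) + 1):
        h = brute_match_at(seq, pos, model)
        if h is not None:
            hits.append(h)
    return hits


def best_parse_score(cm, residues: str) -> float:
    """Maximum parse score by memoized recursion over the state machine."""
    st = cm.states()
    stype = st["stype"]
    coff, cnum, cstate, ccost = st["coff"], st["cnum"], st["cstate"], st["ccost"]
    bifl, bifr = st["bifl"], st["bifr"]
    eml, emp = st["eml"], st["emp"]
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    seq = [code.get(c, 4) for c in residues]
    L = len(seq)

    @lru_cache(maxsize=None)
    def best(v: int, i: int, j: int) -> float:
        t = stype[v]
        if t == 5:  # END
            return 0.0 if i == j else NEG_INF
        if t == 4:  # BIF
            return max(
                best(bifl[v], i, k) + best(bifr[v], k, j) for k in range(i, j + 1)
            )
        ii, jj = i, j
        e = 0.0
        if t == 1:  # left emit
            if i >= j:
                return NEG_INF
            ii = i + 1
            if seq[i] < 4:
                e = float(eml[v, seq[i]])
        elif t == 2:  # right emit
            if i >= j:
                return NEG_INF
            jj = j - 1
            if seq[j - 1] < 4:
                e = float(eml[v, seq[j - 1]])
        elif t == 3:  # pair emit
            if j - i < 2:
                return NEG_INF
            ii, jj = i + 1, j - 1
            if seq[i] < 4 and seq[j - 1] < 4:
                e = float(emp[v, seq[i] * 4 + seq[j - 1]])
        sub = max(
            float(ccost[q]) + best(int(cstate[q]), ii, jj)
            for q in range(coff[v], coff[v] + cnum[v])
        )
        return e + sub if sub > NEG_INF / 2 else NEG_INF

    return best(0, 0, L)


# -- random case generators ----------------------------------------------------


def random_descriptor(rng: np.random.Generator):
    """A small random descriptor: up to 4 elements, budgets <= 2, runs <= 8."""
    from rnpscan.descriptor_engine import DescriptorModel, HelixElement

    symbols = list("ACGTRYSWKMN")
    n_helix = int(rng.integers(0, 2))
    n_ss = int(rng.integers(1, 4 - n_helix))
    elements = {}
    topo_parts = []
    s_idx = 0
    for _ in range(n_ss):
        s_idx += 1
        lab = f"s{s_idx}"
        tokens = []
        for _ in range(int(rng.integers(1, 5))):
            if rng.random() < 0.3:
                lo = int(rng.integers(0, 4))
                hi = lo + int(rng.integers(0, 5))
                tokens.append(RunToken(lo, min(hi, 8)))
            else:
                tokens.append(str(rng.choice(symbols)))
        elements[lab] = SSElement(lab, tuple(tokens), int(rng.integers(0, 3)))
        topo_parts.append(lab)
    if n_helix:
        L = int(rng.integers(2, 5))
        s5 = "".join(str(rng.choice(symbols)) for _ in range(L))
        s3 = "".join(str(rng.choice(symbols)) for _ in range(L))
        elements["h1"] = HelixElement("h1", s5, s3, int(rng.integers(0, 3)))
        # open early, close late, around a random interior single strand
        insert_at = int(rng.integers(0, len(topo_parts) + 1))
        topo_parts.insert(insert_at, "h1")
        close_at = int(rng.integers(insert_at + 1, len(topo_parts) + 1))
        topo_parts.insert(close_at, "h1'")
    return DescriptorModel(
        name="rand", subfamily="bacA", variant="general",
        topology=tuple(topo_parts), elements=elements,
    )


def random_sequence(rng: np.random.Generator, max_len: int = 200, n_prob: float = 0.02) -> str:
    L = int(rng.integers(0, max_len + 1))
    bases = rng.choice(np.array(list("ACGTN")), size=L,
                       p=[(1 - n_prob) / 4] * 4 + [n_prob])
    return "".join(bases)


def random_tiny_alignment(rng: np.random.Generator):
    """A <= 8 column structural alignment for parse-oracle cases."""
    from rnpscan.io_formats import StructuredAlignment

    m = int(rng.integers(2, 9))
    # random bracket string; the stack interpretation is always nested, so
    # only balance needs repairing afterwards
    chars = [str(rng.choice(["<", ">", ".", "."])) for _ in range(m)]
    stack = []
    for k, c in enumerate(chars):
        if c == "<":
            stack.append(k)
        elif c == ">":
            if stack:
                stack.pop()
            else:
                chars[k] = "."
    for k in stack:
        chars[k] = "."
    structure = "".join(chars)

    n_rows = int(rng.integers(1, 4))
    rows = []
    for r in range(n_rows):
        rows.append((f"r{r}", "".join(str(rng.choice(list("ACGT"))) for _ in range(m))))
    return StructuredAlignment(rows=rows, consensus_structure=structure)
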