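import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnpscan.descriptor_engine import (
    DescriptorModel,
    HelixElement,
    RunToken,
    SSElement,
    iupac_match,
    match_at,
    pairs_ok,
    parse_descriptor_text,
    format_descriptor,
    reverse_complement,
    scan,
)
from rnpscan.io_formats import FormatError, SequenceRecord

from .oracles import brute_match_at, brute_scan, random_descriptor, random_sequence


def rec(seq: str, rid: str = "s") -> SequenceRecord:
    return SequenceRecord(id=rid, residues=seq)


EXAMPLE1 = DescriptorModel(
    name="ex1", subfamily="bacA", variant="general",
    topology=("h1", "s2", "h1'"),
    elements={
        "h1": HelixElement("h1", "GGGC", "GCCC", 0),
        "s2": SSElement("s2", ("A", "A", "A"), 0),
    },
)


class TestPrimitives:
    @pytest.mark.parametrize(
        "pattern,base,expected",
        [("R", "A", True), ("Y", "A", False), ("N", "G", True),
         ("S", "C", True), ("W", "C", False)],
    )
    def test_iupac_match(self, pattern, base, expected):
        assert iupac_match(pattern, base) is expected

    def test_iupac_match_invalid_code(self):
        with pytest.raises(ValueError):
            iupac_match("Z", "A")

    def test_pairs_default_includes_wobble(self):
        assert pairs_ok("G", "T")  # G-U wobble on the DNA alphabet
        assert not pairs_ok("A", "G")

    def test_pairs_restricted_set(self):
        gc_only = frozenset([("G", "C"), ("C", "G")])
        assert not pairs_ok("A", "T", gc_only)

    @pytest.mark.parametrize(
        "seq,expected",
        [("ACGT", "ACGT"), ("AAGG", "CCTT"), ("R", "Y"), ("N", "N")],
    )
    def test_reverse_complement(self, seq, expected):
        assert reverse_complement(seq) == expected

    @given(st.text(alphabet="ACGTRYSWKMBDHVN", max_size=60))
    @settings(deadline=None)
    def test_reverse_complement_involutive(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq


class TestParser:
    MINIMAL = (
        "name: m\nsubfamily: bacA\nvariant: general\n"
        "topology: s1 h1 s2 h1' s3\n"
        "s1 0:GG\n"
        "h1 0:GGGC:GCCC\n"
        "s2 1:AN(1,3)A\n"
        "s3 0:TT\n"
    )

    def test_minimal_model(self):
        m = parse_descriptor_text(self.MINIMAL)
        assert len(m.topology) == 5
        assert m.elements["s2"].tokens == ("A", RunToken(1, 3), "A")

    def test_helix_length_mismatch(self):
        bad = self.MINIMAL.replace("h1 0:GGGC:GCCC", "h1 0:GGGC:GCC")
        with pytest.raises(FormatError, match="strand lengths"):
            parse_descriptor_text(bad)

    def test_unresolved_topology_label(self):
        bad = self.MINIMAL.replace("s3 0:TT\n", "")
        with pytest.raises(FormatError, match="resolve"):
            parse_descriptor_text(bad)

    def test_closing_before_opening(self):
        bad = self.MINIMAL.replace("topology: s1 h1 s2 h1' s3",
                                   "topology: s1 h1' s2 h1 s3")
        with pytest.raises(FormatError, match="before its opening"):
            parse_descriptor_text(bad)

    def test_missing_closing_strand(self):
        bad = self.MINIMAL.replace("topology: s1 h1 s2 h1' s3",
                                   "topology: s1 h1 s2 s3")
        with pytest.raises(FormatError, match="exactly twice"):
            parse_descriptor_text(bad)

    def test_format_round_trip(self):
        m = parse_descriptor_text(self.MINIMAL)
        again = parse_descriptor_text(format_descriptor(m))
        assert again == m


class TestMatchAt:
    def test_perfect_hit_with_element_spans(self):
        h = match_at(rec("GGGCAAAGCCC"), 0, EXAMPLE1)
        assert h is not None
        assert (h.start, h.end) == (0, 11)
        assert h.element_spans == {"h1": (0, 4), "s2": (4, 7), "h1'": (7, 11)}
        assert h.mispairs_used == 0

    def test_terminal_mispair_budget_zero(self):
        assert match_at(rec("GGGCAAAGCCG"), 0, EXAMPLE1) is None

    def test_terminal_mispair_budget_one(self):
        relaxed = DescriptorModel(
            name="ex1r", subfamily="bacA", variant="general",
            topology=("h1", "s2", "h1'"),
            elements={
                "h1": HelixElement("h1", "GGGC", "GCCN", 1),
                "s2": SSElement("s2", ("A", "A", "A"), 0),
            },
        )
        h = match_at(rec("GGGCAAAGCCG"), 0, relaxed)
        assert h is not None and h.mispairs_used == 1
        # oracle agrees
        o = brute_match_at("GGGCAAAGCCG", 0, relaxed)
        assert o is not None and o[4] == 1

    def test_subject_n_counts_as_mispair_in_helix(self):
        h = match_at(rec("GGGCAAAGCCN"), 0, EXAMPLE1)
        assert h is None  # N pairs with nothing, budget 0
        h = match_at(rec("NGGCAAAGCCN"), 0, EXAMPLE1)
        assert h is None

    def test_subject_n_free_in_single_strand(self):
        h = match_at(rec("GGGCANAGCCC"), 0, EXAMPLE1)
        assert h is not None and h.mismatches_used == 0


class TestScan:
    def test_planted_hit_recovered_with_oracle_agreement(self):
        rng = np.random.default_rng(0)
        bg = "".join(rng.choice(list("ACGT"), size=1000))
        seq = bg[:100] + "GGGCAAAGCCC" + bg[111:]
        hits = scan(rec(seq), EXAMPLE1, "+")
        oracle = brute_scan(seq, EXAMPLE1)
        assert [(h.start, h.end) for h in hits] == [(o[0], o[1]) for o in oracle]
        assert any(h.start == 100 for h in hits)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(1)
        bg = "".join(rng.choice(list("ACGT"), size=500))
        seq = bg[:200] + "GGGCAAAGCCC" + bg[211:]
        fwd = scan(rec(seq), EXAMPLE1, "both")
        rc = scan(rec(reverse_complement(seq)), EXAMPLE1, "both")
        n = len(seq)
        assert sorted((n - h.end, n - h.start, {"+": "-", "-": "+"}[h.strand])
                      for h in fwd) == sorted((h.start, h.end, h.strand) for h in rc)

    def test_short_record_no_hits(self):
        assert scan(rec("GGG"), EXAMPLE1, "both") == []

    def test_pseudoknot_crossed_helices(self):
        model = DescriptorModel(
            name="pk", subfamily="bacA", variant="general",
            topology=("s1", "h1", "s2", "h2", "s3", "h1'", "s4", "h2'", "s5"),
            elements={
                "s1": SSElement("s1", (), 0),
                "s2": SSElement("s2", (RunToken(1, 2),), 0),
                "s3": SSElement("s3", (RunToken(0, 2),), 0),
                "s4": SSElement("s4", (RunToken(1, 2),), 0),
                "s5": SSElement("s5", (), 0),
                "h1": HelixElement("h1", "GGG", "CCC", 0),
                "h2": HelixElement("h2", "AAA", "TTT", 0),
            },
        )
        # GGG x AAA y CCC z TTT satisfies both crossed pairings
        seq = "GGGAAAACCCATTT"
        hits = scan(rec(seq), model, "+")
        oracle = brute_scan(seq, model)
        assert hits and [(h.start, h.end) for h in hits] == [
            (o[0], o[1]) for o in oracle
        ]

    def test_oracle_equivalence_random_cases(self):
        rng = np.random.default_rng(42)
        for _ in range(150):
            model = random_descriptor(rng)
            seq = random_sequence(rng, max_len=80)
            if rng.random() < 0.5 and len(seq) > 0:
                try:
                    from rnpscan.synthetic import sample_from_descriptor

                    ins = sample_from_descriptor(model, rng)
                    if len(ins) <= len(seq):
                        pos = int(rng.integers(0, len(seq) - len(ins) + 1))
                        seq = seq[:pos] + ins + seq[pos + len(ins):]
                except ValueError:
                    pass
            hits = scan(rec(seq), model, "+")
            oracle = brute_scan(seq, model)
            assert [(h.start, h.end, h.element_spans) for h in hits] == [
                (o[0], o[1], o[2]) for o in oracle
            ]

    def test_budgets_never_exceeded(self):
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(100):
            model = random_descriptor(rng)
            seq = random_sequence(rng, max_len=60)
            for h in scan(rec(seq), model, "+"):
                mm_budget = sum(
                    e.mismatch_budget for e in model.elements.values()
                    if isinstance(e, SSElement)
                )
                mp_budget = sum(
                    e.mispair_budget for e in model.elements.values()
                    if isinstance(e, HelixElement)
                )
                assert h.mismatches_used <= mm_budget
                assert h.mispairs_used <= mp_budget
                checked += 1
        assert checked > 0
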