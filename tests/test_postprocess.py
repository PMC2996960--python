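import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from rnpscan.cascade import GeneCall
from rnpscan.descriptor_engine import reverse_complement
from rnpscan.io_formats import SequenceRecord
from rnpscan.postprocess import (
    assign_homolog,
    dedup,
    gc_content,
    gc_summary,
    size_correlation,
    subfamily_summary,
)


def _call(seq, sub="bacA", strand="+", seq_id="g"):
    return GeneCall(
        seq_id=seq_id, strand=strand, start=0, end=len(seq), subfamily=sub,
        dm_variant="general", local_score=10.0, global_score=10.0,
        evalue=1e-20, sequence=seq, structure="." * len(seq),
    )


class TestDedup:
    def test_grouping_and_multiplicity(self):
        u = dedup([_call("ACGT"), _call("ACGT"), _call("GGCC")])
        assert len(u.representatives) == 2
        assert sorted(u.multiplicity.values()) == [1, 2]
        assert u.total == 3

    def test_idempotent(self):
        calls = [_call("ACGT"), _call("ACGT"), _call("GGCC")]
        once = dedup(calls)
        twice = dedup(once.representatives)
        assert [c.sequence for c in twice.representatives] == [
            c.sequence for c in once.representatives
        ]

    def test_strand_normalization(self):
        # a minus-strand call stores the transcript sequence, so the same
        # gene seen on either strand collapses
        s = "ACCGGT" + "AATT"
        plus = _call(s, strand="+")
        minus = _call(s, strand="-")  # forward residues are revcomp(s)
        u = dedup([plus, minus])
        assert len(u.representatives) == 1 and u.total == 2

    @given(st.lists(st.sampled_from(["AA", "AC", "GT", "GGG"]), max_size=20))
    @settings(deadline=None)
    def test_multiplicity_conserved(self, seqs):
        u = dedup([_call(s) for s in seqs])
        assert u.total == len(seqs)


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [
        ("GCGC", 1.0), ("ATAT", 0.0), ("GANT", 1 / 3),
    ])
    def test_examples(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_all_n_undefined(self):
        with pytest.raises(ValueError):
            gc_content("NNN")

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=60))
    @settings(deadline=None)
    def test_reverse_complement_invariant(self, seq):
        if set(seq) == {"N"}:
            return
        assert gc_content(seq) == pytest.approx(gc_content(reverse_complement(seq)))

    def test_summary_table(self):
        df = gc_summary({"a": ["GCGC", "GGAT"], "b": ["ATAT"]})
        assert set(df["dataset"]) == {"a", "b"}
        assert df[df.dataset == "b"].gc_median.iloc[0] == 0.0


def _refs(rng):
    mk = lambda n: "".join(rng.choice(list("ACGT"), size=n))
    r1 = SequenceRecord(id="ref1", residues=mk(300))
    r2 = SequenceRecord(id="ref2", residues=mk(300))
    r3 = SequenceRecord(id="ref3", residues=mk(300))
    return r1, r2, r3


class TestAssignHomolog:
    def test_identical_reference_gives_species(self):
        rng = np.random.default_rng(0)
        r1, r2, r3 = _refs(rng)
        query = _call(r1.residues)
        a = assign_homolog(query, [(r1, "sp1", "gen1"), (r2, "sp2", "gen2"),
                                   (r3, "sp3", "gen3")])
        assert a.level == "species" and a.hit_ids == ["ref1"]

    def test_two_same_genus_references_give_genus(self):
        rng = np.random.default_rng(1)
        r1, _, r3 = _refs(rng)
        twin = SequenceRecord(id="ref1b", residues=r1.residues)
        query = _call(r1.residues)
        a = assign_homolog(query, [(r1, "sp1", "gen1"), (twin, "sp1b", "gen1"),
                                   (r3, "sp3", "gen3")])
        assert a.level == "genus" and set(a.hit_ids) == {"ref1", "ref1b"}

    def test_cross_genus_hits_give_none_with_flag(self):
        rng = np.random.default_rng(2)
        r1, _, r3 = _refs(rng)
        twin = SequenceRecord(id="refX", residues=r1.residues)
        query = _call(r1.residues)
        a = assign_homolog(query, [(r1, "sp1", "gen1"), (twin, "spX", "genX"),
                                   (r3, "sp3", "gen3")])
        assert a.level == "none" and a.multi_genus

    def test_no_passing_reference(self):
        rng = np.random.default_rng(3)
        r1, r2, r3 = _refs(rng)
        query = _call("".join(rng.choice(list("ACGT"), size=250)))
        a = assign_homolog(query, [(r1, "s", "g"), (r2, "s", "g"), (r3, "s", "g")])
        assert a.level == "none" and not a.multi_genus

    def test_raising_cutoff_never_shrinks_passing_set(self):
        rng = np.random.default_rng(4)
        r1, r2, r3 = _refs(rng)
        near = SequenceRecord(
            id="near", residues=r1.residues[:150] + r2.residues[150:]
        )
        refs = [(r1, "s1", "g1"), (r2, "s2", "g2"), (near, "s3", "g3")]
        query = _call(r1.residues)
        sizes = []
        for cutoff in (1e-80, 1e-50, 1e-20, 1e-5, 1.0):
            a = assign_homolog(query, refs, evalue_cutoff=cutoff)
            sizes.append(len(a.hit_ids) if a.level != "none" or a.multi_genus else 0)
        assert sizes == sorted(sizes)

    def test_empty_references_rejected(self):
        with pytest.raises(ValueError):
            assign_homolog(_call("ACGT"), [])


class TestSummaries:
    def test_subfamily_counts(self):
        u = dedup([_call("AAAA"), _call("CCCC"), _call("GGGG"),
                   _call("TTTT", sub="arcA")])
        s = subfamily_summary(u)
        assert s["bacA"] == 3 and s["arcA"] == 1 and s["nucA"] == 0
        assert s.sum() == len(u.representatives)

    def test_empty_set_all_zero(self):
        s = subfamily_summary(dedup([]))
        assert s.sum() == 0


class TestSizeCorrelation:
    def test_monotone_extremes(self):
        inc = [(i, 10 * i) for i in range(1, 11)]
        dec = [(i, -10 * i) for i in range(1, 11)]
        res = size_correlation({"bacA": inc, "bacB": dec})
        rho = {r.subfamily: r.rho for r in res}
        assert rho["bacA"] == pytest.approx(1.0)
        assert rho["bacB"] == pytest.approx(-1.0)

    def test_simulated_rank_correlation_recovered(self):
        rng = np.random.default_rng(8)
        target = 0.5
        r_pearson = 2 * np.sin(np.pi * target / 6)  # Gaussian copula inversion
        cov = [[1, r_pearson], [r_pearson, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=200)
        pairs = list(zip(xy[:, 0], xy[:, 1]))
        res = size_correlation({"bacA": pairs})
        assert abs(res[0].rho - target) <= 0.15

    def test_small_group_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 3"):
            res = size_correlation({"arcM": [(1, 2), (3, 4)]})
        assert res == []
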