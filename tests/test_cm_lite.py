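import math
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from rnpscan.cm_lite import (
    CalibrationError,
    CovarianceModel,
    EVDParams,
    build_cm,
    calibrate,
    dinucleotide_shuffle,
    evalue,
    fit_gumbel,
    score_global,
    score_local,
    write_cm,
    read_cm,
)
from rnpscan.io_formats import FormatError, StructuredAlignment

from .oracles import best_parse_score, random_tiny_alignment


def _aln(rows, ss):
    return StructuredAlignment(
        rows=[(f"r{i}", s) for i, s in enumerate(rows)], consensus_structure=ss
    )


class TestBuildCm:
    def test_single_column_emission_closed_form(self):
        cm = build_cm(_aln(["A", "A", "A", "A"], "."), pseudocount=1.0)
        node = [n for n in cm.nodes if n.kind == "MATL"][0]
        # log2((4+1)/(4+4) / (1/4)) = log2(2.5)
        assert node.emission[0] == pytest.approx(math.log2(2.5), abs=1e-12)

    def test_pair_emission_closed_form(self):
        cm = build_cm(_aln(["GC", "GC", "GC", "GC"], "<>"), pseudocount=1.0)
        node = [n for n in cm.nodes if n.kind == "MATP"][0]
        # GC entry: log2((4+1)/(4+16) / (1/16)) = 2 bits
        gc_idx = 2 * 4 + 1
        assert node.emission[gc_idx] == pytest.approx(2.0, abs=1e-12)

    def test_gap_majority_column_not_match(self):
        cm = build_cm(_aln(["A-", "A-", "A-", "AC"], ".."), gap_threshold=0.5)
        assert cm.M == 1

    def test_pair_with_gap_column_demoted(self):
        with pytest.warns(UserWarning, match="demoted"):
            cm = build_cm(_aln(["GC", "G-", "G-", "G-"], "<>"))
        assert cm.consensus_structure == "."

    def test_empty_match_set_error(self):
        with pytest.raises(FormatError):
            build_cm(_aln(["--", "--"], ".."), gap_threshold=0.5)

    def test_pseudoknot_tiers_dropped(self):
        cm = build_cm(_aln(["GGAACC" + "TT", "GGAACC" + "TT"], "<<AA>>aa"))
        # nested pairs kept, letter-tier columns become unpaired match columns
        assert cm.consensus_structure == "<<..>>.."


class TestScoring:
    def test_global_score_on_own_sequence_is_emission_sum(self):
        seq = "GGAAACC"
        cm = build_cm(_aln([seq], "<<...>>"), pseudocount=0.01)
        expected = 0.0
        code = {"A": 0, "C": 1, "G": 2, "T": 3}
        cols = {}
        k = 0
        for j, ch in enumerate(seq):
            cols[j] = ch
        m_idx = 0
        for node in cm.nodes:
            if node.kind == "MATL":
                expected += node.emission[code[seq[node.col1]]]
            elif node.kind == "MATP":
                expected += node.emission[code[seq[node.col1]] * 4 + code[seq[node.col2]]]
        sa = score_global(cm, seq)
        assert sa.score == pytest.approx(expected, abs=1e-3)
        assert (sa.start, sa.end) == (0, len(seq))
        assert sa.structure == "<<...>>"

    def test_one_deletion_charged_open_plus_forgone_emission(self):
        seq = "GGAAACC"
        cm = build_cm(_aln([seq], "<<...>>"), pseudocount=0.01)
        full = score_global(cm, seq).score
        # delete the middle unpaired A (model column 3)
        shorter = "GGAACC"
        node = [n for n in cm.nodes if n.kind == "MATL"][1]
        expected = full - (3.0 + node.emission[0])
        got = score_global(cm, shorter).score
        assert got == pytest.approx(expected, abs=1e-3)
        # and the exhaustive parse oracle agrees
        assert got == pytest.approx(best_parse_score(cm, shorter), abs=1e-3)

    def test_empty_input_rejected(self):
        cm = build_cm(_aln(["GC"], "<>"))
        with pytest.raises(ValueError):
            score_global(cm, "")

    def test_short_input_flagged_but_scored(self):
        cm = build_cm(_aln(["GGAAACCTT"], "<<...>>.."))
        sa = score_global(cm, "GG")
        assert "short_input" in sa.flags
        assert np.isfinite(sa.score)

    def test_local_equals_global_on_exact_consensus(self):
        seq = "GGAAACC"
        cm = build_cm(_aln([seq], "<<...>>"), pseudocount=0.01)
        assert score_local(cm, seq).score == pytest.approx(
            score_global(cm, seq).score, abs=1e-3
        )

    def test_local_finds_embedded_consensus_span(self):
        seq = "GGTAACC"
        cm = build_cm(_aln([seq], "<<...>>"), pseudocount=0.01)
        window = "TTTTT" + seq + "AAAAA"
        sa = score_local(cm, window)
        assert (sa.start, sa.end) == (5, 5 + len(seq))
        assert sa.score == pytest.approx(score_global(cm, seq).score, abs=1e-3)

    def test_parse_oracle_equivalence_random_cases(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            aln = random_tiny_alignment(rng)
            cm = build_cm(aln, pseudocount=float(rng.uniform(0.2, 2.0)))
            L = int(rng.integers(1, 13))
            subject = "".join(rng.choice(list("ACGT"), size=L))
            assert score_global(cm, subject).score == pytest.approx(
                best_parse_score(cm, subject), abs=2e-3
            )

    def test_local_never_below_best_subsequence(self):
        rng = np.random.default_rng(4)
        aln = random_tiny_alignment(rng)
        cm = build_cm(aln)
        subject = "".join(rng.choice(list("ACGT"), size=10))
        best_sub = max(
            best_parse_score(cm, subject[i:j])
            for i in range(len(subject) + 1)
            for j in range(i + 1, len(subject) + 1)
        )
        assert score_local(cm, subject).score == pytest.approx(best_sub, abs=2e-3)


class TestShuffle:
    def test_unique_arrangement_fixed_point(self):
        assert dinucleotide_shuffle("AAAA", 0) == "AAAA"

    def test_counts_preserved_exactly(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            L = int(rng.integers(2, 120))
            s = "".join(rng.choice(list("ACGT"), size=L))
            t = dinucleotide_shuffle(s, int(rng.integers(2**31)))
            assert Counter(zip(s, s[1:])) == Counter(zip(t, t[1:]))
            assert len(t) == len(s)

    def test_deterministic_per_seed(self):
        s = "ACGTACGTGGCCAATT" * 4
        assert dinucleotide_shuffle(s, 7) == dinucleotide_shuffle(s, 7)
        assert dinucleotide_shuffle(s, 7) != dinucleotide_shuffle(s, 8)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            dinucleotide_shuffle("A", 0)


class TestCalibration:
    def _toy_cm(self):
        rows = ["GGGCAAAAGCCC", "GGGCAAAAGCCC", "GGGCATAAGCCC", "GGGCAAATGCCC"]
        return build_cm(_aln(rows, "<<<<....>>>>"), pseudocount=0.5)

    def test_too_few_decoys_rejected(self):
        with pytest.raises(ValueError):
            calibrate(self._toy_cm(), n_decoys=10)

    def test_same_seed_same_params(self):
        p1 = calibrate(self._toy_cm(), n_decoys=60, seed=3)
        p2 = calibrate(self._toy_cm(), n_decoys=60, seed=3)
        assert p1 == p2

    def test_degenerate_scores_raise(self):
        with pytest.raises(CalibrationError):
            fit_gumbel(np.full(100, 5.0))

    def test_lambda_recovered_from_simulated_gumbel(self):
        true_lam, true_mu = 0.69, 5.0
        scores = stats.gumbel_r.rvs(
            loc=true_mu, scale=1 / true_lam, size=500,
            random_state=np.random.default_rng(12),
        )
        lam, mu = fit_gumbel(scores)
        assert abs(lam - true_lam) / true_lam < 0.15
        assert abs(mu - true_mu) < 0.5

    def test_calibration_tail_sane_on_fresh_decoys(self):
        """Fresh-decoy hit counts at E <= e stay within 3e."""
        cm = self._toy_cm()
        calibrate(cm, n_decoys=150, seed=0)
        rng = np.random.default_rng(99)
        n_fresh = 200
        wlen = 2 * cm.M
        total_nt = n_fresh * wlen
        counts = {0.1: 0, 1.0: 0, 10.0: 0}
        for _ in range(n_fresh):
            w = "".join(rng.choice(list("ACGT"), size=wlen))
            w = dinucleotide_shuffle(w, rng)
            s = score_local(cm, w).score
            ev = evalue(cm, s, total_nt, strands=1)
            for e in counts:
                if ev <= e:
                    counts[e] += 1
        for e, c in counts.items():
            assert c <= 3 * e, f"E<={e}: {c} hits"


class TestEvalue:
    def _calibrated(self, lam=0.69, mu=10.0):
        cm = build_cm(_aln(["GGGCAAAAGCCC"], "<<<<....>>>>"))
        cm.evd = EVDParams(lam=lam, mu=mu, n_decoys=100, decoy_length=24, seed=0)
        return cm

    def test_closed_form_example(self):
        cm = self._calibrated()
        # W = 1000 windows: search_space = 500 * M with both strands
        ev = evalue(cm, score=20.0, search_space=500 * cm.M, strands=2)
        p = 1 - math.exp(-math.exp(-0.69 * 10))
        assert ev == pytest.approx(1000 * p, rel=1e-9)
        assert ev == pytest.approx(1.0, rel=0.01)

    def test_at_location_parameter(self):
        cm = self._calibrated()
        ev = evalue(cm, score=10.0, search_space=cm.M, strands=1)  # W = 1
        assert ev == pytest.approx(1 - math.exp(-1), rel=1e-9)

    def test_monotone_decreasing_and_vanishing(self):
        cm = self._calibrated()
        evs = [evalue(cm, s, 10_000) for s in (0, 10, 20, 40, 80, 200)]
        assert all(a > b for a, b in zip(evs, evs[1:]))
        assert evs[-1] < 1e-50

    def test_linear_in_search_space(self):
        cm = self._calibrated()
        e1 = evalue(cm, 15.0, 10_000)
        e2 = evalue(cm, 15.0, 20_000)
        assert e2 == pytest.approx(2 * e1, rel=1e-9)

    def test_uncalibrated_model_rejected(self):
        cm = build_cm(_aln(["GC"], "<>"))
        with pytest.raises(ValueError):
            evalue(cm, 10.0, 1000)


class TestSeparationAndPersistence:
    def test_training_rows_beat_their_own_shuffles(self, toy_library):
        """Weakest training member still outscores 100 dinucleotide shuffles."""
        for sub in toy_library.subfamilies():
            entry = toy_library[sub]
            scores = {m: score_global(entry.cm, m).score for m in entry.members}
            weakest = min(scores, key=scores.get)
            rng = np.random.default_rng(17)
            shuffled_max = max(
                score_global(entry.cm, dinucleotide_shuffle(weakest, rng)).score
                for _ in range(100)
            )
            assert scores[weakest] > shuffled_max

    def test_cm_round_trip(self, tmp_path, toy_library):
        cm = toy_library["bacA"].cm
        p = tmp_path / "cm.txt"
        write_cm(cm, p)
        back = read_cm(p)
        assert back.consensus_structure == cm.consensus_structure
        assert back.evd.lam == pytest.approx(cm.evd.lam, rel=1e-6)
        assert back.evd.mu == pytest.approx(cm.evd.mu, abs=1e-5)
        assert back.evd.n_decoys == cm.evd.n_decoys
        seq = toy_library["bacA"].members[0]
        assert score_global(back, seq).score == pytest.approx(
            score_global(cm, seq).score, abs=1e-3
        )
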