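import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from dynrbp.icshape import (IcshapeConfig, NormalizationError, RTBDCounts,
                            combine_replicates, enrichment, normalize_counts,
                            read_counts_table, rescale_scores,
                            score_transcript, write_reactivity_table)
from dynrbp.icshape import read_reactivity_table
from dynrbp.synth import SynthConfig, simulate_rtbd


def make_counts(length=10, fill=300, rt=20, tid="tx"):
    v = np.full(length, rt)
    bd = np.full(length, fill)
    return RTBDCounts(tid, v, v, v * 2, v * 2, bd, bd)


class TestCombineReplicates:
    def test_elementwise_addition(self):
        c = RTBDCounts("t", [1, 2], [3, 4], [0, 0], [0, 0], [1, 1], [1, 1])
        rt_dmso, rt_nai, bd = combine_replicates(c)
        assert rt_dmso.tolist() == [4, 6]

    def test_zero_replicate_is_identity(self):
        c = RTBDCounts("t", [5, 7], [0, 0], [1, 2], [0, 0], [3, 3], [0, 0])
        rt_dmso, rt_nai, bd = combine_replicates(c)
        assert rt_dmso.tolist() == [5, 7]
        assert rt_nai.tolist() == [1, 2]
        assert bd.tolist() == [3, 3]

    def test_all_zero(self):
        c = RTBDCounts("t", [0], [0], [0], [0], [0], [0])
        assert combine_replicates(c)[0].tolist() == [0]

    def test_length_mismatch_names_transcript(self):
        with pytest.raises(ValueError, match="txA"):
            RTBDCounts("txA", [1, 2], [1], [1, 2], [1, 2], [1, 2], [1, 2])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            RTBDCounts("t", [-1], [0], [0], [0], [0], [0])


class TestNormalizeCounts:
    def test_constant_vector_gives_ones(self):
        out, factor = normalize_counts(np.full(50, 7.0))
        assert factor == 7.0
        assert np.allclose(out, 1.0)

    def test_rank_slice_1_to_100(self):
        # oracle: sort, take ascending ranks 91..95, average -> 93
        values = np.arange(1.0, 101.0)
        out, factor = normalize_counts(values, 0.90, 0.95)
        assert factor == pytest.approx(93.0)
        assert np.allclose(out, values / 93.0)

    def test_degenerate_slice_n10(self):
        # rank slice (9, 10] -> single top rank
        values = np.arange(1.0, 11.0)
        _, factor = normalize_counts(values, 0.90, 0.95)
        assert factor == pytest.approx(10.0)

    def test_zero_factor_raises_skip_error(self):
        with pytest.raises(NormalizationError, match="skip"):
            normalize_counts(np.zeros(20))

    @given(st.lists(st.floats(0, 1e6), min_size=2, max_size=60),
           st.floats(0.5, 0.89), st.floats(0.9, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_factor_within_value_range(self, values, lo, hi):
        values = np.asarray(values)
        try:
            _, factor = normalize_counts(values, lo, hi)
        except NormalizationError:
            return
        assert values.min() <= factor <= values.max()


class TestEnrichment:
    def test_direct_evaluation(self):
        out = enrichment([2.0], [1.0], [1.0], alpha=0.25)
        assert out[0] == pytest.approx(1.75)

    def test_alpha_zero_degenerates(self):
        out = enrichment([3.0, 4.0], [9.0, 9.0], [2.0, 2.0], alpha=0.0)
        assert np.allclose(out, [1.5, 2.0])

    def test_zero_bd_is_undefined_not_error(self):
        out = enrichment([1.0], [1.0], [0.0], alpha=0.25)
        assert np.isnan(out[0])


class TestRescaleScores:
    # e over 0..20 evenly: linear-interpolation quantiles give q5=1, q95=19
    def setup_method(self):
        self.e = np.arange(21.0)
        self.cfg = IcshapeConfig()

    def test_lower_anchor(self):
        bd = np.full(21, 300.0)
        out = rescale_scores(self.e, bd, self.cfg)
        assert out[1] == pytest.approx(0.0)  # e=1=q5

    def test_upper_anchor_and_clamp(self):
        bd = np.full(21, 300.0)
        out = rescale_scores(self.e, bd, self.cfg)
        assert out[19] == pytest.approx(1.0)  # e=19=q95
        assert out[20] == pytest.approx(1.0)  # e>q95 clamps

    def test_coverage_cutoff_199_is_null(self):
        bd = np.full(21, 300.0)
        bd[5] = 199.0
        out = rescale_scores(self.e, bd, self.cfg)
        assert np.isnan(out[5])

    def test_coverage_exactly_200_scores(self):
        bd = np.full(21, 200.0)
        out = rescale_scores(self.e, bd, self.cfg)
        assert np.all(np.isfinite(out))

    def test_all_undefined_warns_all_null(self):
        with pytest.warns(UserWarning):
            out = rescale_scores(np.full(5, np.nan), np.full(5, 300.0), self.cfg)
        assert np.all(np.isnan(out))


class TestScoreTranscript:
    def test_output_range_and_length(self):
        counts = make_counts(length=250, fill=300)
        out = score_transcript(counts, IcshapeConfig(window_size=100,
                                                     window_step=20))
        assert len(out) == 250
        finite = out[np.isfinite(out)]
        assert np.all((finite >= 0) & (finite <= 1))

    def test_scale_invariance_under_count_doubling(self):
        rng = np.random.default_rng(5)
        length = 120
        rt = rng.integers(10, 60, length)
        nai = rng.integers(10, 120, length)
        bd = rng.integers(300, 600, length)
        c1 = RTBDCounts("t", rt, rt, nai, nai, bd, bd)
        c2 = RTBDCounts("t", 2 * rt, 2 * rt, 2 * nai, 2 * nai, 2 * bd, 2 * bd)
        cfg = IcshapeConfig(window_size=60, window_step=30)
        out1, out2 = score_transcript(c1, cfg), score_transcript(c2, cfg)
        assert np.allclose(out1, out2, equal_nan=True)

    def test_replicate_swap_invariance(self):
        rng = np.random.default_rng(6)
        length = 80
        a, b = rng.integers(5, 50, (2, length))
        na, nb = rng.integers(5, 90, (2, length))
        bda, bdb = rng.integers(200, 500, (2, length))
        c1 = RTBDCounts("t", a, b, na, nb, bda, bdb)
        c2 = RTBDCounts("t", b, a, nb, na, bdb, bda)
        cfg = IcshapeConfig(window_size=80, window_step=10)
        assert np.allclose(score_transcript(c1, cfg), score_transcript(c2, cfg),
                           equal_nan=True)

    def test_short_transcript_single_window(self):
        counts = make_counts(length=50, fill=300)
        out = score_transcript(counts, IcshapeConfig(window_size=200))
        assert len(out) == 50

    def test_coverage_scan_threshold_is_200(self):
        # merged base densities take every integer value 150..250
        coverages = np.arange(150, 251)
        n = len(coverages)
        rng = np.random.default_rng(1)
        rt = rng.integers(5, 40, n)
        nai = rng.integers(10, 80, n)
        bd1 = coverages // 2
        bd2 = coverages - bd1
        counts = RTBDCounts("scan", rt, rt, nai, nai, bd1, bd2)
        out = score_transcript(counts, IcshapeConfig(window_size=n,
                                                     window_step=n))
        numeric = coverages[np.isfinite(out)]
        assert numeric.min() == 200

    def test_recovery_from_simulated_counts(self):
        cfg = SynthConfig(seed=21, read_depth=1e4)
        rng = np.random.default_rng(21)
        truth = rng.random(400)
        counts = simulate_rtbd("sim", truth, cfg)
        scores = score_transcript(counts, IcshapeConfig(window_size=200,
                                                        window_step=50))
        ok = np.isfinite(scores)
        assert ok.mean() > 0.95
        rho = spearmanr(scores[ok], truth[ok]).statistic
        assert rho >= 0.8

    @given(st.integers(0, 2 ** 16))
    @settings(max_examples=15, deadline=None)
    def test_fuzz_scores_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(10, 120))
        def vec(hi):
            return rng.integers(0, hi, length)
        counts = RTBDCounts("f", vec(50), vec(50), vec(100), vec(100),
                            vec(500), vec(500))
        out = score_transcript(counts, IcshapeConfig(window_size=64,
                                                     window_step=16))
        assert len(out) == length
        finite = out[np.isfinite(out)]
        assert np.all((finite >= 0.0) & (finite <= 1.0))


class TestTabularIO:
    def test_round_trip(self, tmp_path):
        import pandas as pd

        counts = make_counts(length=6)
        rows = [("tx", i + 1, counts.rt_dmso_rep1[i], counts.rt_dmso_rep2[i],
                 counts.rt_nai_rep1[i], counts.rt_nai_rep2[i],
                 counts.bd_dmso_rep1[i], counts.bd_dmso_rep2[i])
                for i in range(6)]
        path = tmp_path / "counts.tsv"
        pd.DataFrame(rows, columns=["transcript_id", "position", "rt_dmso_1",
                                    "rt_dmso_2", "rt_nai_1", "rt_nai_2",
                                    "bd_dmso_1", "bd_dmso_2"]).to_csv(
            path, sep="\t", index=False)
        loaded = read_counts_table(path)
        assert list(loaded) == ["tx"]
        assert np.array_equal(loaded["tx"].bd_dmso_rep1, counts.bd_dmso_rep1)

    def test_reactivity_table_null_handling(self, tmp_path):
        path = tmp_path / "react.tsv"
        profile = np.array([0.5, np.nan, 1.0])
        write_reactivity_table({"tx": profile}, path)
        text = path.read_text()
        assert "NULL" in text
        back = read_reactivity_table(path)
        assert np.allclose(back["tx"], profile, equal_nan=True)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"alpha": -0.1}, {"norm_lo": 0.95, "norm_hi": 0.90},
        {"scale_lo": 0.9, "scale_hi": 0.5},
        {"window_size": 10, "window_step": 20},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            IcshapeConfig(**kwargs)
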