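import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom, kstest

from escape_clock.forest import CopyForest, forest_from_records
from escape_clock.simdata import SimConfig, simulate_sample, emit_gain_posterior, _sub_rng
from escape_clock.io import gain_posteriors_from_table
from escape_clock.timing import (
    SUBCLONAL,
    SUBCLONAL_TIME,
    expected_vaf,
    multiplicity_posterior,
    sample_snv_timing,
    snv_rng,
    time_all_snvs,
)

from conftest import fixed_gain_posterior


class TestExpectedVaf:
    def test_clonal_examples(self):
        assert expected_vaf(2, 0.5, 3) == pytest.approx(0.4)
        assert expected_vaf(2, 1.0, 2) == pytest.approx(1.0)
        assert expected_vaf(1, 1.0, 2) == pytest.approx(0.5)

    def test_subclonal_example(self):
        assert expected_vaf(SUBCLONAL, 0.8, 2, ccf=0.5) == pytest.approx(0.2)

    def test_impossible_multiplicity(self):
        with pytest.raises(ValueError, match="multiplicity"):
            expected_vaf(3, 0.5, 2)

    def test_invalid_purity(self):
        with pytest.raises(ValueError):
            expected_vaf(1, 0.0, 2)
        with pytest.raises(ValueError):
            expected_vaf(1, 1.2, 2)

    @given(
        rho=st.floats(0.05, 1.0),
        n_t=st.integers(1, 8),
    )
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing_in_m(self, rho, n_t):
        fs = [expected_vaf(m, rho, n_t) for m in range(1, n_t + 1)]
        assert all(b > a for a, b in zip(fs, fs[1:]))
        assert all(0 < f <= 1 for f in fs)


class TestMultiplicityPosterior:
    def test_probabilities_normalized(self, single_gain_forest):
        mp = multiplicity_posterior(30, 100, single_gain_forest, 0.8)
        assert mp.probs.sum() == pytest.approx(1.0)
        assert (mp.probs >= 0).all()

    def test_high_depth_m2(self, single_gain_forest):
        # brute-force: 4 states (m=1, m=2, subclonal); depth 1000 at VAF 2/3
        mp = multiplicity_posterior(667, 1000, single_gain_forest, 1.0)
        assert mp.prob_of(2) > 0.99

    def test_oracle_agreement_brute_force(self, single_gain_forest):
        # independent Bayes computation over enumerated states
        alt, depth, rho = 40, 100, 0.9
        n_t = 3
        denom = n_t * rho + 2 * (1 - rho)
        priors = {1: 2.4, 2: 0.3, SUBCLONAL: 0.1 * 2.7}
        fs = {1: rho / denom, 2: 2 * rho / denom, SUBCLONAL: 0.5 * rho / denom}
        w = {s: priors[s] * binom.pmf(alt, depth, fs[s]) for s in priors}
        z = sum(w.values())
        mp = multiplicity_posterior(alt, depth, single_gain_forest, rho)
        for s in priors:
            assert mp.prob_of(s) == pytest.approx(w[s] / z, rel=1e-9)

    def test_subclonal_modal_at_low_vaf(self, diploid_forest):
        mp = multiplicity_posterior(40, 200, diploid_forest, 1.0, subclonal_ccf=0.4)
        assert mp.modal_state == SUBCLONAL

    def test_zero_alt_shifts_to_lowest_state(self, single_gain_forest):
        mp = multiplicity_posterior(0, 100, single_gain_forest, 0.8)
        low = min(s for s in mp.states if s != SUBCLONAL)
        clonal_probs = {s: mp.prob_of(s) for s in mp.states if s != SUBCLONAL}
        assert max(clonal_probs, key=clonal_probs.get) == low

    def test_alt_exceeding_depth_rejected(self, diploid_forest):
        with pytest.raises(ValueError):
            multiplicity_posterior(101, 100, diploid_forest, 1.0)


class TestSampleSnvTiming:
    def test_diploid_uniform_mean(self, diploid_forest):
        gp = fixed_gain_posterior(diploid_forest, 250)
        post = sample_snv_timing(50, 100, gp, 1.0, S=250, rng=np.random.default_rng(0))
        # mean of 250 uniforms: 0.5 +/- 3 sigma
        assert abs(post.mean - 0.5) < 0.09
        assert post.S == 250

    def test_m2_draws_before_gain(self, single_gain_forest):
        gp = fixed_gain_posterior(single_gain_forest, 200)
        post = sample_snv_timing(60, 100, gp, 0.9, S=200, rng=np.random.default_rng(1))
        m2 = post.draws[post.multiplicities == 2]
        assert len(m2) > 0
        assert (m2 < 0.3).all()

    def test_wgd_high_depth_pre_wgd(self, wgd_forest):
        gp = fixed_gain_posterior(wgd_forest, 2000)
        post = sample_snv_timing(1000, 2000, gp, 1.0, S=2000, rng=np.random.default_rng(2))
        assert np.mean(post.draws < 0.4) >= 0.99

    def test_draws_respect_sampled_multiplicity_edges(self, single_gain_forest):
        gp = fixed_gain_posterior(single_gain_forest, 500)
        post = sample_snv_timing(45, 100, gp, 0.8, S=500, rng=np.random.default_rng(3))
        for t, m in zip(post.draws, post.multiplicities):
            if t == SUBCLONAL_TIME:
                assert m == 0
                continue
            assert any(
                e.leaf_count == m and e.t_start <= t <= e.t_end
                for e in single_gain_forest.edges
            )

    def test_values_in_law_domain(self, wgd_forest):
        gp = fixed_gain_posterior(wgd_forest, 300)
        post = sample_snv_timing(10, 100, gp, 0.7, S=300, rng=np.random.default_rng(4))
        ok = (post.draws == SUBCLONAL_TIME) | ((post.draws >= 0) & (post.draws <= 1))
        assert ok.all()

    def test_gain_draw_pairing_cycles(self, single_gain_forest):
        gp = fixed_gain_posterior(single_gain_forest, 10)
        post = sample_snv_timing(60, 100, gp, 0.9, S=25, rng=np.random.default_rng(5))
        assert post.S == 25


class TestMonotoneConcentration:
    def test_posterior_sd_non_increasing_in_depth(self):
        # same 50 SNVs (same forests, same true multiplicities); only the
        # read counts are redrawn at each depth
        cfg = SimConfig(
            cancer_types=["X"],
            samples_per_type=1,
            mean_depth=100.0,
            purity_range=(0.9, 0.9),
            wgd_probability=1.0,
            background_snvs_per_sample=50,
            driver_snvs_per_sample=0,
            n_segments=5,
            draws_S=100,
            seed=77,
        )
        bundle, truth = simulate_sample(cfg, "X", "X_000", rng=_sub_rng(77, "s"))
        gains = emit_gain_posterior(truth, 0.0, 100, rng=_sub_rng(77, "g"))
        gps = gain_posteriors_from_table(gains, bundle["segments"])["X_000"]
        n_t = {
            str(r.segment_id): int(r.major) + int(r.minor)
            for r in bundle["segments"].itertuples()
        }
        rng = np.random.default_rng(99)
        sds = {}
        for depth in (30, 100, 300):
            snvs = bundle["snvs"].copy()
            f = np.array(
                [
                    expected_vaf(int(m), truth.purity, n_t[str(s)])
                    for m, s in zip(truth.snvs["m_true"], truth.snvs["segment_id"])
                ]
            )
            alt = rng.binomial(depth, f)
            snvs["alt_count"] = alt
            snvs["ref_count"] = depth - alt
            _, draws = time_all_snvs(
                snvs, gps, bundle["segments"], truth.purity, "X_000", S=100, seed=77
            )
            clonal = np.where(draws == SUBCLONAL_TIME, np.nan, draws)
            sds[depth] = np.nanmean(np.nanstd(clonal, axis=1))
        assert sds[30] >= sds[100] - 0.01
        assert sds[100] >= sds[300] - 0.01


class TestTimeAllSnvs:
    @pytest.fixture
    def sample_bundle(self, small_config):
        bundle, truth = simulate_sample(small_config, "A", "A_000", rng=_sub_rng(1, "x"))
        gains = emit_gain_posterior(truth, 0.01, small_config.draws_S, rng=_sub_rng(1, "g"))
        gps = gain_posteriors_from_table(gains, bundle["segments"])["A_000"]
        return bundle, truth, gps

    def test_deterministic_under_seed(self, sample_bundle):
        bundle, truth, gps = sample_bundle
        t1, d1 = time_all_snvs(bundle["snvs"], gps, bundle["segments"], truth.purity, "A_000", S=40, seed=9)
        t2, d2 = time_all_snvs(bundle["snvs"], gps, bundle["segments"], truth.purity, "A_000", S=40, seed=9)
        pd.testing.assert_frame_equal(t1, t2)
        np.testing.assert_array_equal(d1, d2)

    def test_row_order_invariance(self, sample_bundle):
        bundle, truth, gps = sample_bundle
        snvs = bundle["snvs"]
        t1, _ = time_all_snvs(snvs, gps, bundle["segments"], truth.purity, "A_000", S=30, seed=9)
        shuffled = snvs.sample(frac=1.0, random_state=4).reset_index(drop=True)
        t2, _ = time_all_snvs(shuffled, gps, bundle["segments"], truth.purity, "A_000", S=30, seed=9)
        merged = t1.merge(t2, on=["chrom", "pos"], suffixes=("_a", "_b"))
        assert len(merged) == len(t1)
        np.testing.assert_allclose(merged["mean_time_a"], merged["mean_time_b"])

    def test_snv_outside_segments_flagged_untimed(self, sample_bundle):
        bundle, truth, gps = sample_bundle
        snvs = pd.concat(
            [
                bundle["snvs"],
                pd.DataFrame(
                    [{"sample": "A_000", "chrom": "chr99", "pos": 5, "ref": "A", "alt": "T",
                      "gene": "X", "classification": "Missense_Mutation", "ref_count": 30, "alt_count": 20}]
                ),
            ],
            ignore_index=True,
        )
        table, draws = time_all_snvs(snvs, gps, bundle["segments"], truth.purity, "A_000", S=20, seed=1)
        row = table[table["chrom"] == "chr99"].iloc[0]
        assert not row["timed"]
        assert np.isnan(row["mean_time"])
        assert np.isnan(draws[table["chrom"] == "chr99"]).all()

    def test_recovery_correlation_on_gained_segments(self):
        # >=300 clonal SNVs at depth 100 on gained segments: r > 0.6
        cfg = SimConfig(
            cancer_types=["X"],
            samples_per_type=1,
            mean_depth=100.0,
            purity_range=(0.85, 0.95),
            wgd_probability=1.0,
            max_gains_per_segment=1,
            background_snvs_per_sample=400,
            driver_snvs_per_sample=0,
            n_segments=8,
            draws_S=100,
            seed=13,
        )
        bundle, truth = simulate_sample(cfg, "X", "X_000", rng=_sub_rng(13, "s"))
        gains = emit_gain_posterior(truth, 0.01, 100, rng=_sub_rng(13, "g"))
        gps = gain_posteriors_from_table(gains, bundle["segments"])["X_000"]
        table, draws = time_all_snvs(
            bundle["snvs"], gps, bundle["segments"], truth.purity, "X_000", S=100, seed=13
        )
        clonal = np.where(draws == SUBCLONAL_TIME, np.nan, draws)
        post_mean = np.nanmean(clonal, axis=1)
        gained = {
            str(r.segment_id)
            for r in bundle["segments"].itertuples()
            if (int(r.major) + int(r.minor)) > 2
        }
        merged = table.assign(post_mean=post_mean, t_true=truth.snvs["t_true"].to_numpy())
        sub = merged[merged["segment_id"].isin(gained) & merged["timed"]]
        assert len(sub) >= 300
        r = np.corrcoef(sub["post_mean"], sub["t_true"])[0, 1]
        assert r > 0.6

    def test_subclonal_truth_recovered(self):
        cfg = SimConfig(
            cancer_types=["X"],
            samples_per_type=1,
            mean_depth=200.0,
            purity_range=(0.9, 1.0),
            subclonal_fraction=1.0,
            subclonal_ccf_range=(0.2, 0.5),
            background_snvs_per_sample=100,
            driver_snvs_per_sample=0,
            wgd_probability=0.0,
            max_gains_per_segment=1,
            n_segments=5,
            draws_S=100,
            seed=21,
        )
        bundle, truth = simulate_sample(cfg, "X", "X_000", rng=_sub_rng(21, "s"))
        gains = emit_gain_posterior(truth, 0.0, 100, rng=_sub_rng(21, "g"))
        gps = gain_posteriors_from_table(gains, bundle["segments"])["X_000"]
        table, _ = time_all_snvs(
            bundle["snvs"], gps, bundle["segments"], truth.purity, "X_000", S=100, seed=21
        )
        frac_detected = np.mean(table["clonal_fraction"] < 0.2)
        assert frac_detected >= 0.9


class TestSnvRng:
    def test_stable_across_calls(self):
        a = snv_rng(5, "s1", "chr1", 100).random(3)
        b = snv_rng(5, "s1", "chr1", 100).random(3)
        np.testing.assert_array_equal(a, b)

    def test_distinct_per_snv(self):
        a = snv_rng(5, "s1", "chr1", 100).random()
        b = snv_rng(5, "s1", "chr1", 101).random()
        assert a != b
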