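import json

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from escape_clock.forest import forest_from_records
from escape_clock.simdata import (
    SimConfig,
    TimeDistribution,
    _sub_rng,
    emit_gain_posterior,
    simulate_cohort,
    simulate_sample,
)
from escape_clock.timing import expected_vaf


class TestSimConfig:
    def test_defaults_valid(self):
        SimConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"purity_range": (0.0, 0.9)},
            {"purity_range": (0.5, 1.2)},
            {"wgd_probability": 1.5},
            {"subclonal_fraction": -0.1},
            {"subclonal_ccf_range": (0.2, 1.0)},
            {"mean_depth": 0},
            {"gain_posterior_jitter_sd": -1},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)

    def test_empty_pathway_named_in_error(self):
        with pytest.raises(ValueError, match="badpw"):
            SimConfig(pathway_gene_sets={"badpw": []})

    def test_shared_genes_recorded(self):
        cfg = SimConfig(pathway_gene_sets={"a": ["G1", "G2"], "b": ["G2", "G3"]})
        assert cfg.shared_genes == {"G2"}

    def test_yaml_round_trip(self, tmp_path, small_config):
        import yaml

        p = tmp_path / "sim.yaml"
        p.write_text(yaml.safe_dump(small_config.to_dict()))
        cfg = SimConfig.from_yaml(p)
        assert cfg.to_dict() == small_config.to_dict()


class TestTimeDistribution:
    def test_beta(self):
        d = TimeDistribution.parse({"family": "beta", "a": 2, "b": 8})
        vals = [d.sample(np.random.default_rng(i)) for i in range(100)]
        assert all(0 <= v <= 1 for v in vals)

    def test_point(self):
        d = TimeDistribution.parse({"family": "point", "value": 0.1})
        assert d.sample(np.random.default_rng(0)) == 0.1

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            TimeDistribution.parse({"family": "cauchy"}).sample(np.random.default_rng(0))


class TestSimulateSample:
    def test_vaf_formula_examples(self):
        assert expected_vaf(2, 0.5, 3) == pytest.approx(0.4)
        assert expected_vaf(1, 1.0, 2) == pytest.approx(0.5)

    def test_segment_cn_matches_forest_leaf_counts(self, small_config):
        bundle, truth = simulate_sample(small_config, "A", "A_000", rng=_sub_rng(1, "a"))
        forests = truth.forests()
        for rec in bundle["segments"].itertuples():
            f = forests[str(rec.segment_id)]
            assert (f.major_cn, f.minor_cn) == (int(rec.major), int(rec.minor))

    def test_all_clonal_when_fraction_zero(self, small_config):
        bundle, truth = simulate_sample(small_config, "A", "A_000", rng=_sub_rng(2, "a"))
        assert not truth.snvs["is_subclonal"].any()
        assert truth.snvs["t_true"].notna().all()

    def test_all_subclonal_when_fraction_one(self):
        cfg = SimConfig(subclonal_fraction=1.0, driver_snvs_per_sample=10)
        _, truth = simulate_sample(cfg, "A", "A_000", rng=_sub_rng(3, "a"))
        assert truth.snvs["is_subclonal"].all()
        assert (truth.snvs["m_true"] == 1).all()
        assert (truth.snvs["ccf_true"] < 1).all()

    def test_snv_time_precedes_downstream_gains(self):
        # m_true > 1 implies t_true <= every gain time below the mutated edge
        cfg = SimConfig(
            background_snvs_per_sample=200, driver_snvs_per_sample=0,
            wgd_probability=1.0, max_gains_per_segment=2, seed=4,
        )
        _, truth = simulate_sample(cfg, "A", "A_000", rng=_sub_rng(4, "a"))
        forests = truth.forests()
        for rec in truth.snvs.itertuples():
            if rec.m_true > 1:
                f = forests[str(rec.segment_id)]
                covering = [
                    e for e in f.edges
                    if e.t_start <= rec.t_true < e.t_end and e.leaf_count == rec.m_true
                ]
                assert covering, f"no edge of multiplicity {rec.m_true} covers t={rec.t_true}"

    def test_vaf_convergence_high_depth(self):
        # diploid-only cohort: empirical VAF of clonal m=1 SNVs ~ f(1)
        cfg = SimConfig(
            cancer_types=["X"], samples_per_type=1, mean_depth=2000.0,
            purity_range=(0.8, 0.8), wgd_probability=0.0, max_gains_per_segment=0,
            background_snvs_per_sample=300, driver_snvs_per_sample=0, seed=6,
        )
        bundle, _ = simulate_sample(cfg, "X", "X_000", rng=_sub_rng(6, "a"))
        snvs = bundle["snvs"]
        depth = snvs["ref_count"] + snvs["alt_count"]
        f1 = expected_vaf(1, 0.8, 2)
        vafs = snvs["alt_count"] / depth
        # SE of the mean VAF over n SNVs at ~2000x each
        se = np.sqrt(f1 * (1 - f1) / (2000 * len(snvs)))
        assert abs(vafs.mean() - f1) < 3 * se

    def test_planted_distribution_recovered_ks(self):
        cfg = SimConfig(
            cancer_types=["X"], samples_per_type=1, mean_depth=30.0,
            pathway_gene_sets={"pw": ["G1", "G2"]},
            pathway_time_distributions={"pw": {"family": "beta", "a": 2, "b": 8}},
            pathway_snvs_per_mutated_sample=600,
            driver_snvs_per_sample=0, seed=8,
        )
        _, truth = simulate_sample(cfg, "X", "X_000", rng=_sub_rng(8, "a"))
        t = truth.snvs.loc[truth.snvs["gene"].str.startswith("G"), "t_true"]
        assert len(t) >= 500
        from scipy.stats import beta

        assert kstest(t, beta(2, 8).cdf).pvalue > 0.01


class TestEmitGainPosterior:
    @pytest.fixture
    def wgd_truth(self):
        cfg = SimConfig(wgd_probability=1.0, max_gains_per_segment=2, n_segments=4, seed=9)
        _, truth = simulate_sample(cfg, "A", "A_000", rng=_sub_rng(9, "a"))
        return truth

    def test_zero_jitter_reproduces_truth(self, wgd_truth):
        g = emit_gain_posterior(wgd_truth, 0.0, 3, rng=_sub_rng(9, "g"))
        merged = g.merge(
            wgd_truth.gain_records, on=["sample", "segment_id", "node_id"], suffixes=("", "_true")
        )
        np.testing.assert_allclose(merged["time"], merged["time_true"])

    def test_truncated_normal_mean(self):
        truth_rec = pd.DataFrame(
            [{"sample": "s", "segment_id": "seg0", "node_id": 0, "parent_id": None,
              "allele": "major", "time": 0.3, "is_wgd": False}]
        )
        from escape_clock.simdata import SampleTruth

        truth = SampleTruth(
            sample="s", cancer_type="X", purity=0.8, has_wgd=False, wgd_time=None,
            gain_records=truth_rec,
            segments=pd.DataFrame([{"sample": "s", "chrom": "chr1", "start": 0, "end": 10,
                                    "segment_id": "seg0", "major": 2, "minor": 1}]),
            snvs=pd.DataFrame(), hla=pd.DataFrame(),
        )
        g = emit_gain_posterior(truth, 0.05, 10_000, rng=np.random.default_rng(0))
        assert abs(g["time"].mean() - 0.3) < 0.01

    def test_wgd_simultaneity_across_segments(self, wgd_truth):
        g = emit_gain_posterior(wgd_truth, 0.05, 20, rng=_sub_rng(9, "g2"))
        wgd_rows = g[g["is_wgd"]]
        for draw, grp in wgd_rows.groupby("draw"):
            assert grp["time"].nunique() == 1

    def test_ancestral_ordering_preserved(self, wgd_truth):
        g = emit_gain_posterior(wgd_truth, 0.1, 25, rng=_sub_rng(9, "g3"))
        for (seg, draw), grp in g.groupby(["segment_id", "draw"]):
            times = dict(zip(grp["node_id"], grp["time"]))
            for rec in grp.itertuples():
                if rec.parent_id != -1:
                    assert times[rec.parent_id] <= rec.time + 1e-12

    def test_times_clipped_to_unit_interval(self, wgd_truth):
        g = emit_gain_posterior(wgd_truth, 0.5, 10, rng=_sub_rng(9, "g4"))
        assert g["time"].between(0, 1).all()


class TestSimulateCohort:
    def test_deterministic_byte_identical(self, tmp_path, small_config):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_cohort(small_config, d1)
        simulate_cohort(small_config, d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel

    def test_manifest_counts(self, tmp_path, small_config):
        cfg = small_config
        out = simulate_cohort(cfg, tmp_path / "c")
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["n_samples"] == len(cfg.cancer_types) * cfg.samples_per_type
        snvs = pd.read_csv(out / "snvs.tsv", sep="\t")
        assert manifest["files"]["snvs.tsv"] == len(snvs)
        assert not (out / ".incomplete").exists()

    def test_point_mass_pathway_earlier_than_drivers(self, tmp_path):
        cfg = SimConfig(
            cancer_types=["X"], samples_per_type=20, mean_depth=30.0,
            pathway_gene_sets={"pwEarly": ["G1", "G2"]},
            pathway_time_distributions={"pwEarly": {"family": "point", "value": 0.1}},
            driver_snvs_per_sample=4, seed=10,
        )
        out = simulate_cohort(cfg, tmp_path / "p")
        truth = pd.read_csv(out / "truth_snvs.tsv", sep="\t")
        pw_mean = truth.loc[truth["gene"].str.startswith("G"), "t_true"].mean()
        drv_mean = truth.loc[truth["gene"].str.startswith("DRV"), "t_true"].mean()
        assert pw_mean < drv_mean

    def test_gain_posterior_readable_round_trip(self, tmp_path, small_config):
        from escape_clock.io import read_gain_posteriors, read_segments

        out = simulate_cohort(small_config, tmp_path / "r")
        segments = read_segments(out / "segments.tsv")
        gps = read_gain_posteriors(out / "gain_posterior.tsv", segments)
        assert len(gps) == 6
        some = next(iter(gps.values()))
        assert len(some) == small_config.n_segments
        assert next(iter(some.values())).S == small_config.draws_S
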