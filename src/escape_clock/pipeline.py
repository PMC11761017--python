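"""Cohort-level orchestration: simulate → time → classify → aggregate.

Each stage consumes and produces the documented table layouts, so a run
can be resumed from any intermediate file; the in-memory helpers here are
what the CLI wires to disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .classify import (
    EARLY_LATE_FRACTION,
    MIN_DETERMINED_SAMPLES,
    RATIO_EARLY,
    RATIO_LATE,
    aggregate_timeline,
    classify_sample_events,
    timing_strata_export,
)
from .loh import AI_P_THRESHOLD, LOH_MINOR_CN_THRESHOLD, time_all_loh
from .timing import (
    DEFAULT_DRAWS,
    DEFAULT_SUBCLONAL_CCF,
    DEFAULT_SUBCLONAL_PRIOR_WEIGHT,
    time_all_snvs,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "time_cohort", "classify_cohort", "loh_cohort", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline configuration; thresholds carry the method's standard
    defaults and any override is echoed into the run manifest."""

    out_dir: str = "escape_clock_run"
    seed: int = 0
    S: int = DEFAULT_DRAWS
    simulate: Optional[dict] = None  # SimConfig fields, or None to use inputs below
    snvs: Optional[str] = None
    segments: Optional[str] = None
    purity: Optional[str] = None
    gains: Optional[str] = None
    hla: Optional[str] = None
    drivers: Optional[str] = None
    gene_sets: Optional[str] = None
    early_late_fraction: float = EARLY_LATE_FRACTION
    ratio_early: float = RATIO_EARLY
    ratio_late: float = RATIO_LATE
    min_determined_samples: int = MIN_DETERMINED_SAMPLES
    loh_p_threshold: float = AI_P_THRESHOLD
    loh_minor_cn_threshold: float = LOH_MINOR_CN_THRESHOLD
    include_subclonal_in_means: bool = True
    exclude_self_from_background: bool = True
    multiplicity_prior: str = "edge_length"
    subclonal_prior_weight: float = DEFAULT_SUBCLONAL_PRIOR_WEIGHT
    subclonal_ccf: float = DEFAULT_SUBCLONAL_CCF
    overrides: dict = dc_field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        defaults = cls()
        overrides = {
            k: v
            for k, v in data.items()
            if hasattr(defaults, k) and k != "overrides" and getattr(defaults, k) != v
        }
        unknown = [k for k in data if not hasattr(defaults, k)]
        if unknown:
            raise ValueError(f"unknown run-config key(s): {unknown}")
        cfg = cls(**data)
        cfg.overrides = overrides
        return cfg


def time_cohort(
    snvs: pd.DataFrame,
    segments: pd.DataFrame,
    purity: pd.DataFrame,
    gain_posteriors: Mapping[str, Mapping],
    S: int = DEFAULT_DRAWS,
    seed: int = 0,
    subclonal_ccf: float = DEFAULT_SUBCLONAL_CCF,
    subclonal_prior_weight: float = DEFAULT_SUBCLONAL_PRIOR_WEIGHT,
    prior_mode: str = "edge_length",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Time every SNV of every sample; returns (table, draws matrix)."""
    purity_by_sample = dict(zip(purity["sample"].astype(str), purity["purity"].astype(float)))
    tables, draw_blocks = [], []
    for sample, snv_grp in snvs.groupby("sample", sort=True):
        sample = str(sample)
        if sample not in purity_by_sample:
            raise ValueError(f"sample {sample} missing from the purity table")
        seg_grp = segments[segments["sample"].astype(str) == sample]
        table, draws = time_all_snvs(
            snv_grp.reset_index(drop=True),
            gain_posteriors.get(sample, {}),
            seg_grp,
            purity_by_sample[sample],
            sample,
            S=S,
            seed=seed,
            subclonal_ccf=subclonal_ccf,
            subclonal_prior_weight=subclonal_prior_weight,
            prior_mode=prior_mode,
        )
        tables.append(table)
        draw_blocks.append(draws)
        n_untimed = int((~table["timed"]).sum())
        if n_untimed:
            logger.info("sample %s: %d/%d SNVs untimed (no segment coverage)", sample, n_untimed, len(table))
    table = pd.concat(tables, ignore_index=True)
    draws = np.vstack(draw_blocks) if draw_blocks else np.empty((0, S))
    return table, draws


def classify_cohort(
    timing: pd.DataFrame,
    draws: np.ndarray,
    driver_genes: list,
    gene_sets: Mapping[str, list],
    cancer_type_by_sample: Mapping[str, str],
    fraction_threshold: float = EARLY_LATE_FRACTION,
    include_subclonal_in_means: bool = True,
    exclude_self_from_background: bool = True,
    gene_events: bool = False,
    nonsynonymous_only: bool = True,
) -> pd.DataFrame:
    """Per-sample early/late calls for pathway (and optionally driver
    gene) events, each against that sample's driver background clock."""
    from .prevalence import is_nonsynonymous

    events = {name: set(genes) for name, genes in gene_sets.items()}
    if gene_events:
        for g in driver_genes:
            events.setdefault(f"gene:{g}", {g})
    timed = timing["timed"].fillna(False).astype(bool).to_numpy()
    keep = timed.copy()
    if nonsynonymous_only:
        keep &= timing["classification"].map(is_nonsynonymous).to_numpy()
    sub = timing[keep].reset_index(drop=True)
    sub_draws = draws[keep]
    if not include_subclonal_in_means:
        sub_draws = np.where(sub_draws == 1.01, np.nan, sub_draws)
    rows = []
    for sample, grp in sub.groupby("sample", sort=True):
        idx = grp.index.to_numpy()
        d = sub_draws[idx]
        if not include_subclonal_in_means:
            # drop SNVs that are subclonal in every draw; remaining NaNs
            # would poison per-draw means, so fall back to clonal draws only
            all_nan = np.isnan(d).all(axis=1)
            grp, d = grp[~all_nan], d[~all_nan]
            d = np.where(np.isnan(d), np.nanmean(d, axis=1, keepdims=True), d)
        calls = classify_sample_events(
            grp.reset_index(drop=True),
            d,
            set(driver_genes),
            events,
            str(sample),
            fraction_threshold=fraction_threshold,
            exclude_self_from_background=exclude_self_from_background,
        )
        if not calls:
            logger.info("sample %s: no driver SNVs, excluded from classification", sample)
        for c in calls:
            rows.append(
                {
                    "sample": c.sample,
                    "cancer_type": cancer_type_by_sample.get(c.sample, "unknown"),
                    "event": c.event,
                    "n_snvs": c.n_snvs,
                    "frac_early": c.frac_early,
                    "frac_late": c.frac_late,
                    "delta_mean": c.delta_mean,
                    "label": c.label,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["sample", "cancer_type", "event", "n_snvs", "frac_early", "frac_late", "delta_mean", "label"],
    )


def loh_cohort(
    hla: pd.DataFrame,
    gain_posteriors: Mapping[str, Mapping],
    purity: pd.DataFrame,
    seed: int = 0,
    p_threshold: float = AI_P_THRESHOLD,
    minor_threshold: float = LOH_MINOR_CN_THRESHOLD,
) -> tuple[pd.DataFrame, dict]:
    """Call HLA LOH and time pre-WGD events against each sample's WGD draws."""
    wgd_by_sample = {}
    for sample, gps in gain_posteriors.items():
        t = eio.sample_wgd_draws(gps)
        if t is not None:
            wgd_by_sample[str(sample)] = t
    wgd_flag = dict(zip(purity["sample"].astype(str), purity["wgd_status"].astype(bool)))
    for sample, flagged in wgd_flag.items():
        if flagged and sample not in wgd_by_sample and sample in gain_posteriors:
            raise ValueError(f"sample {sample}: flagged WGD but gain posterior has no WGD nodes")
    return time_all_loh(
        hla, wgd_by_sample, seed=seed, p_threshold=p_threshold, minor_threshold=minor_threshold
    )


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write outputs plus a manifest.

    Reruns with the same config are byte-identical.
    """
    from . import __version__
    from .simdata import SimConfig, simulate_cohort

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    if config.simulate is not None:
        sim_cfg = SimConfig(**{**config.simulate, "seed": config.seed, "draws_S": config.S})
        sim_dir = out / "cohort"
        simulate_cohort(sim_cfg, sim_dir)
        snvs_path = sim_dir / "snvs.tsv"
        segments_path = sim_dir / "segments.tsv"
        purity_path = sim_dir / "purity.tsv"
        gains_path = sim_dir / "gain_posterior.tsv"
        hla_path = sim_dir / "hla.tsv"
        drivers_path = sim_dir / "drivers.txt"
        gmt_path = sim_dir / "gene_sets.gmt"
    else:
        required = ["snvs", "segments", "purity", "gains", "drivers", "gene_sets"]
        missing = [k for k in required if getattr(config, k) is None]
        if missing:
            raise ValueError(f"run config must set simulate or provide inputs; missing {missing}")
        snvs_path, segments_path = config.snvs, config.segments
        purity_path, gains_path = config.purity, config.gains
        hla_path = config.hla
        drivers_path, gmt_path = config.drivers, config.gene_sets

    snvs = eio.read_snv_table(snvs_path)
    segments = eio.read_segments(segments_path)
    purity = eio.read_purity(purity_path)
    gps = eio.read_gain_posteriors(gains_path, segments)
    drivers = eio.read_gene_list(drivers_path)
    gene_sets = eio.read_gmt(gmt_path)
    counts["snvs"] = len(snvs)
    counts["segments"] = len(segments)
    counts["samples"] = purity["sample"].nunique()

    timing, draws = time_cohort(
        snvs,
        segments,
        purity,
        gps,
        S=config.S,
        seed=config.seed,
        subclonal_ccf=config.subclonal_ccf,
        subclonal_prior_weight=config.subclonal_prior_weight,
        prior_mode=config.multiplicity_prior,
    )
    eio.write_snv_table(timing, out / "timing.tsv")
    eio.write_draws_matrix(timing, draws, out / "timing_draws.tsv")
    counts["timed_snvs"] = int(timing["timed"].sum())
    counts["untimed_snvs"] = int((~timing["timed"]).sum())

    if hla_path is not None:
        loh_table, _ = loh_cohort(
            eio.read_hla(hla_path),
            gps,
            purity,
            seed=config.seed,
            p_threshold=config.loh_p_threshold,
            minor_threshold=config.loh_minor_cn_threshold,
        )
        eio.write_hla(loh_table, out / "loh_timing.tsv")
        counts["hla_loh_calls"] = int(loh_table["is_LOH"].fillna(False).sum())

    if "cancer_type" in purity.columns:
        ctype_col = purity["cancer_type"].astype(str)
    else:
        ctype_col = pd.Series("unknown", index=purity.index)
    ctype = dict(zip(purity["sample"].astype(str), ctype_col))
    calls = classify_cohort(
        timing,
        draws,
        drivers,
        gene_sets,
        ctype,
        fraction_threshold=config.early_late_fraction,
        include_subclonal_in_means=config.include_subclonal_in_means,
        exclude_self_from_background=config.exclude_self_from_background,
    )
    calls.to_csv(out / "calls.tsv", sep="\t", index=False, float_format="%.10g", lineterminator="\n")
    counts["event_calls"] = len(calls)

    timeline = aggregate_timeline(
        calls,
        min_determined=config.min_determined_samples,
        ratio_early=config.ratio_early,
        ratio_late=config.ratio_late,
    )
    timeline.to_csv(out / "timeline.tsv", sep="\t", index=False, float_format="%.10g", lineterminator="\n")
    counts["timeline_entries"] = len(timeline)

    eio.write_json(timing_strata_export(calls), out / "strata.json")

    from .prevalence import prevalence_table

    matrix, prev, leftover = prevalence_table(
        snvs.rename(columns={"class": "classification"}),
        gene_sets,
        sample_types=ctype,
        all_samples=purity["sample"].astype(str),
    )
    matrix.to_csv(out / "mutant_matrix.tsv", sep="\t", lineterminator="\n")
    prev.to_csv(out / "prevalence.tsv", sep="\t", float_format="%.10g", lineterminator="\n")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "S": config.S,
        "thresholds": {
            "early_late_fraction": config.early_late_fraction,
            "ratio_early": config.ratio_early,
            "ratio_late": config.ratio_late,
            "min_determined_samples": config.min_determined_samples,
            "loh_p_threshold": config.loh_p_threshold,
            "loh_minor_cn_threshold": config.loh_minor_cn_threshold,
            "subclonal_marker": 1.01,
        },
        "switches": {
            "include_subclonal_in_means": config.include_subclonal_in_means,
            "exclude_self_from_background": config.exclude_self_from_background,
            "multiplicity_prior": config.multiplicity_prior,
            "subclonal_prior_weight": config.subclonal_prior_weight,
        },
        "overrides": config.overrides,
        "counts": counts,
    }
    eio.write_json(manifest, out / "manifest.json")
    return out
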