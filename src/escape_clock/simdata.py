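"""Synthetic multi-cancer-type cohorts with known ground truth.

Generates everything the downstream pipeline consumes — allele-specific
copy-number segments, SNV read counts, gain-timing posterior draws, HLA
allelic-imbalance tables, purity/ploidy/WGD status — together with truth
tables (true mutation times, multiplicities, gain histories, LOH events)
sufficient to score every stage.

Generative model
----------------
Each segment's copy history starts from one copy per parental allele.
Non-WGD gains duplicate exactly one extant copy at a uniform time; a WGD
duplicates every extant copy of every segment at one shared sample-level
time. Clonal SNVs with a planted time distribution are placed on a copy
chosen uniformly among those extant at the drawn time; SNVs without a
planted distribution land on an edge chosen proportionally to its
time-length with a uniform time within it. Either way the SNV's true
multiplicity is the number of final copies descending from the mutated
lineage. Read depth is Poisson around the configured mean (independent
of local copy number); alt counts are Binomial at the purity- and
copy-number-adjusted expected VAF.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .forest import CopyForest, forest_from_records
from .timing import expected_vaf

__all__ = ["SimConfig", "SampleTruth", "simulate_sample", "emit_gain_posterior", "simulate_cohort"]

HLA_GENES = ("HLA-A", "HLA-B", "HLA-C")
SEGMENT_SPAN = 1_000_000
INCOMPLETE_MARKER = ".incomplete"


@dataclass
class TimeDistribution:
    """Planted true-mutation-time distribution on [0, 1]."""

    family: str  # "uniform" | "beta" | "point"
    params: dict

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "uniform":
            lo = float(self.params.get("low", 0.0))
            hi = float(self.params.get("high", 1.0))
            return float(rng.uniform(lo, hi))
        if self.family == "beta":
            return float(rng.beta(float(self.params["a"]), float(self.params["b"])))
        if self.family == "point":
            return float(self.params["value"])
        raise ValueError(f"unknown time distribution family {self.family!r}")

    @classmethod
    def parse(cls, spec) -> "TimeDistribution":
        if isinstance(spec, TimeDistribution):
            return spec
        if isinstance(spec, dict):
            d = dict(spec)
            family = d.pop("family")
            return cls(family, d.get("params", d))
        if isinstance(spec, (list, tuple)) and len(spec) == 2:
            return cls(spec[0], dict(spec[1]))
        raise ValueError(f"cannot parse time distribution from {spec!r}")


@dataclass
class SimConfig:
    cancer_types: list = dc_field(default_factory=lambda: ["TypeA"])
    samples_per_type: int = 10
    purity_range: tuple = (0.5, 0.9)
    mean_depth: float = 60.0
    wgd_probability: float = 0.5
    wgd_time_range: tuple = (0.2, 0.8)
    max_gains_per_segment: int = 2
    n_segments: int = 10
    driver_genes: list = dc_field(default_factory=lambda: [f"DRV{i}" for i in range(1, 11)])
    pathway_gene_sets: dict = dc_field(default_factory=dict)
    pathway_time_distributions: dict = dc_field(default_factory=dict)
    driver_time_distribution: TimeDistribution = dc_field(
        default_factory=lambda: TimeDistribution("uniform", {})
    )
    driver_snvs_per_sample: int = 5
    pathway_mutation_probability: float = 1.0
    pathway_snvs_per_mutated_sample: int = 3
    background_snvs_per_sample: int = 0
    subclonal_fraction: float = 0.0
    subclonal_ccf_range: tuple = (0.2, 0.8)
    hla_loh_probability: float = 0.2
    gain_posterior_jitter_sd: float = 0.02
    draws_S: int = 250
    seed: int = 0

    def __post_init__(self):
        self.driver_time_distribution = TimeDistribution.parse(self.driver_time_distribution)
        self.pathway_time_distributions = {
            k: TimeDistribution.parse(v) for k, v in self.pathway_time_distributions.items()
        }
        self.purity_range = tuple(float(x) for x in self.purity_range)
        self.subclonal_ccf_range = tuple(float(x) for x in self.subclonal_ccf_range)
        self.wgd_time_range = tuple(float(x) for x in self.wgd_time_range)
        self.validate()

    def validate(self) -> None:
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"purity_range {self.purity_range} must lie within (0, 1]")
        for name, v in [
            ("wgd_probability", self.wgd_probability),
            ("subclonal_fraction", self.subclonal_fraction),
            ("pathway_mutation_probability", self.pathway_mutation_probability),
            ("hla_loh_probability", self.hla_loh_probability),
        ]:
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.subclonal_ccf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"subclonal_ccf_range {self.subclonal_ccf_range} must lie within (0, 1)")
        if self.samples_per_type < 1 or self.n_segments < 1 or self.draws_S < 1:
            raise ValueError("samples_per_type, n_segments and draws_S must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.gain_posterior_jitter_sd < 0:
            raise ValueError("gain_posterior_jitter_sd must be nonnegative")
        for name, genes in self.pathway_gene_sets.items():
            if not genes:
                raise ValueError(f"pathway {name!r} has an empty gene set")

    @property
    def shared_genes(self) -> set:
        """Genes appearing in more than one pathway gene set (allowed, recorded)."""
        seen: dict[str, int] = {}
        for genes in self.pathway_gene_sets.values():
            for g in set(genes):
                seen[g] = seen.get(g, 0) + 1
        return {g for g, n in seen.items() if n > 1}

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("pathway_time_distributions", "driver_time_distribution")
        }
        d["purity_range"] = list(self.purity_range)
        d["subclonal_ccf_range"] = list(self.subclonal_ccf_range)
        d["wgd_time_range"] = list(self.wgd_time_range)
        d["pathway_time_distributions"] = {
            k: {"family": v.family, "params": {kk: float(vv) for kk, vv in v.params.items()}}
            for k, v in self.pathway_time_distributions.items()
        }
        v = self.driver_time_distribution
        d["driver_time_distribution"] = {
            "family": v.family,
            "params": {kk: float(vv) for kk, vv in v.params.items()},
        }
        return d


@dataclass
class SampleTruth:
    sample: str
    cancer_type: str
    purity: float
    has_wgd: bool
    wgd_time: Optional[float]
    gain_records: pd.DataFrame  # sample, segment_id, node_id, parent_id, allele, time, is_wgd
    segments: pd.DataFrame
    snvs: pd.DataFrame  # includes t_true, m_true, is_subclonal, ccf_true
    hla: pd.DataFrame  # hla_gene, loh_present, t_true, pre_wgd

    def forests(self) -> dict[str, CopyForest]:
        out = {}
        cn = {
            str(r.segment_id): (int(r.major), int(r.minor))
            for r in self.segments.itertuples(index=False)
        }
        for seg_id, g in self.gain_records.groupby("segment_id", sort=True):
            records = list(zip(g["node_id"], g["parent_id"], g["allele"], g["time"], g["is_wgd"]))
            out[str(seg_id)] = forest_from_records(records, cn[str(seg_id)], segment_id=str(seg_id))
        for seg_id, c in cn.items():
            if seg_id not in out:
                out[seg_id] = CopyForest([], c[0], c[1], segment_id=seg_id)
        return out


def _sub_rng(seed: int, *key: str) -> np.random.Generator:
    digest = hashlib.sha256("\x00".join(key).encode()).digest()
    spawn = tuple(int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn))


# -- gain-history growth ------------------------------------------------

def _simulate_segment_history(
    rng: np.random.Generator,
    n_gains: int,
    wgd_time: Optional[float],
) -> tuple[list[dict], int, int]:
    """Grow one segment's copy forest; returns (node records, major, minor).

    Copies are (allele, parent_node_id) pairs; each event duplicates one
    copy (or, for WGD, all of them) and the record's parent is the event
    that created the duplicated copy.
    """
    events = sorted([("gain", float(t)) for t in rng.uniform(0, 1, size=n_gains)], key=lambda e: e[1])
    if wgd_time is not None:
        events.append(("wgd", wgd_time))
        events.sort(key=lambda e: e[1])
    copies: list[tuple[str, Optional[int]]] = [("major", None), ("minor", None)]
    records: list[dict] = []
    next_id = 0
    for kind, t in events:
        if kind == "gain":
            i = int(rng.integers(len(copies)))
            allele, parent = copies[i]
            records.append(
                {"node_id": next_id, "parent_id": -1 if parent is None else parent,
                 "allele": allele, "time": t, "is_wgd": False}
            )
            copies[i] = (allele, next_id)
            copies.append((allele, next_id))
            next_id += 1
        else:  # WGD duplicates every extant copy simultaneously
            new_copies = []
            for allele, parent in copies:
                records.append(
                    {"node_id": next_id, "parent_id": -1 if parent is None else parent,
                     "allele": allele, "time": t, "is_wgd": True}
                )
                new_copies.append((allele, next_id))
                new_copies.append((allele, next_id))
                next_id += 1
            copies = new_copies
    major = sum(1 for a, _ in copies if a == "major")
    minor = len(copies) - major
    if minor > major:  # keep the conventional major >= minor labelling
        swap = {"major": "minor", "minor": "major"}
        for r in records:
            r["allele"] = swap[r["allele"]]
        major, minor = minor, major
    return records, major, minor


def _sample_depth(rng: np.random.Generator, mean_depth: float) -> int:
    for _ in range(1000):
        d = int(rng.poisson(mean_depth))
        if d >= 1:
            return d
    raise RuntimeError(f"could not draw a positive depth at mean_depth={mean_depth}")


def _place_at_time(forest: CopyForest, t: float, rng: np.random.Generator) -> int:
    """Multiplicity of an SNV arising at time t on a uniformly chosen
    extant copy."""
    edges = forest.edges_covering(t)
    e = edges[int(rng.integers(len(edges)))]
    return e.leaf_count


def _place_by_length(forest: CopyForest, rng: np.random.Generator) -> tuple[float, int]:
    """(time, multiplicity) for an SNV landing uniformly per copy-time."""
    lengths = np.array([e.length for e in forest.edges])
    p = lengths / lengths.sum()
    i = int(rng.choice(len(p), p=p))
    e = forest.edges[i]
    return float(rng.uniform(e.t_start, e.t_end)), e.leaf_count


def _gene_layout(config: SimConfig) -> dict[str, tuple[int, int]]:
    """gene -> (segment index, rank within segment), deterministic
    round-robin so every pathway spans several copy-number contexts."""
    genes: list[str] = list(dict.fromkeys(config.driver_genes))
    for name in sorted(config.pathway_gene_sets):
        for g in config.pathway_gene_sets[name]:
            if g not in genes:
                genes.append(g)
    return {g: (i % config.n_segments, i // config.n_segments) for i, g in enumerate(genes)}


def simulate_sample(
    config: SimConfig,
    cancer_type: str,
    sample: str,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict, SampleTruth]:
    """Simulate one sample's input bundle and its ground truth.

    The bundle maps table names (snvs, segments, purity, hla) to
    DataFrames in the on-disk layouts of :mod:`escape_clock.io`.
    """
    if rng is None:
        rng = _sub_rng(config.seed, "sample", sample)
    purity = float(rng.uniform(*config.purity_range))
    has_wgd = bool(rng.random() < config.wgd_probability)
    wgd_time = float(rng.uniform(*config.wgd_time_range)) if has_wgd else None

    seg_rows, gain_rows = [], []
    forests: dict[str, CopyForest] = {}
    for j in range(config.n_segments):
        seg_id = f"seg{j}"
        n_gains = int(rng.integers(0, config.max_gains_per_segment + 1))
        records, major, minor = _simulate_segment_history(rng, n_gains, wgd_time)
        for r in records:
            gain_rows.append({"sample": sample, "segment_id": seg_id, **r})
        seg_rows.append(
            {
                "sample": sample,
                "chrom": f"chr{j + 1}",
                "start": 0,
                "end": SEGMENT_SPAN,
                "segment_id": seg_id,
                "major": major,
                "minor": minor,
            }
        )
        forests[seg_id] = forest_from_records(
            [(r["node_id"], r["parent_id"], r["allele"], r["time"], r["is_wgd"]) for r in records],
            (major, minor),
            segment_id=seg_id,
        )
    segments = pd.DataFrame(seg_rows)
    gain_records = pd.DataFrame(
        gain_rows, columns=["sample", "segment_id", "node_id", "parent_id", "allele", "time", "is_wgd"]
    )

    layout = _gene_layout(config)
    snv_rows = []
    pos_counter: dict[str, int] = {}

    def emit_snv(gene: str, classification: str, dist: Optional[TimeDistribution], seg_idx: int):
        seg_id = f"seg{seg_idx}"
        forest = forests[seg_id]
        n_t = forest.total_cn
        subclonal = bool(rng.random() < config.subclonal_fraction)
        if subclonal:
            ccf = float(rng.uniform(*config.subclonal_ccf_range))
            t_true, m_true = np.nan, 1
            f = expected_vaf("subclonal", purity, n_t, ccf=ccf)
        else:
            ccf = np.nan
            if dist is not None:
                t_true = dist.sample(rng)
                m_true = _place_at_time(forest, t_true, rng)
            else:
                t_true, m_true = _place_by_length(forest, rng)
            f = expected_vaf(m_true, purity, n_t)
        depth = _sample_depth(rng, config.mean_depth)
        alt = int(rng.binomial(depth, f))
        if gene in layout:
            base = 1000 * (layout[gene][1] + 1)
            key = gene
        else:  # background SNVs share a per-chromosome counter
            base = 500_000
            key = f"__bg__{seg_idx}"
        k = pos_counter.get(key, 0)
        pos_counter[key] = k + 1
        snv_rows.append(
            {
                "sample": sample,
                "chrom": f"chr{seg_idx + 1}",
                "pos": base + k,
                "ref": "A",
                "alt": "T",
                "gene": gene,
                "classification": classification,
                "ref_count": depth - alt,
                "alt_count": alt,
                "segment_id": seg_id,
                "t_true": t_true,
                "m_true": m_true,
                "is_subclonal": subclonal,
                "ccf_true": ccf,
            }
        )

    drivers = list(dict.fromkeys(config.driver_genes))
    for _ in range(config.driver_snvs_per_sample):
        gene = drivers[int(rng.integers(len(drivers)))]
        emit_snv(gene, "Missense_Mutation", config.driver_time_distribution, layout[gene][0])
    for name in sorted(config.pathway_gene_sets):
        genes = config.pathway_gene_sets[name]
        if not genes:
            raise ValueError(f"pathway {name!r} has an empty gene set")
        if rng.random() >= config.pathway_mutation_probability:
            continue
        dist = config.pathway_time_distributions.get(name)
        for _ in range(config.pathway_snvs_per_mutated_sample):
            gene = genes[int(rng.integers(len(genes)))]
            emit_snv(gene, "Missense_Mutation", dist, layout[gene][0])
    for i in range(config.background_snvs_per_sample):
        seg_idx = int(rng.integers(config.n_segments))
        emit_snv(f"BG{i}", "IGR", None, seg_idx)

    snvs = pd.DataFrame(
        snv_rows,
        columns=[
            "sample", "chrom", "pos", "ref", "alt", "gene", "classification",
            "ref_count", "alt_count", "segment_id", "t_true", "m_true",
            "is_subclonal", "ccf_true",
        ],
    )

    hla_rows = []
    for hla_gene in HLA_GENES:
        loh = bool(rng.random() < config.hla_loh_probability)
        if loh:
            t_loh = float(rng.uniform(0, 1))
            pre = has_wgd and t_loh < wgd_time
            minor_cn, major_cn = 0.0, (2.0 if pre else 1.0)
            p = float(rng.uniform(1e-6, 0.0099))
        else:
            t_loh, pre = np.nan, False
            minor_cn = 1.0
            major_cn = 2.0 if has_wgd else 1.0
            p = float(rng.uniform(0.02, 1.0))
        hla_rows.append(
            {
                "sample": sample,
                "hla_gene": hla_gene,
                "ai_p_value": p,
                "minor_cn": minor_cn,
                "major_cn": major_cn,
                "loh_present": loh,
                "t_true": t_loh,
                "pre_wgd": pre,
            }
        )
    hla = pd.DataFrame(hla_rows)

    ploidy = float((segments["major"] + segments["minor"]).mean())
    purity_row = pd.DataFrame(
        [
            {
                "sample": sample,
                "purity": purity,
                "ploidy": ploidy,
                "wgd_status": has_wgd,
                "cancer_type": cancer_type,
            }
        ]
    )
    bundle = {
        "snvs": snvs[
            ["sample", "chrom", "pos", "ref", "alt", "gene", "classification", "ref_count", "alt_count"]
        ].copy(),
        "segments": segments,
        "purity": purity_row,
        "hla": hla[["sample", "hla_gene", "ai_p_value", "minor_cn", "major_cn"]].copy(),
    }
    truth = SampleTruth(
        sample=sample,
        cancer_type=cancer_type,
        purity=purity,
        has_wgd=has_wgd,
        wgd_time=wgd_time,
        gain_records=gain_records,
        segments=segments,
        snvs=snvs,
        hla=hla,
    )
    return bundle, truth


# -- gain-posterior emission --------------------------------------------

def emit_gain_posterior(
    truth: SampleTruth,
    jitter_sd: float,
    S: int,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Fabricate posterior draws of the sample's gain times.

    Each draw adds truncated-normal noise (clipped to [0, 1]) to the true
    gain times while preserving ancestral ordering (a node never precedes
    its parent nor outlives a WGD descendant) and WGD simultaneity across
    segments within a draw. ``jitter_sd=0`` reproduces the truth exactly.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be nonnegative")
    if rng is None:
        rng = _sub_rng(0, "gains", truth.sample)
    if truth.has_wgd:
        wgd_draws = np.clip(truth.wgd_time + rng.normal(0, jitter_sd, size=S), 0.0, 1.0)
    else:
        wgd_draws = None

    rows = []
    for seg_id, g in truth.gain_records.groupby("segment_id", sort=True):
        nodes = g.sort_values("node_id").to_dict("records")
        by_id = {r["node_id"]: r for r in nodes}
        children: dict = {}
        for r in nodes:
            if not _is_root(r["parent_id"]):
                children.setdefault(int(r["parent_id"]), []).append(r["node_id"])
        # does a WGD event lie at-or-below each node's subtree?
        has_wgd_below: dict[int, bool] = {}

        def _wgd_below(nid: int) -> bool:
            if nid in has_wgd_below:
                return has_wgd_below[nid]
            r = by_id[nid]
            v = bool(r["is_wgd"]) or any(_wgd_below(c) for c in children.get(nid, []))
            has_wgd_below[nid] = v
            return v

        order = _topological_order(nodes)
        for s in range(S):
            final: dict[int, float] = {}
            for nid in order:
                r = by_id[nid]
                parent = r["parent_id"]
                lower = 0.0 if _is_root(parent) else final[int(parent)]
                if bool(r["is_wgd"]):
                    t = float(wgd_draws[s])
                    t = min(max(t, lower), 1.0)
                else:
                    upper = float(wgd_draws[s]) if (wgd_draws is not None and _wgd_below(nid) and not r["is_wgd"]) else 1.0
                    t = float(np.clip(r["time"] + rng.normal(0, jitter_sd), lower, upper))
                final[nid] = t
                rows.append(
                    {
                        "sample": truth.sample,
                        "segment_id": seg_id,
                        "draw": s,
                        "node_id": nid,
                        "parent_id": -1 if _is_root(parent) else int(parent),
                        "allele": r["allele"],
                        "time": t,
                        "is_wgd": bool(r["is_wgd"]),
                    }
                )
    return pd.DataFrame(rows, columns=eio.GAIN_COLUMNS)


def _is_root(parent_id) -> bool:
    return parent_id is None or pd.isna(parent_id) or int(parent_id) < 0


def _topological_order(nodes: list[dict]) -> list[int]:
    """Node ids parent-before-child."""
    by_id = {r["node_id"]: r for r in nodes}
    order: list[int] = []
    seen: set[int] = set()

    def visit(nid: int) -> None:
        if nid in seen:
            return
        r = by_id[nid]
        p = r["parent_id"]
        if not _is_root(p):
            visit(int(p))
        seen.add(nid)
        order.append(nid)

    for r in nodes:
        visit(r["node_id"])
    return order


# -- cohort -------------------------------------------------------------

def simulate_cohort(config: SimConfig, out_dir) -> Path:
    """Simulate the full cohort and write the on-disk bundle.

    Deterministic given the config seed: the same config produces a
    byte-identical bundle. A marker file flags interrupted writes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / INCOMPLETE_MARKER
    marker.write_text("in progress\n")

    bundles, truths, gain_tables = [], [], []
    sample_entries = []
    for ctype in config.cancer_types:
        for i in range(config.samples_per_type):
            sample = f"{ctype}_{i:03d}"
            rng = _sub_rng(config.seed, "sample", sample)
            bundle, truth = simulate_sample(config, ctype, sample, rng=rng)
            gains = emit_gain_posterior(
                truth,
                config.gain_posterior_jitter_sd,
                config.draws_S,
                rng=_sub_rng(config.seed, "gains", sample),
            )
            bundles.append(bundle)
            truths.append(truth)
            gain_tables.append(gains)
            sample_entries.append(sample)

    snvs = pd.concat([b["snvs"] for b in bundles], ignore_index=True)
    segments = pd.concat([b["segments"] for b in bundles], ignore_index=True)
    purity = pd.concat([b["purity"] for b in bundles], ignore_index=True)
    hla = pd.concat([b["hla"] for b in bundles], ignore_index=True)
    gains = pd.concat([g for g in gain_tables if len(g)] or gain_tables[:1], ignore_index=True)

    truth_snvs = pd.concat([t.snvs for t in truths], ignore_index=True)
    gain_frames = [t.gain_records for t in truths if len(t.gain_records)]
    truth_gains = (
        pd.concat(gain_frames, ignore_index=True)
        if gain_frames
        else truths[0].gain_records
    )
    truth_hla = pd.concat(
        [t.hla.assign(sample=t.sample)[["sample", "hla_gene", "loh_present", "t_true", "pre_wgd"]] for t in truths],
        ignore_index=True,
    )
    truth_samples = pd.DataFrame(
        [
            {
                "sample": t.sample,
                "cancer_type": t.cancer_type,
                "purity": t.purity,
                "wgd_status": t.has_wgd,
                "wgd_time": np.nan if t.wgd_time is None else t.wgd_time,
            }
            for t in truths
        ]
    )

    files = {
        "snvs.tsv": snvs,
        "segments.tsv": segments,
        "purity.tsv": purity,
        "hla.tsv": hla,
        "gain_posterior.tsv": gains,
        "truth_snvs.tsv": truth_snvs,
        "truth_gains.tsv": truth_gains,
        "truth_hla.tsv": truth_hla,
        "truth_samples.tsv": truth_samples,
    }
    manifest_files = {}
    for name, df in files.items():
        df.to_csv(out / name, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
        manifest_files[name] = int(len(df))

    vcf_dir = out / "vcf"
    for b in bundles:
        s = str(b["snvs"]["sample"].iloc[0]) if len(b["snvs"]) else None
        if s is None:
            continue
        eio.write_vcf(b["snvs"], vcf_dir / f"{s}.vcf", s)
        manifest_files[f"vcf/{s}.vcf"] = int(len(b["snvs"]))

    eio.write_gmt(config.pathway_gene_sets, out / "gene_sets.gmt", description="simulated")
    eio.write_gene_list(config.driver_genes, out / "drivers.txt")
    manifest_files["gene_sets.gmt"] = len(config.pathway_gene_sets)
    manifest_files["drivers.txt"] = len(config.driver_genes)

    manifest = {
        "seed": config.seed,
        "n_samples": len(sample_entries),
        "samples": sample_entries,
        "coordinates": "0-based half-open; SNV pos 0-based",
        "shared_pathway_genes": sorted(config.shared_genes),
        "config": config.to_dict(),
        "files": manifest_files,
    }
    eio.write_json(manifest, out / "manifest.json")
    marker.unlink()
    return out
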