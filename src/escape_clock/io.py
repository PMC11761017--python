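"""Readers and writers for the pipeline's on-disk formats.

All tables are plain TSV; coordinates are 0-based half-open. The SNV
table also round-trips through a minimal single-sample VCF (INFO
``gene=``/``class=``; FORMAT ``AD`` with ref,alt depths).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .forest import CopyForest, ForestError, GainPosterior, forest_from_records

__all__ = [
    "read_snv_table",
    "write_snv_table",
    "read_vcf",
    "write_vcf",
    "read_segments",
    "write_segments",
    "read_purity",
    "write_purity",
    "read_hla",
    "write_hla",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "read_gain_posteriors",
    "write_gain_posteriors",
    "read_draws_matrix",
    "write_draws_matrix",
    "write_json",
]

PathLike = Union[str, Path]

SNV_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "gene", "classification", "ref_count", "alt_count"]
SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "segment_id", "major", "minor"]
PURITY_COLUMNS = ["sample", "purity", "ploidy", "wgd_status", "cancer_type"]
HLA_COLUMNS = ["sample", "hla_gene", "ai_p_value", "minor_cn", "major_cn"]
GAIN_COLUMNS = ["sample", "segment_id", "draw", "node_id", "parent_id", "allele", "time", "is_wgd"]

_FLOAT_FMT = "%.10g"


def _read_tsv(path: PathLike, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def _write_tsv(df: pd.DataFrame, path: PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_snv_table(path: PathLike) -> pd.DataFrame:
    return _read_tsv(path, ["sample", "chrom", "pos", "ref_count", "alt_count"])


def write_snv_table(df: pd.DataFrame, path: PathLike) -> None:
    _write_tsv(df, path)


def read_segments(path: PathLike) -> pd.DataFrame:
    return _read_tsv(path, ["sample", "chrom", "start", "end", "segment_id", "major", "minor"])


def write_segments(df: pd.DataFrame, path: PathLike) -> None:
    _write_tsv(df, path)


def read_purity(path: PathLike) -> pd.DataFrame:
    return _read_tsv(path, ["sample", "purity", "ploidy", "wgd_status"])


def write_purity(df: pd.DataFrame, path: PathLike) -> None:
    _write_tsv(df, path)


def read_hla(path: PathLike) -> pd.DataFrame:
    return _read_tsv(path, HLA_COLUMNS)


def write_hla(df: pd.DataFrame, path: PathLike) -> None:
    _write_tsv(df, path)


# -- VCF ----------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=gene,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=class,Number=1,Type=String,Description="Variant classification">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_vcf(snvs: pd.DataFrame, path: PathLike, sample: str) -> None:
    """Write one sample's SNVs as a minimal VCF (POS is 1-based)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(sample=sample))
        for rec in snvs.itertuples(index=False):
            info = f"gene={rec.gene};class={rec.classification}"
            fh.write(
                f"{rec.chrom}\t{int(rec.pos) + 1}\t.\t{rec.ref}\t{rec.alt}\t.\t.\t"
                f"{info}\tAD\t{int(rec.ref_count)},{int(rec.alt_count)}\n"
            )


def read_vcf(path: PathLike, sample: Optional[str] = None) -> pd.DataFrame:
    """Read a minimal VCF back into the SNV-table layout (0-based pos)."""
    rows = []
    with open(path) as fh:
        header_sample = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                header_sample = fields[9] if len(fields) > 9 else None
                continue
            f = line.split("\t")
            info = dict(kv.split("=", 1) for kv in f[7].split(";") if "=" in kv)
            ad = f[9].split(":")[f[8].split(":").index("AD")].split(",")
            rows.append(
                {
                    "sample": sample or header_sample or "sample",
                    "chrom": f[0],
                    "pos": int(f[1]) - 1,
                    "ref": f[3],
                    "alt": f[4],
                    "gene": info.get("gene", ""),
                    "classification": info.get("class", ""),
                    "ref_count": int(ad[0]),
                    "alt_count": int(ad[1]),
                }
            )
    return pd.DataFrame(rows, columns=SNV_COLUMNS)


# -- gene sets ----------------------------------------------------------

def read_gmt(path: PathLike) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: Mapping[str, list], path: PathLike, description: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(gene_sets[name])
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_gene_list(path: PathLike) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def write_gene_list(genes: list, path: PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("".join(f"{g}\n" for g in genes))


# -- gain posteriors ----------------------------------------------------

def write_gain_posteriors(rows: pd.DataFrame, path: PathLike) -> None:
    """Write the long-format gain-posterior table (one row per node per
    draw per segment per sample)."""
    _write_tsv(rows[GAIN_COLUMNS], path)


def gain_posteriors_from_table(
    df: pd.DataFrame,
    segments: pd.DataFrame,
    validate_wgd: bool = True,
) -> dict[str, dict[str, GainPosterior]]:
    """Build per-sample GainPosterior maps from the long-format table.

    Segments with no gain rows get a degenerate "no gain" forest repeated
    for every draw index, so every segment in ``segments`` is
    represented. Extra columns are tolerated. Per-sample WGD simultaneity
    is validated across segments within each draw.
    """
    missing = [c for c in GAIN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gain posterior table missing column(s) {missing}")
    seg_cn = {
        (str(r.sample), str(r.segment_id)): (int(r.major), int(r.minor))
        for r in segments.itertuples(index=False)
    }
    out: dict[str, dict[str, GainPosterior]] = {}
    n_draws_global = int(df["draw"].max()) + 1 if len(df) else 1
    for (sample, seg_id), g in df.groupby(["sample", "segment_id"], sort=True):
        sample, seg_id = str(sample), str(seg_id)
        cn = seg_cn.get((sample, seg_id))
        if cn is None:
            raise ValueError(f"gain posterior references unknown segment {seg_id} of {sample}")
        g = g.sort_values(["draw", "node_id"])
        node_ids = np.sort(g["node_id"].unique())
        n_nodes = len(node_ids)
        if len(g) % n_nodes:
            raise ValueError(
                f"segment {seg_id} of {sample}: draws carry different node sets"
            )
        first = g.iloc[:n_nodes]
        topology = forest_from_records(
            list(zip(first["node_id"], first["parent_id"], first["allele"], first["time"], first["is_wgd"])),
            cn,
            segment_id=seg_id,
        )
        times = g["time"].to_numpy(dtype=float).reshape(-1, n_nodes)
        out.setdefault(sample, {})[seg_id] = GainPosterior(
            seg_id, topology=topology, times=times
        )
    # ungained segments: one forest repeated for every draw
    for (sample, seg_id), cn in seg_cn.items():
        if seg_id not in out.get(sample, {}):
            f = CopyForest([], cn[0], cn[1], segment_id=seg_id)
            out.setdefault(sample, {})[seg_id] = GainPosterior(
                seg_id, topology=f, times=np.zeros((n_draws_global, 0))
            )
    if validate_wgd:
        for sample, gps in out.items():
            _check_wgd_simultaneity(sample, gps)
    return out


def read_gain_posteriors(
    path: PathLike,
    segments: pd.DataFrame,
    validate_wgd: bool = True,
) -> dict[str, dict[str, GainPosterior]]:
    """Parse the gain-posterior TSV into per-sample GainPosterior maps."""
    df = _read_tsv(path, GAIN_COLUMNS)
    return gain_posteriors_from_table(df, segments, validate_wgd=validate_wgd)


def _check_wgd_simultaneity(sample: str, gps: Mapping[str, GainPosterior]) -> None:
    wgd = {sid: gp.wgd_times() for sid, gp in gps.items()}
    wgd = {sid: t for sid, t in wgd.items() if t is not None}
    if len(wgd) < 2:
        return
    ref_sid, ref = next(iter(wgd.items()))
    for sid, t in wgd.items():
        if len(t) != len(ref):
            raise ForestError(
                f"sample {sample}: segments {ref_sid} and {sid} have different WGD draw counts"
            )
        if not np.allclose(t, ref, atol=1e-9):
            raise ForestError(
                f"sample {sample}: WGD times differ between segments {ref_sid} and {sid} "
                f"within a draw (simultaneity violated)"
            )


def sample_wgd_draws(
    gps: Mapping[str, GainPosterior],
) -> Optional[np.ndarray]:
    """Per-draw WGD times for a sample (from any WGD-bearing segment)."""
    for gp in gps.values():
        t = gp.wgd_times()
        if t is not None:
            return t
    return None


# -- per-SNV draw matrices ----------------------------------------------

def write_draws_matrix(meta: pd.DataFrame, draws: np.ndarray, path: PathLike) -> None:
    """Sidecar with one row per SNV: key columns + draw_1..draw_S."""
    S = draws.shape[1]
    block = pd.DataFrame(draws, columns=[f"draw_{j + 1}" for j in range(S)])
    wide = pd.concat(
        [meta[["sample", "chrom", "pos", "gene", "classification"]].reset_index(drop=True), block],
        axis=1,
    )
    _write_tsv(wide, path)


def read_draws_matrix(path: PathLike) -> tuple[pd.DataFrame, np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    draw_cols = [c for c in df.columns if c.startswith("draw_")]
    draw_cols.sort(key=lambda c: int(c.split("_")[1]))
    draws = df[draw_cols].to_numpy(dtype=float)
    meta = df.drop(columns=draw_cols)
    return meta, draws


def write_json(obj, path: PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
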