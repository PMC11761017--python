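"""HLA LOH calling from allelic-imbalance summaries and timing vs WGD.

Calls follow the two-threshold rule (allelic imbalance when the AI
p-value is below 0.01; LOH when additionally the minor-allele copy number
is below 0.5). An LOH in a whole-genome-doubled tumor with minor copy
number 0 and major copy number above 1 must predate the doubling — the
lost allele is unlikely to have been lost twice — and is assigned a
uniform time between 0 and each posterior WGD time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "LOHCall",
    "LOHTiming",
    "call_hla_loh",
    "time_loh_vs_wgd",
    "time_all_loh",
    "AI_P_THRESHOLD",
    "LOH_MINOR_CN_THRESHOLD",
]

AI_P_THRESHOLD = 0.01
LOH_MINOR_CN_THRESHOLD = 0.5
#: real-valued estimates of "minor copy number equal to 0" pass below this
MINOR_CN_ZERO_TOL = 0.05
#: real-valued estimates of "major copy number greater than 1" pass above this
MAJOR_CN_GT_ONE = 1.5


@dataclass(frozen=True)
class LOHCall:
    sample: str
    hla_gene: str
    ai_p_value: float
    minor_cn: float
    major_cn: float
    is_AI: Optional[bool]  # None = no-call (missing inputs)
    is_LOH: Optional[bool]


@dataclass
class LOHTiming:
    sample: str
    hla_gene: str
    status: str  # "pre_wgd" | "undetermined"
    draws: np.ndarray = field(default_factory=lambda: np.empty(0))


def call_hla_loh(
    ai_p_value: float,
    minor_cn: float,
    p_threshold: float = AI_P_THRESHOLD,
    minor_threshold: float = LOH_MINOR_CN_THRESHOLD,
) -> tuple[Optional[bool], Optional[bool]]:
    """(is_AI, is_LOH) for one HLA allele; (None, None) on missing values."""
    if ai_p_value is None or minor_cn is None:
        return None, None
    if isinstance(ai_p_value, float) and math.isnan(ai_p_value):
        return None, None
    if isinstance(minor_cn, float) and math.isnan(minor_cn):
        return None, None
    if not (0.0 <= ai_p_value <= 1.0):
        raise ValueError(f"p-value {ai_p_value} outside [0, 1]")
    if minor_cn < 0:
        raise ValueError(f"negative minor copy number {minor_cn}")
    is_ai = ai_p_value < p_threshold
    is_loh = is_ai and minor_cn < minor_threshold
    return is_ai, is_loh


def time_loh_vs_wgd(
    loh: LOHCall,
    wgd_draws: Optional[np.ndarray],
    rng: np.random.Generator,
    sample_has_wgd: Optional[bool] = None,
    minor_zero_tol: float = MINOR_CN_ZERO_TOL,
    major_gt_one: float = MAJOR_CN_GT_ONE,
    integer_cn: bool = False,
) -> LOHTiming:
    """Time an HLA LOH event relative to whole-genome doubling.

    Pre-WGD status requires a doubled sample with minor copy number 0 and
    major copy number above 1; its timing draws are Uniform(0, t_WGD) per
    paired WGD posterior draw. Anything else is undetermined with no
    draws. Real-valued copy-number estimates use tolerances
    (``minor_zero_tol``, ``major_gt_one``); set ``integer_cn`` for exact
    integer comparisons.
    """
    if not loh.is_LOH:
        raise ValueError("time_loh_vs_wgd requires an LOH-positive call")
    if sample_has_wgd is None:
        sample_has_wgd = wgd_draws is not None
    if sample_has_wgd and wgd_draws is None:
        raise ValueError(
            f"sample {loh.sample}: flagged WGD but no WGD timing draws supplied"
        )
    if not sample_has_wgd:
        return LOHTiming(loh.sample, loh.hla_gene, "undetermined")
    if integer_cn:
        pre = loh.minor_cn == 0 and loh.major_cn > 1
    else:
        pre = loh.minor_cn < minor_zero_tol and loh.major_cn > major_gt_one
    if not pre:
        return LOHTiming(loh.sample, loh.hla_gene, "undetermined")
    wgd = np.asarray(wgd_draws, dtype=float)
    draws = rng.random(wgd.shape) * wgd
    return LOHTiming(loh.sample, loh.hla_gene, "pre_wgd", draws)


def time_all_loh(
    hla: pd.DataFrame,
    wgd_draws_by_sample: dict,
    seed: int = 0,
    p_threshold: float = AI_P_THRESHOLD,
    minor_threshold: float = LOH_MINOR_CN_THRESHOLD,
    integer_cn: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Call and time HLA LOH for a cohort table.

    ``hla`` needs columns sample, hla_gene, ai_p_value, minor_cn,
    major_cn. Returns a summary table plus a mapping
    (sample, hla_gene) -> timing draws for pre-WGD events.
    """
    rows = []
    draw_map: dict[tuple[str, str], np.ndarray] = {}
    for rec in hla.itertuples(index=False):
        is_ai, is_loh = call_hla_loh(
            rec.ai_p_value, rec.minor_cn, p_threshold, minor_threshold
        )
        call = LOHCall(
            str(rec.sample),
            str(rec.hla_gene),
            float(rec.ai_p_value),
            float(rec.minor_cn),
            float(rec.major_cn),
            is_ai,
            is_loh,
        )
        status = ""
        mean_time = np.nan
        if is_loh:
            wgd = wgd_draws_by_sample.get(call.sample)
            rng = _loh_rng(seed, call.sample, call.hla_gene)
            timing = time_loh_vs_wgd(call, wgd, rng, integer_cn=integer_cn)
            status = timing.status
            if timing.status == "pre_wgd":
                draw_map[(call.sample, call.hla_gene)] = timing.draws
                mean_time = float(timing.draws.mean())
        rows.append(
            {
                "sample": call.sample,
                "hla_gene": call.hla_gene,
                "ai_p_value": call.ai_p_value,
                "minor_cn": call.minor_cn,
                "major_cn": call.major_cn,
                "is_AI": is_ai,
                "is_LOH": is_loh,
                "timing_status": status,
                "mean_time": mean_time,
            }
        )
    return pd.DataFrame(rows), draw_map


def _loh_rng(seed: int, sample: str, hla_gene: str) -> np.random.Generator:
    import hashlib

    digest = hashlib.sha256(f"loh\x00{sample}\x00{hla_gene}".encode()).digest()
    key = tuple(int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))
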