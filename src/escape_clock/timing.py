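"""Posterior timing of somatic SNVs via hierarchical sampling.

For each SNV and each posterior draw of its segment's gain history, a
multiplicity state is sampled from the read-count posterior, then a
mutation time is drawn uniformly on an edge of matching multiplicity.
Subclonal draws are marked with the sentinel value 1.01; all other draws
lie in [0, 1].
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.stats import binom

from .forest import CopyForest, GainPosterior, total_length_by_multiplicity

__all__ = [
    "SUBCLONAL",
    "SUBCLONAL_TIME",
    "DEFAULT_DRAWS",
    "MultiplicityPosterior",
    "SNVTimingPosterior",
    "expected_vaf",
    "multiplicity_posterior",
    "sample_snv_timing",
    "time_all_snvs",
    "snv_rng",
]

SUBCLONAL = "subclonal"
#: Sentinel timing value assigned to subclonal draws.
SUBCLONAL_TIME = 1.01
DEFAULT_DRAWS = 250
DEFAULT_SUBCLONAL_CCF = 0.5
DEFAULT_SUBCLONAL_PRIOR_WEIGHT = 0.1


def expected_vaf(
    m_or_ccf: Union[int, float, str],
    rho: float,
    n_t: int,
    ccf: Optional[float] = None,
) -> float:
    """Expected variant allele fraction of an SNV.

    A clonal SNV at multiplicity ``m`` in a tumor of purity ``rho`` on a
    segment of total copy number ``n_t`` (normal cells diploid) has

        f = m * rho / (n_t * rho + 2 * (1 - rho)).

    A subclonal SNV (pass ``m_or_ccf=SUBCLONAL`` with ``ccf``) carries a
    single copy in a fraction CCF of tumor cells, so m is replaced by CCF.
    """
    if not (0.0 < rho <= 1.0):
        raise ValueError(f"purity must be in (0, 1], got {rho}")
    if n_t < 1:
        raise ValueError(f"total copy number must be >= 1, got {n_t}")
    denom = n_t * rho + 2.0 * (1.0 - rho)
    if m_or_ccf == SUBCLONAL:
        if ccf is None or not (0.0 < ccf < 1.0):
            raise ValueError(f"subclonal state requires CCF in (0, 1), got {ccf}")
        return ccf * rho / denom
    m = int(m_or_ccf)
    if not (1 <= m <= n_t):
        raise ValueError(f"impossible multiplicity m={m} for total copy number {n_t}")
    return m * rho / denom


@dataclass
class MultiplicityPosterior:
    """Posterior over multiplicity states for one SNV under one forest.

    ``states`` lists clonal multiplicities (ints) and possibly the
    :data:`SUBCLONAL` marker; ``probs`` are the matching posterior
    probabilities and ``vafs`` the expected VAF of each state.
    """

    states: list
    probs: np.ndarray
    vafs: np.ndarray
    alt: int
    depth: int
    rho: float
    n_t: int
    subclonal_ccf: float

    def prob_of(self, state) -> float:
        for s, p in zip(self.states, self.probs):
            if s == state:
                return float(p)
        return 0.0

    @property
    def modal_state(self):
        return self.states[int(np.argmax(self.probs))]


def _state_priors(
    forest: CopyForest,
    subclonal_prior_weight: float,
    prior_mode: str,
) -> tuple[list, np.ndarray]:
    lengths = total_length_by_multiplicity(forest)
    ms = sorted(lengths)
    total = sum(lengths.values())
    if prior_mode == "edge_length":
        prior = [lengths[m] for m in ms]
    elif prior_mode == "uniform":
        prior = [1.0 for _ in ms]
    else:
        raise ValueError(f"unknown prior mode {prior_mode!r}")
    states: list = list(ms)
    if subclonal_prior_weight > 0:
        states.append(SUBCLONAL)
        if prior_mode == "edge_length":
            prior.append(subclonal_prior_weight * total)
        else:
            prior.append(subclonal_prior_weight)
    return states, np.asarray(prior, dtype=float)


def multiplicity_posterior(
    alt: int,
    depth: int,
    forest: CopyForest,
    rho: float,
    subclonal_ccf: float = DEFAULT_SUBCLONAL_CCF,
    subclonal_prior_weight: float = DEFAULT_SUBCLONAL_PRIOR_WEIGHT,
    prior_mode: str = "edge_length",
) -> MultiplicityPosterior:
    """Posterior over multiplicity states given alt/depth read counts.

    P(state) is proportional to prior(state) * Binomial(alt | depth,
    f(state)). The default prior weights each clonal multiplicity by the
    total edge time-length carrying it (uniform mutation arrival on the
    copy forest); the subclonal state gets ``subclonal_prior_weight``
    times the total forest length.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not (0 <= alt <= depth):
        raise ValueError(f"alt count {alt} outside [0, depth={depth}]")
    states, prior = _state_priors(forest, subclonal_prior_weight, prior_mode)
    if not np.any(prior > 0):
        raise ValueError(
            f"segment {forest.segment_id}: all state priors are zero (degenerate forest)"
        )
    vafs = np.array(
        [
            expected_vaf(s, rho, forest.total_cn, ccf=subclonal_ccf)
            if s == SUBCLONAL
            else expected_vaf(s, rho, forest.total_cn)
            for s in states
        ]
    )
    lik = binom.pmf(alt, depth, vafs)
    post = prior * lik
    tot = post.sum()
    if tot <= 0:  # extreme counts underflow every state; fall back to prior
        post = prior / prior.sum()
    else:
        post = post / tot
    return MultiplicityPosterior(
        states=states,
        probs=post,
        vafs=vafs,
        alt=alt,
        depth=depth,
        rho=rho,
        n_t=forest.total_cn,
        subclonal_ccf=subclonal_ccf,
    )


@dataclass
class SNVTimingPosterior:
    """S posterior timing draws for one SNV.

    Each draw is a mutation time in [0, 1], or exactly 1.01 for draws in
    which the SNV was sampled as subclonal.
    """

    draws: np.ndarray
    multiplicities: np.ndarray = field(repr=False)  # 0 marks subclonal draws

    @property
    def S(self) -> int:
        return len(self.draws)

    @property
    def mean(self) -> float:
        """Mean over all draws, subclonal 1.01 markers included."""
        return float(np.mean(self.draws))

    @property
    def clonal_fraction(self) -> float:
        return float(np.mean(self.draws != SUBCLONAL_TIME))

    @property
    def clonal_mean(self) -> float:
        """Mean over clonal draws only (NaN if every draw is subclonal)."""
        clonal = self.draws[self.draws != SUBCLONAL_TIME]
        return float(clonal.mean()) if clonal.size else float("nan")


def _stack_edge_times(gp: GainPosterior) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Edge intervals per draw: (starts, ends) of shape (S, E), leaf counts (E,)."""
    return gp.edge_time_arrays()


def sample_snv_timing(
    alt: int,
    depth: int,
    gain_posterior: GainPosterior,
    rho: float,
    S: int = DEFAULT_DRAWS,
    rng: Optional[np.random.Generator] = None,
    subclonal_ccf: float = DEFAULT_SUBCLONAL_CCF,
    subclonal_prior_weight: float = DEFAULT_SUBCLONAL_PRIOR_WEIGHT,
    prior_mode: str = "edge_length",
) -> SNVTimingPosterior:
    """Hierarchically sample S timing values for one SNV.

    Draw s: (1) take gain-history draw s (cycled if S exceeds the number
    of gain draws, so WGD-time coherence within a draw index is kept
    across a sample's SNVs); (2) sample a multiplicity state from the
    read-count posterior under that forest; (3) a subclonal state emits
    1.01; (4) otherwise pick an edge of that multiplicity with
    probability proportional to its time-length and draw the time
    uniformly on its interval. Where the SNV has no preceding gain the
    lower limit is 0; no subsequent gain, the upper limit is 1.
    """
    if rng is None:
        rng = np.random.default_rng()
    if S < 1:
        raise ValueError("S must be >= 1")
    starts, ends, lc = _stack_edge_times(gain_posterior)
    n_gain_draws = starts.shape[0]
    idx = np.arange(S) % n_gain_draws
    starts, ends = starts[idx], ends[idx]  # (S, E)
    lengths = ends - starts

    n_t = gain_posterior.total_cn
    ms = np.unique(lc)
    states: list = list(int(m) for m in ms)
    # per-draw prior over states
    class_len = np.stack([lengths[:, lc == m].sum(axis=1) for m in ms], axis=1)
    if prior_mode == "edge_length":
        prior = class_len.copy()
    elif prior_mode == "uniform":
        prior = np.ones_like(class_len)
    else:
        raise ValueError(f"unknown prior mode {prior_mode!r}")
    if subclonal_prior_weight > 0:
        states.append(SUBCLONAL)
        if prior_mode == "edge_length":
            sub = subclonal_prior_weight * lengths.sum(axis=1, keepdims=True)
        else:
            sub = np.full((S, 1), subclonal_prior_weight)
        prior = np.concatenate([prior, sub], axis=1)

    vafs = np.array(
        [
            expected_vaf(s, rho, n_t, ccf=subclonal_ccf)
            if s == SUBCLONAL
            else expected_vaf(s, rho, n_t)
            for s in states
        ]
    )
    lik = binom.pmf(alt, depth, vafs)  # (K,)
    post = prior * lik[None, :]
    tot = post.sum(axis=1, keepdims=True)
    bad = (tot <= 0).ravel()
    if bad.any():
        post[bad] = prior[bad] / prior[bad].sum(axis=1, keepdims=True)
        tot = post.sum(axis=1, keepdims=True)
    post = post / tot

    # vectorized categorical draw of a state per draw
    u = rng.random((S, 1))
    state_idx = (post.cumsum(axis=1) < u).sum(axis=1)
    state_idx = np.minimum(state_idx, len(states) - 1)

    draws = np.full(S, SUBCLONAL_TIME, dtype=float)
    mults = np.zeros(S, dtype=int)
    for k, m in enumerate(ms):
        sel = state_idx == k
        if not sel.any():
            continue
        cols = np.flatnonzero(lc == m)
        w = lengths[np.ix_(sel, cols)]
        wsum = w.sum(axis=1, keepdims=True)
        zero = (wsum <= 0).ravel()
        p = np.empty_like(w)
        p[~zero] = w[~zero] / wsum[~zero]
        p[zero] = 1.0 / w.shape[1]  # zero-length ties broken uniformly
        ue = rng.random((sel.sum(), 1))
        e_idx = (p.cumsum(axis=1) < ue).sum(axis=1)
        e_idx = np.minimum(e_idx, len(cols) - 1)
        rows = np.flatnonzero(sel)
        s0 = starts[rows, cols[e_idx]]
        s1 = ends[rows, cols[e_idx]]
        draws[sel] = s0 + rng.random(sel.sum()) * (s1 - s0)
        mults[sel] = int(m)
    return SNVTimingPosterior(draws=draws, multiplicities=mults)


def snv_rng(seed: int, sample: str, chrom: str, pos: int) -> np.random.Generator:
    """Deterministic per-SNV RNG substream.

    Derived by hashing (sample, chrom, pos) into the seed sequence so row
    order never changes results.
    """
    digest = hashlib.sha256(f"{sample}\x00{chrom}\x00{pos}".encode()).digest()
    key = tuple(int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def time_all_snvs(
    snvs: pd.DataFrame,
    gain_posteriors: dict,
    segments: pd.DataFrame,
    purity: float,
    sample: str,
    S: int = DEFAULT_DRAWS,
    seed: int = 0,
    subclonal_ccf: float = DEFAULT_SUBCLONAL_CCF,
    subclonal_prior_weight: float = DEFAULT_SUBCLONAL_PRIOR_WEIGHT,
    prior_mode: str = "edge_length",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Time every SNV of one sample.

    Parameters
    ----------
    snvs
        Table with columns chrom, pos, alt_count, ref_count (plus any
        metadata carried through, e.g. gene and classification).
    gain_posteriors
        Mapping segment_id -> :class:`GainPosterior`.
    segments
        Segment table (chrom, start, end, segment_id) for this sample,
        0-based half-open coordinates.

    Returns
    -------
    (table, draws)
        ``table`` has one row per SNV with mean_time, clonal_fraction,
        mean_time_clonal and a ``timed`` flag; SNVs outside any segment
        with a gain posterior are flagged untimed (NaN summaries), not
        dropped. ``draws`` is an (n_snvs, S) array; untimed rows are NaN.
    """
    seg = segments.reset_index(drop=True)
    rows = []
    draws_out = np.full((len(snvs), S), np.nan)
    for i, rec in enumerate(snvs.itertuples(index=False)):
        chrom, pos = str(rec.chrom), int(rec.pos)
        hit = seg[(seg["chrom"].astype(str) == chrom) & (seg["start"] <= pos) & (pos < seg["end"])]
        seg_id = str(hit.iloc[0]["segment_id"]) if len(hit) else None
        gp = gain_posteriors.get(seg_id) if seg_id is not None else None
        row = {c: getattr(rec, c) for c in snvs.columns}
        row["sample"] = sample
        row["segment_id"] = seg_id
        if gp is None:
            row.update(
                timed=False,
                mean_time=np.nan,
                clonal_fraction=np.nan,
                mean_time_clonal=np.nan,
            )
        else:
            rng = snv_rng(seed, sample, chrom, pos)
            post = sample_snv_timing(
                int(rec.alt_count),
                int(rec.alt_count) + int(rec.ref_count),
                gp,
                purity,
                S=S,
                rng=rng,
                subclonal_ccf=subclonal_ccf,
                subclonal_prior_weight=subclonal_prior_weight,
                prior_mode=prior_mode,
            )
            draws_out[i] = post.draws
            row.update(
                timed=True,
                mean_time=post.mean,
                clonal_fraction=post.clonal_fraction,
                mean_time_clonal=post.clonal_mean,
            )
        rows.append(row)
    return pd.DataFrame(rows), draws_out
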