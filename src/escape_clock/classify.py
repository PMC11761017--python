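"""Early/late classification of mutation events against a driver-gene clock.

Each sample's background clock is the per-draw mean timing of its
driver-gene SNVs. An event (a gene or a pathway gene set) is compared
draw-by-draw: with Δ_s = (event mean at draw s) − (background at draw s),
the event is early if more than 60% of draws have Δ_s < 0, late if more
than 60% have Δ_s > 0, otherwise undetermined. Cancer-type timelines use
the smoothed ratio (n_late + 1)/(n_early + 1) with cutoffs 0.5 and 2,
restricted to events determined in at least five samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "EARLY_LATE_FRACTION",
    "RATIO_EARLY",
    "RATIO_LATE",
    "MIN_DETERMINED_SAMPLES",
    "BackgroundClock",
    "EventCall",
    "TimelineEntry",
    "background_timing",
    "classify_event",
    "classify_sample_events",
    "aggregate_timeline",
    "timing_strata_export",
]

EARLY_LATE_FRACTION = 0.6
RATIO_EARLY = 0.5
RATIO_LATE = 2.0
MIN_DETERMINED_SAMPLES = 5


@dataclass
class BackgroundClock:
    """Per-draw mean timing of a sample's driver-gene SNVs."""

    sample: str
    draws: np.ndarray
    n_driver_snvs: int

    @property
    def S(self) -> int:
        return len(self.draws)


@dataclass
class EventCall:
    sample: str
    event: str
    frac_early: float
    frac_late: float
    label: str  # "early" | "late" | "undetermined"
    n_snvs: int
    delta_mean: float


@dataclass
class TimelineEntry:
    cancer_type: str
    event: str
    n_early: int
    n_late: int
    n_undetermined: int
    ratio: float
    eligible: bool
    label: Optional[str]  # None when ineligible


def background_timing(driver_draws: np.ndarray, sample: str = "") -> BackgroundClock:
    """Build the background clock from an (n_snvs, S) driver draw matrix.

    Subclonal 1.01 markers are included verbatim in the per-draw means.
    """
    draws = np.atleast_2d(np.asarray(driver_draws, dtype=float))
    if draws.shape[0] < 1 or draws.size == 0:
        raise ValueError(f"sample {sample}: no driver SNVs for background timing")
    return BackgroundClock(sample, draws.mean(axis=0), draws.shape[0])


def classify_event(
    event_draws: np.ndarray,
    clock: BackgroundClock,
    event: str = "",
    fraction_threshold: float = EARLY_LATE_FRACTION,
) -> EventCall:
    """Classify one event in one sample against the background clock.

    Δ_s ties at exactly 0 count toward neither fraction; both thresholds
    are strict (a fraction of exactly 0.6 does not call).
    """
    draws = np.atleast_2d(np.asarray(event_draws, dtype=float))
    if draws.size == 0:
        raise ValueError(f"event {event}: no timed SNVs")
    if draws.shape[1] != clock.S:
        raise ValueError(
            f"event {event}: draw count {draws.shape[1]} != clock draw count {clock.S}"
        )
    delta = draws.mean(axis=0) - clock.draws
    frac_early = float(np.mean(delta < 0))
    frac_late = float(np.mean(delta > 0))
    if frac_early > fraction_threshold:
        label = "early"
    elif frac_late > fraction_threshold:
        label = "late"
    else:
        label = "undetermined"
    return EventCall(
        sample=clock.sample,
        event=event,
        frac_early=frac_early,
        frac_late=frac_late,
        label=label,
        n_snvs=draws.shape[0],
        delta_mean=float(delta.mean()),
    )


def classify_sample_events(
    snv_meta: pd.DataFrame,
    draws: np.ndarray,
    driver_genes: set,
    events: dict,
    sample: str,
    fraction_threshold: float = EARLY_LATE_FRACTION,
    exclude_self_from_background: bool = True,
) -> list[EventCall]:
    """Classify every event of one sample.

    Parameters
    ----------
    snv_meta
        One row per timed SNV (column ``gene``), aligned with ``draws``
        rows (an (n_snvs, S) array of timing draws).
    events
        Mapping event name -> set of gene symbols (a gene event is just a
        singleton set).
    exclude_self_from_background
        When an event's genes overlap the driver list, drop the event's
        own SNVs from its background clock so an event is not compared
        against itself. Set False for the literal all-driver-SNVs clock.
    """
    genes = snv_meta["gene"].astype(str).str.strip().str.upper().to_numpy()
    driver_upper = {g.strip().upper() for g in driver_genes}
    is_driver = np.isin(genes, sorted(driver_upper))
    if not is_driver.any():
        return []
    calls = []
    full_clock = background_timing(draws[is_driver], sample=sample)
    for event, gene_set in events.items():
        ev_genes = {g.strip().upper() for g in gene_set}
        in_event = np.isin(genes, sorted(ev_genes))
        if not in_event.any():
            continue
        if exclude_self_from_background and (ev_genes & driver_upper):
            bg = is_driver & ~in_event
            if not bg.any():
                continue  # no independent clock for this event
            clock = background_timing(draws[bg], sample=sample)
        else:
            clock = full_clock
        calls.append(
            classify_event(draws[in_event], clock, event=event, fraction_threshold=fraction_threshold)
        )
    return calls


def aggregate_timeline(
    calls: pd.DataFrame,
    min_determined: int = MIN_DETERMINED_SAMPLES,
    ratio_early: float = RATIO_EARLY,
    ratio_late: float = RATIO_LATE,
) -> pd.DataFrame:
    """Cancer-type-level timeline from per-sample calls.

    ``calls`` needs columns cancer_type, event, label. Events are eligible
    when determined (early or late) in at least ``min_determined``
    samples; the ratio (n_late + 1)/(n_early + 1) labels the event early
    below ``ratio_early`` and late above ``ratio_late`` (both strict).
    """
    rows = []
    for (ctype, event), grp in calls.groupby(["cancer_type", "event"], sort=True):
        n_early = int((grp["label"] == "early").sum())
        n_late = int((grp["label"] == "late").sum())
        n_undet = int((grp["label"] == "undetermined").sum())
        ratio = (n_late + 1) / (n_early + 1)
        eligible = (n_early + n_late) >= min_determined
        if not eligible:
            label = ""
        elif ratio < ratio_early:
            label = "early"
        elif ratio > ratio_late:
            label = "late"
        else:
            label = "undetermined"
        rows.append(
            TimelineEntry(ctype, event, n_early, n_late, n_undet, ratio, eligible, label)
        )
    return pd.DataFrame(
        [
            {
                "cancer_type": t.cancer_type,
                "event": t.event,
                "n_early": t.n_early,
                "n_late": t.n_late,
                "n_undetermined": t.n_undetermined,
                "ratio": t.ratio,
                "eligible": t.eligible,
                "label": t.label,
            }
            for t in rows
        ]
    )


def timing_strata_export(calls: pd.DataFrame) -> dict:
    """Early/late sample lists per (cancer_type, event) stratum.

    Output feeds external differential-expression tooling; the lists are
    disjoint by construction of the per-sample labels.
    """
    out: dict[str, dict[str, dict[str, list]]] = {}
    for (ctype, event), grp in calls.groupby(["cancer_type", "event"], sort=True):
        early = sorted(grp.loc[grp["label"] == "early", "sample"].astype(str))
        late = sorted(grp.loc[grp["label"] == "late", "sample"].astype(str))
        out.setdefault(str(ctype), {})[str(event)] = {"early": early, "late": late}
    return out
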