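"""ROI definition, region timecourses and event-locked percent change.

Two epoching conventions are provided.  The *task* convention (controlled
stimuli) baseline-corrects each event against the mean of the 5 s preceding
its onset and expresses the response as percent of that baseline over
-10 ... +20 s.  The *IED* convention (spontaneous discharges, no baseline
control) expresses the gray-matter-normalized degree as percent change
relative to the global mean (normalized mean = 1) over -20 ... +30 s.

Events are aligned to the sampling grid by nearest sample (no
interpolation); events whose epoch span or baseline would run off the
series are dropped and logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import BoldSeries, EventTrain, RegionSet
from .fcd import FcdSeries
from .synth import HrfModel, event_regressor

__all__ = ["EpochSet", "glm_localizer", "extract_region_timecourse",
           "epoch_percent_change", "epoch_global_mean_change",
           "extract_hemodynamic_response"]

log = logging.getLogger(__name__)


@dataclass
class EpochSet:
    """Event x time-offset matrix of percent change for one region.

    ``valid`` flags events with a usable baseline (B > 0); ``average`` is
    the mean curve over valid events.
    """

    values: np.ndarray
    offsets: np.ndarray
    convention: str  # "task_baseline" | "global_mean"
    region: int | str = ""
    valid: np.ndarray | None = None
    n_dropped: int = 0
    baseline_seconds: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.values.shape[1] != self.offsets.size:
            raise ValueError("values and offsets disagree")
        if self.valid is None:
            self.valid = np.ones(self.values.shape[0], dtype=bool)

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def average(self) -> np.ndarray:
        """Mean percent-change curve over valid events.

        NaN-aware: offsets that fall on missing (flagged) windows for some
        events are averaged over the events where they are defined.
        """
        if not np.any(self.valid):
            raise ValueError("no valid events to average")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values[self.valid], axis=0)


def glm_localizer(bold: BoldSeries, events: EventTrain, hrf: HrfModel,
                  threshold_quantile: float = 0.95,
                  t_cutoff: float | None = None,
                  t_cap: float = 1e6) -> tuple[np.ndarray, np.ndarray]:
    """Single-run GLM localizer: per-voxel t for the task regressor.

    The design is an intercept plus the event boxcar convolved with the
    HRF.  Returns ``(roi_rows, t_map)`` where the ROI holds the voxels with
    t above ``t_cutoff`` if given, else above the ``threshold_quantile``
    quantile of the t map.  Perfect (noiseless) fits produce infinite t;
    these are capped at ``t_cap`` and always fall in the ROI.
    """
    if len(events) == 0:
        raise ValueError("no events for the localizer")
    reg = event_regressor(events, hrf, bold.tr, bold.n_timepoints)
    if np.ptp(reg) == 0:
        raise ValueError("constant task regressor")
    x = np.column_stack([np.ones_like(reg), reg])
    beta, *_ = np.linalg.lstsq(x, bold.data.T, rcond=None)
    resid = bold.data.T - x @ beta
    dof = bold.n_timepoints - 2
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    xtx_inv = np.linalg.inv(x.T @ x)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 * xtx_inv[1, 1])
        t_map = np.where(se > 0, beta[1] / np.where(se > 0, se, 1.0),
                         np.sign(beta[1]) * t_cap)
    t_map = np.clip(t_map, -t_cap, t_cap)
    cutoff = float(np.quantile(t_map, threshold_quantile)) if t_cutoff is None \
        else float(t_cutoff)
    roi_rows = np.flatnonzero(t_map >= cutoff)
    return roi_rows, t_map


def extract_region_timecourse(series: FcdSeries | BoldSeries,
                              regions: RegionSet | np.ndarray,
                              region_id: int | None = None
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Mean series over a region's voxels: returns (times, values).

    ``regions`` may be a RegionSet (then ``region_id`` selects the region,
    labels indexing BoldSeries rows) or directly an array of row indices.
    """
    if isinstance(regions, RegionSet):
        if region_id is None:
            raise ValueError("region_id required with a RegionSet")
        rows = regions.rows(region_id)
    else:
        rows = np.asarray(regions, dtype=int)
    if rows.size == 0:
        raise ValueError("empty region")
    if isinstance(series, FcdSeries):
        positions = np.flatnonzero(np.isin(series.voxel_rows, rows))
        if positions.size == 0:
            raise ValueError("region has no voxels inside the FCD mask")
        return series.time_centers, series.degrees[positions].mean(axis=0)
    return series.times, series.data[rows].mean(axis=0)


def _epoch_indices(times: np.ndarray, events: EventTrain, pre: float, post: float
                   ) -> tuple[list[int], list[int], int, int, float]:
    """Nearest-sample alignment: returns kept event anchors and grid extents."""
    dt = float(np.median(np.diff(times)))
    k_pre = int(round(pre / dt))
    k_post = int(round(post / dt))
    anchors, kept = [], []
    for e, onset in enumerate(events.onsets):
        j0 = int(np.argmin(np.abs(times - onset)))
        if j0 - k_pre < 0 or j0 + k_post >= times.size:
            continue
        anchors.append(j0)
        kept.append(e)
    n_dropped = len(events) - len(kept)
    if n_dropped:
        log.info("epoching: dropped %d events without full coverage", n_dropped)
    if not anchors:
        raise ValueError("no event has full epoch coverage")
    return anchors, kept, k_pre, k_post, dt


def epoch_percent_change(times: np.ndarray, values: np.ndarray,
                         events: EventTrain, pre: float = 10.0,
                         post: float = 20.0, baseline: float = 5.0,
                         mode: str = "percent", region: int | str = "",
                         ) -> EpochSet:
    """Task-convention epochs: baseline-corrected percent change.

    Per event, B_e is the mean of the curve over [onset - baseline, onset)
    (half-open: the onset sample is post-stimulus) and the event's curve is
    baseline-corrected by subtracting B_e.

    ``mode="percent"`` (default) expresses the corrected curves as percent
    of the *pooled* baseline level: 100 * (x - B_e) / mean_e(B_e).  Using
    the pooled mean as the denominator keeps the percent scale while
    avoiding the upward bias that dividing by each event's own noisy B_e
    induces at offsets where the curve has decorrelated from its baseline
    (E[1/B] > 1/E[B]).  ``mode="percent_event"`` divides by the event's own
    B_e; ``mode="subtract"`` only subtracts.  Events with a non-positive
    denominator are flagged invalid in the percent modes.
    """
    if mode not in ("percent", "percent_event", "subtract"):
        raise ValueError("mode must be 'percent', 'percent_event' or 'subtract'")
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    anchors, kept, k_pre, k_post, dt = _epoch_indices(times, events, pre, post)
    offsets = np.arange(-k_pre, k_post + 1) * dt
    out = np.empty((len(anchors), offsets.size))
    valid = np.ones(len(anchors), dtype=bool)
    baselines = np.full(len(anchors), np.nan)
    for row, (j0, ev) in enumerate(zip(anchors, kept)):
        onset = events.onsets[ev]
        base_sel = (times >= onset - baseline) & (times < onset)
        if not np.any(base_sel):
            valid[row] = False
            out[row] = np.nan
            continue
        b = np.nanmean(values[base_sel])
        baselines[row] = b
        seg = values[j0 - k_pre: j0 + k_post + 1]
        if mode == "subtract":
            out[row] = seg - b
        elif mode == "percent_event":
            if not b > 0:
                valid[row] = False
                out[row] = np.nan
                continue
            out[row] = 100.0 * (seg - b) / b
        else:
            out[row] = seg - b  # scaled by the pooled baseline below
    if mode == "percent":
        b_pool = np.nanmean(baselines[valid]) if np.any(valid) else np.nan
        if not b_pool > 0:
            valid[:] = False
            out[:] = np.nan
        else:
            out[valid] = 100.0 * out[valid] / b_pool
    return EpochSet(values=out, offsets=offsets, convention="task_baseline",
                    region=region, valid=valid,
                    n_dropped=len(events) - len(anchors),
                    baseline_seconds=baseline)


def epoch_global_mean_change(times: np.ndarray, values: np.ndarray,
                             events: EventTrain, pre: float = 20.0,
                             post: float = 30.0, region: int | str = "",
                             ) -> EpochSet:
    """IED-convention epochs: percent change relative to the global mean.

    ``values`` must be a gray-matter-normalized degree curve (global mean
    = 1 by construction), so the percent change is 100 * (value - 1).
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    anchors, _, k_pre, k_post, dt = _epoch_indices(times, events, pre, post)
    offsets = np.arange(-k_pre, k_post + 1) * dt
    out = np.empty((len(anchors), offsets.size))
    for row, j0 in enumerate(anchors):
        out[row] = 100.0 * (values[j0 - k_pre: j0 + k_post + 1] - 1.0)
    return EpochSet(values=out, offsets=offsets, convention="global_mean",
                    region=region, n_dropped=len(events) - len(anchors))


def extract_hemodynamic_response(bold: BoldSeries, roi_rows: np.ndarray,
                                 events: EventTrain, post: float = 20.0,
                                 baseline: float = 5.0
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Event-averaged ROI BOLD percent signal change over [0, post] s.

    Baseline-corrects each event against the mean ROI signal in the
    ``baseline`` seconds before onset; returns (offsets, average curve).
    """
    times, curve = extract_region_timecourse(bold, np.asarray(roi_rows))
    epochs = epoch_percent_change(times, curve, events, pre=0.0, post=post,
                                  baseline=baseline)
    return epochs.offsets, epochs.average
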