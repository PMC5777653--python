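"""Confound assembly and removal by partial regression.

The confound set follows the common fast-fMRI recipe: six head-motion
parameters, mean CSF and white-matter signals, the global (gray-matter mean)
signal, and eight RETROICOR regressors — sine and cosine of the cardiac and
respiratory phases up to second order.  Everything is removed jointly in a
single ordinary-least-squares regression with an intercept; no temporal
filtering is applied.

Cardiac phase is the linear fraction of the current inter-beat interval;
respiratory phase is the amplitude-histogram-equalized position in the
breathing cycle signed by the breathing direction, so one full cycle maps to
[0, 2*pi) per breath.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg as slinalg
from scipy import signal as ssignal

from .datatypes import BoldSeries, PhysioTrace

__all__ = [
    "PhaseSeries",
    "ConfoundMatrix",
    "cardiac_phase",
    "respiratory_phase",
    "build_retroicor_regressors",
    "assemble_confounds",
    "partial_regress",
]

TWO_PI = 2.0 * np.pi


@dataclass
class PhaseSeries:
    """Phase in [0, 2*pi) at each BOLD sample, for one physiological rhythm."""

    phase: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float) % TWO_PI


@dataclass
class ConfoundMatrix:
    """Named nuisance regressors, one column per regressor."""

    columns: np.ndarray  # time x n_regressors
    names: list[str]

    def __post_init__(self) -> None:
        self.columns = np.atleast_2d(np.asarray(self.columns, dtype=float))
        if self.columns.shape[1] != len(self.names):
            raise ValueError("column count and names inconsistent")
        if not np.all(np.isfinite(self.columns)):
            raise ValueError("confound columns contain non-finite values")


def detect_cardiac_peaks(trace: PhysioTrace, min_interval: float = 0.25) -> np.ndarray:
    """Systolic peak times: local maxima above the trace median, separated
    by at least ``min_interval`` seconds."""
    distance = max(1, int(round(min_interval * trace.sampling_rate)))
    idx, _ = ssignal.find_peaks(trace.samples, height=float(np.median(trace.samples)),
                                distance=distance)
    return idx / trace.sampling_rate


def cardiac_phase(trace: PhysioTrace, bold_times: np.ndarray,
                  min_interval: float = 0.25) -> PhaseSeries:
    """Cardiac phase at each BOLD sample from pulse-oximeter peaks.

    Between consecutive beats t1 < t <= t2 the phase is
    2*pi*(t - t1)/(t2 - t1); a sample on a peak has phase 0.  Outside the
    first/last detected peak the beat grid is extended linearly.
    """
    bold_times = np.asarray(bold_times, dtype=float)
    if trace.duration < bold_times.max():
        raise ValueError("physio trace does not cover the BOLD series")
    peaks = detect_cardiac_peaks(trace, min_interval)
    if peaks.size < 2:
        raise ValueError("fewer than 2 cardiac peaks detected")
    # unwrapped phase is piecewise-linear through (peak_k, 2*pi*k);
    # np.interp clamps outside, so extend the peak grid past both ends first
    first_iv = peaks[1] - peaks[0]
    last_iv = peaks[-1] - peaks[-2]
    n_before = int(np.ceil(max(0.0, peaks[0] - bold_times.min()) / first_iv)) + 1
    n_after = int(np.ceil(max(0.0, bold_times.max() - peaks[-1]) / last_iv)) + 1
    grid = np.concatenate([
        peaks[0] - first_iv * np.arange(n_before, 0, -1),
        peaks,
        peaks[-1] + last_iv * np.arange(1, n_after + 1),
    ])
    unwrapped = TWO_PI * (np.arange(grid.size) - n_before)
    phase = np.interp(bold_times, grid, unwrapped)
    return PhaseSeries(phase=phase, kind="cardiac")


def respiratory_phase(trace: PhysioTrace, bold_times: np.ndarray) -> PhaseSeries:
    """Respiratory phase by amplitude histogram equalization.

    The phase magnitude is pi times the empirical CDF of the belt amplitude
    (so the trace maximum maps to half a cycle) and the sign follows the
    breathing direction: inhale (rising amplitude) covers (0, pi], exhale
    covers (pi, 2*pi).  For a sinusoidal trace the result advances
    monotonically, one full cycle per breath.
    """
    bold_times = np.asarray(bold_times, dtype=float)
    if trace.duration < bold_times.max():
        raise ValueError("physio trace does not cover the BOLD series")
    x = trace.samples
    if np.ptp(x) == 0:
        raise ValueError("constant respiratory trace")
    t = trace.times
    amp = np.interp(bold_times, t, x)
    slope = np.interp(bold_times, t, np.gradient(x, t))
    # empirical CDF of the full trace, evaluated at the BOLD-sample amplitudes
    order = np.sort(x)
    cdf = (np.searchsorted(order, amp, side="right")) / x.size
    signed = np.pi * cdf * np.where(slope >= 0, 1.0, -1.0)
    return PhaseSeries(phase=signed, kind="respiratory")  # wrapped to [0, 2*pi)


def build_retroicor_regressors(cardiac: PhaseSeries, respiratory: PhaseSeries,
                               order: int = 2) -> ConfoundMatrix:
    """Sine/cosine expansions of both phases up to ``order`` (8 columns at 2)."""
    if order < 1:
        raise ValueError("order must be >= 1")
    cols, names = [], []
    for series, tag in ((cardiac, "cardiac"), (respiratory, "respiratory")):
        for k in range(1, order + 1):
            cols.append(np.sin(k * series.phase))
            names.append(f"{tag}_sin{k}")
            cols.append(np.cos(k * series.phase))
            names.append(f"{tag}_cos{k}")
    return ConfoundMatrix(columns=np.column_stack(cols), names=names)


def global_signal(bold: BoldSeries, mask_rows: np.ndarray | None = None) -> np.ndarray:
    """Mean series over the given rows (gray-matter mask by default = all)."""
    rows = np.arange(bold.n_voxels) if mask_rows is None else np.asarray(mask_rows)
    if rows.size == 0:
        raise ValueError("empty mask for global signal")
    return bold.data[rows].mean(axis=0)


def assemble_confounds(bold: BoldSeries, motion: np.ndarray, csf: np.ndarray,
                       wm: np.ndarray, cardiac: PhysioTrace,
                       respiratory: PhysioTrace,
                       gray_rows: np.ndarray | None = None,
                       order: int = 2) -> ConfoundMatrix:
    """Full 17-column confound matrix: 6 motion + csf + wm + global + 8 RETROICOR."""
    motion = np.asarray(motion, dtype=float)
    if motion.shape != (bold.n_timepoints, 6):
        raise ValueError("motion must be time x 6")
    times = bold.times
    card = cardiac_phase(cardiac, times)
    resp = respiratory_phase(respiratory, times)
    retro = build_retroicor_regressors(card, resp, order=order)
    cols = np.column_stack([
        motion,
        np.asarray(csf, dtype=float),
        np.asarray(wm, dtype=float),
        global_signal(bold, gray_rows),
        retro.columns,
    ])
    names = [f"motion_{i}" for i in range(1, 7)] + ["csf", "wm", "global"] + retro.names
    return ConfoundMatrix(columns=cols, names=names)


def partial_regress(bold: BoldSeries, confounds: ConfoundMatrix,
                    rcond: float = 1e-10) -> BoldSeries:
    """Voxelwise OLS residuals of BOLD on the confounds plus an intercept.

    Exactly collinear columns are dropped with a warning (QR with column
    pivoting); the intercept is always retained, so residuals are demeaned
    and orthogonal to every retained confound column.
    """
    x = confounds.columns
    if x.shape[0] != bold.n_timepoints:
        raise ValueError("confound length does not match BOLD time axis")
    design = np.column_stack([np.ones(x.shape[0]), x])
    names = ["intercept"] + list(confounds.names)
    _, r_piv, piv = slinalg.qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r_piv))
    tol = diag.max() * max(design.shape) * rcond
    rank = int(np.sum(diag > tol))
    if rank == 0:
        raise ValueError("all confound columns dropped")
    if rank < design.shape[1]:
        dropped = [names[i] for i in piv[rank:]]
        warnings.warn(f"dropping exactly-collinear confounds: {dropped}",
                      stacklevel=2)
        design = design[:, np.sort(piv[:rank])]
    q, r = np.linalg.qr(design)
    beta = slinalg.solve_triangular(r, q.T @ bold.data.T)
    resid = bold.data - (design @ beta).T
    out = bold.copy()
    out.data = resid
    return out
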