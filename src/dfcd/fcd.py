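"""Sliding-window functional connectivity degree (FCD).

For every full window of ``n_samples`` consecutive volumes (advanced by
``step_samples``), the Pearson correlation is computed between every pair of
masked voxels on exactly those samples; a voxel's degree is the number of
other voxels whose |r| exceeds the critical value of a two-sided test of
zero correlation at significance ``p`` (default 0.001) with n - 2 degrees
of freedom.  Window values are assigned to the window's *center* time, so
degree transients align with the events that caused them.

The per-window correlations are computed as standardized matrix products;
the resulting integer degrees match a naive per-pair recomputation exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sstats

from .datatypes import BoldSeries

__all__ = ["WindowSpec", "FcdSeries", "correlation_threshold", "sliding_fcd",
           "normalize_fcd"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry.

    ``n_samples`` is the number of volumes per window; it must give at least
    one degree of freedom for the correlation (n >= 3) and agree with the
    nominal ``length_seconds`` to within one TR.
    """

    length_seconds: float
    n_samples: int
    step_samples: int = 1
    centered: bool = True

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3 (df = n - 2 >= 1)")
        if self.step_samples < 1:
            raise ValueError("step_samples must be >= 1")

    @classmethod
    def from_seconds(cls, length_seconds: float, tr: float,
                     step_samples: int = 1, centered: bool = True) -> "WindowSpec":
        """Nominal length -> samples by rounding to the nearest volume count.

        13.2 s at TR 0.66 s gives 20 samples; 7.8 s at TR 2.64 s gives 3.
        """
        n = int(round(length_seconds / tr))
        if abs(n * tr - length_seconds) > tr:
            raise ValueError(
                f"window of {length_seconds} s is not within one TR of a "
                f"whole number of samples at TR={tr}")
        return cls(length_seconds=length_seconds, n_samples=n,
                   step_samples=step_samples, centered=centered)


@dataclass
class FcdSeries:
    """Per-voxel degree counts over window-center times.

    ``degrees`` is voxel x window (raw counts are integers in [0, V-1]);
    ``voxel_rows`` indexes the rows of the source BoldSeries; ``missing``
    flags windows whose gray-matter mean degree was zero (set only by
    normalization).
    """

    degrees: np.ndarray
    window: WindowSpec
    r_threshold: float
    time_centers: np.ndarray
    tr: float
    voxel_rows: np.ndarray
    mask_index: np.ndarray
    space_shape: tuple[int, int, int]
    normalized: bool = False
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.degrees = np.asarray(self.degrees, dtype=float)
        self.time_centers = np.asarray(self.time_centers, dtype=float)
        if self.degrees.shape[1] != self.time_centers.size:
            raise ValueError("degrees and time_centers disagree on window count")
        if self.missing is None:
            self.missing = np.zeros(self.time_centers.size, dtype=bool)

    @property
    def n_windows(self) -> int:
        return self.time_centers.size


def correlation_threshold(n_samples: int, p: float = 0.001) -> float:
    """Critical |r| of a two-sided zero-correlation test at significance p.

    Uses the exact t-transform r = t / sqrt(t^2 + df) with df = n - 2, so
    that on null (independent Gaussian) data P(|r| > threshold) = p.
    """
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3 (df = n - 2 >= 1)")
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    df = n_samples - 2
    t_crit = sstats.t.ppf(1.0 - p / 2.0, df)
    return float(t_crit / np.hypot(t_crit, np.sqrt(df)))


def sliding_fcd(bold: BoldSeries, mask_rows: np.ndarray | None,
                window: WindowSpec, p: float = 0.001,
                laterality: str = "two_sided") -> FcdSeries:
    """Raw sliding-window degree counts for the masked voxels.

    ``laterality`` selects whether |r| ("two_sided", default — null
    exceedance rate exactly p) or only positive r ("positive") counts as a
    connection; the critical value is the two-sided one in both cases.
    Voxels with zero variance inside a window contribute no connections in
    that window (correlation undefined -> non-connection) and are logged.
    """
    if laterality not in ("two_sided", "positive"):
        raise ValueError("laterality must be 'two_sided' or 'positive'")
    rows = (np.arange(bold.n_voxels) if mask_rows is None
            else np.asarray(mask_rows, dtype=int))
    if rows.size == 0:
        raise ValueError("empty mask")
    n, step = window.n_samples, window.step_samples
    t_len = bold.n_timepoints
    if t_len < n:
        raise ValueError("no full window fits in the series")
    r_th = correlation_threshold(n, p)
    data = bold.data[rows]
    starts = np.arange(0, t_len - n + 1, step)
    degrees = np.zeros((rows.size, starts.size), dtype=np.int64)
    n_degenerate = 0
    for w, i in enumerate(starts):
        x = data[:, i:i + n]
        xc = x - x.mean(axis=1, keepdims=True)
        norm = np.sqrt(np.einsum("ij,ij->i", xc, xc))
        ok = norm > 0
        n_degenerate += int(np.sum(~ok))
        z = np.zeros_like(xc)
        z[ok] = xc[ok] / norm[ok, None]
        r = z @ z.T
        conn = (np.abs(r) > r_th) if laterality == "two_sided" else (r > r_th)
        np.fill_diagonal(conn, False)
        degrees[:, w] = conn.sum(axis=1)
    if n_degenerate:
        log.info("sliding_fcd: %d zero-variance voxel-windows treated as "
                 "non-connections", n_degenerate)
    centers = (starts + (n - 1) / 2.0) * bold.tr if window.centered \
        else starts * bold.tr
    return FcdSeries(degrees=degrees.astype(float), window=window,
                     r_threshold=r_th, time_centers=centers, tr=bold.tr,
                     voxel_rows=rows, mask_index=bold.mask_index[rows],
                     space_shape=bold.space_shape, normalized=False)


def normalize_fcd(fcd: FcdSeries, gray_rows: np.ndarray | None = None) -> FcdSeries:
    """Divide every voxel's degree by the gray-matter mean degree per window.

    After normalization the gray-matter mean is 1 at every valid window;
    windows with zero gray-matter mean are marked missing (NaN), not divided.
    """
    if fcd.normalized:
        raise ValueError("series is already normalized")
    if gray_rows is None:
        positions = np.arange(fcd.voxel_rows.size)
    else:
        positions = np.flatnonzero(np.isin(fcd.voxel_rows, np.asarray(gray_rows)))
        if positions.size == 0:
            raise ValueError("gray mask does not overlap the FCD voxels")
    gm_mean = fcd.degrees[positions].mean(axis=0)
    valid = gm_mean > 0
    if not np.all(valid):
        log.warning("normalize_fcd: %d windows with zero gray-matter mean "
                    "marked missing", int(np.sum(~valid)))
    out = np.full_like(fcd.degrees, np.nan)
    out[:, valid] = fcd.degrees[:, valid] / gm_mean[valid]
    return replace(fcd, degrees=out, normalized=True,
                   missing=~valid, time_centers=fcd.time_centers.copy())
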