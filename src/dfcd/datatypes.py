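"""Core containers shared across the pipeline.

All times are in seconds; the first volume is acquired at t = 0 and voxel
indices are 0-based.  BOLD data live in a masked 2-D layout (voxel x time)
with the 3-D coordinates of every row kept alongside, so volumes can be
reconstructed for NIfTI export without carrying empty background around.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class EventTrain:
    """Onsets and durations of brief events (task stimuli or IEDs).

    Onsets are absolute series time in seconds and must be strictly
    ascending; durations are non-negative.
    """

    onsets: np.ndarray
    durations: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        if self.onsets.ndim != 1 or self.durations.shape != self.onsets.shape:
            raise ValueError("onsets and durations must be 1-D and of equal length")
        if self.onsets.size and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly ascending")
        if np.any(self.durations < 0):
            raise ValueError("durations must be >= 0")

    def __len__(self) -> int:
        return self.onsets.size

    @property
    def ends(self) -> np.ndarray:
        return self.onsets + self.durations


@dataclass
class BoldSeries:
    """Masked BOLD matrix (voxel x time) with its repetition time.

    ``mask_index`` maps each matrix row to its (i, j, k) voxel coordinate
    inside a grid of shape ``space_shape``.
    """

    data: np.ndarray
    tr: float
    mask_index: np.ndarray
    space_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask_index = np.asarray(self.mask_index, dtype=int)
        self.space_shape = tuple(int(s) for s in self.space_shape)
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ValueError("data must be voxel x time with >= 2 time points")
        if self.mask_index.shape != (self.data.shape[0], 3):
            raise ValueError("mask_index must be (n_voxels, 3)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each volume (first volume at t = 0)."""
        return np.arange(self.n_timepoints) * self.tr

    @property
    def duration(self) -> float:
        return self.n_timepoints * self.tr

    def copy(self) -> "BoldSeries":
        return replace(self, data=self.data.copy(), mask_index=self.mask_index.copy())

    def to_volume(self) -> np.ndarray:
        """Scatter the masked rows back into a 4-D (x, y, z, t) array."""
        vol = np.zeros(self.space_shape + (self.n_timepoints,), dtype=float)
        i, j, k = self.mask_index.T
        vol[i, j, k, :] = self.data
        return vol


@dataclass
class PhysioTrace:
    """Raw peripheral recording (pulse oximeter or respiratory belt)."""

    samples: np.ndarray
    sampling_rate: float
    kind: str  # "cardiac" | "respiratory"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.kind not in ("cardiac", "respiratory"):
            raise ValueError("kind must be 'cardiac' or 'respiratory'")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class RegionSet:
    """Voxel -> region-id labels over the rows of a BoldSeries.

    Label 0 means "unlabelled"; region ids are positive integers.
    """

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D per-voxel vector")

    def rows(self, region_id: int) -> np.ndarray:
        """Row indices belonging to one region."""
        return np.flatnonzero(self.labels == region_id)

    @property
    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]
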