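"""File formats: NIfTI-1 volumes, BIDS-style TSV tables, JSON sidecars.

Conventions
-----------
- BOLD: 4-D NIfTI-1 (x, y, z, t), TR stored in the header (pixdim[4]);
  an accompanying mask is a 3-D integer NIfTI of the same grid.
- Events: TSV with columns onset, duration, trial_type (seconds).
- Confounds: TSV, one named column per regressor, one row per volume.
- Physio: two-column TSV (time, amplitude) plus a JSON sidecar carrying
  sampling_rate and kind.
- FCD: 4-D NIfTI over window centers plus a JSON sidecar (window spec,
  r threshold, center times) and a flat TSV export of the masked voxels.
- Epochs: long-format TSV (event, offset, value) plus a JSON sidecar.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import BoldSeries, EventTrain, PhysioTrace
from .eventlock import EpochSet
from .fcd import FcdSeries, WindowSpec

__all__ = [
    "save_bold", "load_bold", "save_mask", "load_mask",
    "save_events", "load_events", "save_confounds", "load_confounds",
    "save_physio", "load_physio", "save_fcd", "load_fcd",
    "save_epochs", "load_epochs", "save_table", "load_table",
]


def save_bold(path: str | Path, bold: BoldSeries) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(bold.to_volume().astype(np.float32), affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, float(bold.tr)))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, path)
    return path


def load_bold(path: str | Path, mask: np.ndarray | None = None,
              tr: float | None = None) -> BoldSeries:
    """Read a 4-D NIfTI into the masked layout.

    ``mask`` is a boolean/int 3-D array selecting voxels (all non-zero
    voxels of the volume if omitted ... a saved all-zero background voxel is
    then dropped).  ``tr`` overrides the header value with a warning on
    mismatch, since headers are often wrong in practice.
    """
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=float)
    if vol.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D volume, got shape {vol.shape}")
    header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if tr is None:
        if header_tr <= 0:
            raise ValueError(f"{path}: header TR is {header_tr}; pass tr= explicitly")
        tr = header_tr
    elif header_tr > 0 and abs(header_tr - tr) > 1e-6:
        warnings.warn(f"{path}: header TR {header_tr} != requested {tr}; using {tr}",
                      stacklevel=2)
    if mask is None:
        mask3d = np.any(vol != 0, axis=3)
    else:
        mask3d = np.asarray(mask) != 0
    idx = np.argwhere(mask3d)
    data = vol[mask3d]
    return BoldSeries(data=data, tr=tr, mask_index=idx, space_shape=vol.shape[:3])


def save_mask(path: str | Path, labels3d: np.ndarray) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(labels3d, dtype=np.int16), affine=np.eye(4))
    nib.save(img, path)
    return path


def load_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D label volume, got {arr.shape}")
    return arr.astype(int)


def save_events(path: str | Path, events: EventTrain) -> Path:
    path = Path(path)
    df = pd.DataFrame({
        "onset": events.onsets,
        "duration": events.durations,
        "trial_type": [events.label or "event"] * len(events),
    })
    df.to_csv(path, sep="\t", index=False)
    return path


def load_events(path: str | Path) -> EventTrain:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("onset", "duration"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    label = ""
    if "trial_type" in df.columns and len(df):
        label = str(df["trial_type"].iloc[0])
    return EventTrain(onsets=df["onset"].to_numpy(float),
                      durations=df["duration"].to_numpy(float), label=label)


def save_confounds(path: str | Path, columns: np.ndarray, names: list[str]) -> Path:
    path = Path(path)
    pd.DataFrame(np.asarray(columns), columns=list(names)).to_csv(
        path, sep="\t", index=False)
    return path


def load_confounds(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return df.to_numpy(float), list(df.columns)


def save_physio(path: str | Path, trace: PhysioTrace) -> Path:
    """TSV (time, amplitude) + .json sidecar with sampling_rate and kind."""
    path = Path(path)
    pd.DataFrame({"time": trace.times, "amplitude": trace.samples}).to_csv(
        path, sep="\t", index=False)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(
        {"sampling_rate": trace.sampling_rate, "kind": trace.kind}, indent=1))
    return path


def load_physio(path: str | Path) -> PhysioTrace:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    meta = json.loads(path.with_suffix(".json").read_text())
    return PhysioTrace(samples=df["amplitude"].to_numpy(float),
                       sampling_rate=float(meta["sampling_rate"]),
                       kind=str(meta["kind"]))


def save_fcd(path: str | Path, fcd: FcdSeries) -> Path:
    """4-D NIfTI over window centers + JSON sidecar + flat TSV export."""
    path = Path(path)
    vol = np.zeros(fcd.space_shape + (fcd.n_windows,), dtype=np.float32)
    i, j, k = fcd.mask_index.T
    vol[i, j, k, :] = fcd.degrees
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    step_sec = float(fcd.window.step_samples * fcd.tr)
    img.header.set_zooms((1.0, 1.0, 1.0, step_sec))
    nib.save(img, path)
    sidecar = {
        "window": {"length_seconds": fcd.window.length_seconds,
                   "n_samples": fcd.window.n_samples,
                   "step_samples": fcd.window.step_samples,
                   "centered": fcd.window.centered},
        "r_threshold": fcd.r_threshold,
        "tr": fcd.tr,
        "time_centers": fcd.time_centers.tolist(),
        "normalized": bool(fcd.normalized),
        "missing": np.asarray(fcd.missing).astype(int).tolist(),
        "voxel_rows": fcd.voxel_rows.tolist(),
        "mask_index": fcd.mask_index.tolist(),
        "space_shape": list(fcd.space_shape),
    }
    _json_path(path).write_text(json.dumps(sidecar))
    flat = pd.DataFrame(fcd.degrees,
                        columns=[f"w{c:.3f}" for c in fcd.time_centers])
    flat.insert(0, "voxel_row", fcd.voxel_rows)
    flat.to_csv(path.parent / (_stem(path) + "_flat.tsv"), sep="\t", index=False)
    return path


def _stem(path: Path) -> str:
    name = path.name
    for suffix in (".nii.gz", ".nii", ".tsv"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return path.stem


def _json_path(path: Path) -> Path:
    return path.parent / (_stem(path) + ".json")


def load_fcd(path: str | Path) -> FcdSeries:
    path = Path(path)
    meta = json.loads(_json_path(path).read_text())
    flat = pd.read_csv(path.parent / (_stem(path) + "_flat.tsv"), sep="\t", float_precision="round_trip")
    degrees = flat.drop(columns=["voxel_row"]).to_numpy(float)
    w = meta["window"]
    window = WindowSpec(length_seconds=w["length_seconds"], n_samples=w["n_samples"],
                        step_samples=w["step_samples"], centered=w["centered"])
    return FcdSeries(
        degrees=degrees, window=window, r_threshold=float(meta["r_threshold"]),
        time_centers=np.asarray(meta["time_centers"], float), tr=float(meta["tr"]),
        voxel_rows=np.asarray(meta["voxel_rows"], dtype=int),
        mask_index=np.asarray(meta["mask_index"], dtype=int),
        space_shape=tuple(meta["space_shape"]),
        normalized=bool(meta["normalized"]),
        missing=np.asarray(meta["missing"], dtype=bool))


def save_epochs(path: str | Path, epochs: EpochSet) -> Path:
    """Long-format TSV (event, offset, value) + JSON sidecar."""
    path = Path(path)
    n_ev, n_off = epochs.values.shape
    df = pd.DataFrame({
        "event": np.repeat(np.arange(n_ev), n_off),
        "offset": np.tile(epochs.offsets, n_ev),
        "value": epochs.values.ravel(),
    })
    df.to_csv(path, sep="\t", index=False)
    sidecar = {
        "convention": epochs.convention,
        "region": epochs.region,
        "baseline_seconds": epochs.baseline_seconds,
        "valid": np.asarray(epochs.valid).astype(int).tolist(),
        "n_dropped": int(epochs.n_dropped),
    }
    _json_path(path).write_text(json.dumps(sidecar))
    return path


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    meta = json.loads(_json_path(path).read_text())
    offsets = np.unique(df["offset"].to_numpy(float))
    n_ev = int(df["event"].max()) + 1 if len(df) else 0
    values = df["value"].to_numpy(float).reshape(n_ev, offsets.size)
    return EpochSet(values=values,
                    offsets=df["offset"].to_numpy(float)[:offsets.size],
                    convention=str(meta["convention"]), region=meta["region"],
                    valid=np.asarray(meta["valid"], dtype=bool),
                    n_dropped=int(meta["n_dropped"]),
                    baseline_seconds=meta["baseline_seconds"])


def save_table(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
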