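"""End-to-end runner: simulate -> denoise -> FCD -> event-lock -> stats.

The pipeline emulates the multi-TR control experiment: for each synthetic
subject an event train and BOLD runs at every requested TR are generated,
denoised by partial regression of the full confound set, converted to
sliding-window degree series at every requested window length, event-locked
in the functional ROI, and summarized as peak amplitude/latency tables with
the within-subject ANOVA and Bonferroni post-hocs.

Every stage is deterministic given (config, seed); a provenance record of
parameters, package versions and artifact checksums is written alongside
the result tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, eventlock, fcd, io, nuisance, stats, synth

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "demo_config"]


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run (times in seconds)."""

    trs: tuple[float, ...] = (2.64, 1.32, 0.66, 0.33)
    windows: tuple[float, ...] = (7.8, 13.2, 18.4)
    threshold_p: float = 0.001
    laterality: str = "two_sided"
    baseline_seconds: float = 5.0
    task_epoch: tuple[float, float] = (10.0, 20.0)   # pre, post
    ied_epoch: tuple[float, float] = (20.0, 30.0)
    peak_band1: tuple[float, float] = (0.0, 10.0)
    peak_band2: tuple[float, float] = (10.0, 20.0)
    n_subjects: int = 10
    total_time: float = 360.0
    n_events: int = 12
    event_duration: float = 0.5
    isi: tuple[float, float] = (18.0, 26.0)
    grid_shape: tuple[int, int, int] = (8, 8, 3)
    roi_quantile: float = 0.95
    seed: int = 0
    out_dir: str = "scratch/pipeline"
    denoise: bool = True

    def validate(self) -> None:
        """Check every field against the owning stage's preconditions."""
        if not self.trs or any(tr <= 0 for tr in self.trs):
            raise ValueError("PipelineConfig.trs must be positive")
        for tr in self.trs:
            for w in self.windows:
                try:
                    fcd.WindowSpec.from_seconds(w, tr)
                except ValueError as err:
                    raise ValueError(
                        f"WindowSpec: window {w} s invalid at TR {tr} s: {err}"
                    ) from err
        if not 0 < self.threshold_p < 1:
            raise ValueError("threshold_p must be in (0, 1)")
        if self.baseline_seconds <= 0:
            raise ValueError("baseline_seconds must be > 0")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2 for the within-subject ANOVA")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.isi[0] > self.isi[1]:
            raise ValueError("isi must be (min, max) with min <= max")
        if not self.peak_band1[1] <= self.peak_band2[0]:
            raise ValueError("peak bands must be disjoint and ordered")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
            else json.loads(text)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    peaks: pd.DataFrame
    anova: dict[str, pd.DataFrame]
    posthoc: pd.DataFrame
    roi_epochs: dict[tuple[int, float, float], "eventlock.EpochSet"]
    provenance: dict
    out_dir: Path | None = None


def _child_seeds(seed: int, n: int) -> list[int]:
    # keep derived seeds below 2**31
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def demo_config(seed: int = 0, out_dir: str = "scratch/pipeline") -> PipelineConfig:
    """Desk-scale defaults: full 4 TR x 3 window grid, small voxel grid."""
    return PipelineConfig(seed=seed, out_dir=out_dir)


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Run all stages; returns the result bundle and (optionally) writes
    FCD volumes, epoch tables, the peak table, ANOVA/post-hoc tables and a
    provenance log under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    hrf = synth.HrfModel()
    network = synth.demo_network(shape=config.grid_shape)
    stage_log: list[str] = []
    checksums: dict[str, str] = {}

    seeds = _child_seeds(config.seed, config.n_subjects * (1 + len(config.trs)))
    peak_rows = []
    roi_epochs: dict[tuple[int, float, float], eventlock.EpochSet] = {}

    for s in range(config.n_subjects):
        ev_seed = seeds[s * (1 + len(config.trs))]
        try:
            events = synth.make_event_train(
                config.n_events, config.isi[0], config.isi[1],
                config.event_duration,
                config.total_time - hrf.duration, ev_seed, label="checkerboard")
        except ValueError as err:
            raise ValueError(f"simulate: event train for subject {s}: {err}") from err
        for t_i, tr in enumerate(config.trs):
            run_seed = seeds[s * (1 + len(config.trs)) + 1 + t_i]
            sim = synth.generate_bold(network, events, hrf, tr,
                                      config.total_time, run_seed)
            bold = sim.bold
            if config.denoise:
                conf = nuisance.assemble_confounds(
                    bold, sim.confounds.motion, sim.confounds.csf,
                    sim.confounds.wm, sim.confounds.cardiac,
                    sim.confounds.respiratory)
                bold = nuisance.partial_regress(bold, conf)
            roi_rows, t_map = eventlock.glm_localizer(
                bold, events, hrf, threshold_quantile=config.roi_quantile)
            stage_log.append(
                f"subject={s} tr={tr} voxels={bold.n_voxels} "
                f"events={len(events)} roi={roi_rows.size}")
            for w in config.windows:
                wspec = fcd.WindowSpec.from_seconds(w, tr)
                raw = fcd.sliding_fcd(bold, None, wspec, p=config.threshold_p,
                                      laterality=config.laterality)
                norm = fcd.normalize_fcd(raw)
                times, curve = eventlock.extract_region_timecourse(norm, roi_rows)
                epochs = eventlock.epoch_percent_change(
                    times, curve, events, pre=config.task_epoch[0],
                    post=config.task_epoch[1],
                    baseline=config.baseline_seconds, region="roi")
                roi_epochs[(s, tr, w)] = epochs
                p1, p2 = stats.find_peaks(epochs.offsets, epochs.average,
                                          config.peak_band1, config.peak_band2)
                for k, pk in ((1, p1), (2, p2)):
                    peak_rows.append(dict(subject=s, tr=tr, window=w,
                                          peak=k, amplitude=pk.amplitude,
                                          latency=pk.latency,
                                          local_max=pk.is_local_max))
                if write and s == 0 and t_i == len(config.trs) - 1 \
                        and w == config.windows[0]:
                    p = io.save_fcd(out / "sub-00_fcd.nii.gz", norm)
                    checksums[p.name] = _sha256(p)
                    p = io.save_epochs(out / "sub-00_epochs.tsv", epochs)
                    checksums[p.name] = _sha256(p)
        if write and s == 0:
            p = io.save_events(out / "sub-00_events.tsv", events)
            checksums[p.name] = _sha256(p)
            p = io.save_bold(out / "sub-00_bold.nii.gz", sim.bold)
            checksums[p.name] = _sha256(p)
            p = io.save_physio(out / "sub-00_cardiac.tsv", sim.confounds.cardiac)
            checksums[p.name] = _sha256(p)

    peaks = pd.DataFrame(peak_rows)
    anova: dict[str, pd.DataFrame] = {}
    for peak_index in (1, 2):
        for measure in ("amplitude", "latency"):
            sub = peaks[peaks["peak"] == peak_index]
            anova[f"peak{peak_index}_{measure}"] = stats.rm_anova(
                sub, dv=measure)
    posthoc = stats.posthoc_paired(peaks[peaks["peak"] == 1], dv="amplitude")

    provenance = {
        "config": config.to_dict(),
        "versions": _versions(),
        "stages": stage_log,
        "checksums": checksums,
    }
    result = PipelineResult(peaks=peaks, anova=anova, posthoc=posthoc,
                            roi_epochs=roi_epochs, provenance=provenance,
                            out_dir=out if write else None)
    if write:
        io.save_table(out / "peaks.tsv", peaks)
        for name, table in anova.items():
            io.save_table(out / f"anova_{name}.tsv", table)
            (out / f"anova_{name}.json").write_text(
                table.to_json(orient="records", indent=1))
        io.save_table(out / "posthoc_peak1_amplitude.tsv", posthoc)
        (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return result


def _versions() -> dict[str, str]:
    import nibabel
    import scipy

    return {"dfcd": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "nibabel": nibabel.__version__}
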