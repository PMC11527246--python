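"""End-to-end recipes: preprocess → cardiac → epoch → CCA → metrics → stats.

`run_pipeline` executes the full single-condition chain on a continuous
recording; passing a previously trained spatial-filter model switches to
the transfer recipe (filters trained on mixed-nerve data applied
unchanged to sensory-nerve epochs, keeping selection and testing
independent).  All stage parameters funnel through one
:class:`PipelineConfig`, loadable from a TOML file, and all randomness
through one integer seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np

from . import cardiac as _cardiac
from . import cca as _cca
from . import metrics as _metrics
from . import preprocess as _pre
from . import stats as _stats
from .io_montage import MontageSpec, Recording, builtin_montage, read_recording

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "save_epochs",
           "load_epochs"]


@dataclass
class PipelineConfig:
    """All stage parameters of the evoked-potential extraction recipe.

    Defaults follow the mixed-nerve cervical recipe: 30–400 Hz band-pass
    with a 48–53 Hz notch, epochs −200..700 ms baselined on −110..−10 ms,
    CCA trained on ±5 ms around the expected 13.3 ms negativity.
    """

    montage_name: str = "cervical"
    target_fs: float = 1000.0
    # stimulation artifact
    artifact_search_ms: tuple[float, float] = (-20.0, 30.0)
    artifact_window_ms: tuple[float, float] | None = None  # manual override
    # filtering
    band: tuple[float, float] | None = (30.0, 400.0)
    notch: tuple[float, float] | None = (48.0, 53.0)
    comb: tuple[float, int] | None = None
    # cardiac
    cardiac_enabled: bool = True
    cardiac_n_pcs: int = 4
    # referencing / rejection
    reference: str | None = "AC"  # ventral channel; None keeps the recording ref
    reject_threshold_uv: float = 100.0
    # epoching
    epoch_ms: tuple[float, float] = (-200.0, 700.0)
    baseline_ms: tuple[float, float] = (-110.0, -10.0)
    # CCA
    cca_halfwidth_ms: float = 5.0
    expected_latency_ms: float = 13.3
    expected_polarity: int = -1
    latency_tol_ms: float = 3.0
    # stats
    tail: str = "two"
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as f:
            raw = tomllib.load(f)
        flat: dict[str, Any] = {}
        for key, val in raw.items():
            if isinstance(val, dict):
                flat.update(val)
            else:
                flat[key] = val
        kwargs = {}
        for name, f_ in cls.__dataclass_fields__.items():
            if name in flat:
                v = flat[name]
                kwargs[name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    def montage(self) -> MontageSpec:
        return builtin_montage(self.montage_name)


@dataclass
class PipelineResult:
    """Per-stage outputs of one pipeline run."""

    artifact_window: _pre.ArtifactWindow
    r_peaks: _cardiac.RPeakSeries
    dropped_channels: list[str]
    epochs: _pre.EpochSet
    model: _cca.SpatialFilterModel
    traces: np.ndarray                 # trials x time component traces
    amplitudes: np.ndarray             # single-trial peak amplitudes (a.u.)
    component_measure: _metrics.EvokedMeasure
    target_measure: _metrics.EvokedMeasure
    ttest: _stats.TestResult
    manifest: dict = field(default_factory=dict)


def _component_average(traces: np.ndarray, retained: np.ndarray) -> np.ndarray:
    return traces[retained].mean(axis=0)


def run_pipeline(
    config: PipelineConfig,
    recording: Recording | str,
    model: _cca.SpatialFilterModel | None = None,
    out_dir: str | None = None,
    roles: dict[str, tuple[str, str]] | None = None,
) -> PipelineResult:
    """Run the full extraction chain on one continuous recording.

    ``recording`` is a :class:`Recording` or a BrainVision header path.
    When ``model`` is given, CCA training and component selection are
    skipped and the supplied filters are applied unchanged (transfer
    recipe).  ``out_dir`` receives per-stage text outputs and a
    ``manifest.json``.
    """
    montage = config.montage()
    if isinstance(recording, str):
        role_map = {lab: ("esg", montage.name) for lab in montage.labels}
        role_map.update({"AC": ("esg", "none"), "AL": ("esg", "none"),
                         "ECG": ("ecg", "none")})
        if roles:
            role_map.update(roles)
        recording = read_recording(recording, roles=role_map, montage=montage)
        recording.reference = montage.reference_label
    manifest: dict[str, Any] = {"config": asdict(config), "stages": []}

    # --- stage 1: preprocess (stim artifact, resample, reref, filter, reject)
    events = recording.event_samples()
    if config.artifact_window_ms is not None:
        window = _pre.ArtifactWindow(*config.artifact_window_ms,
                                     scope=montage.name)
    else:
        window = _pre.detect_stim_artifact_window(
            recording, events, montage.labels, config.artifact_search_ms
        )
    rec = _pre.interpolate_artifact(recording, events, window)
    rec = _pre.resample(rec, config.target_fs)
    events = rec.event_samples()
    manifest["stages"].append(
        {"stage": "preprocess", "artifact_window_ms": [window.start_ms,
                                                       window.end_ms],
         "fallback_window": window.fallback, "n_events": int(len(events))}
    )

    # --- stage 2: cardiac artifact removal on esg channels
    esg_idx = [i for i, c in enumerate(rec.channels) if c.role == "esg"]
    if config.cardiac_enabled:
        ecg_idx = [i for i, c in enumerate(rec.channels) if c.role == "ecg"]
        if not ecg_idx:
            raise RuntimeError("cardiac stage enabled but no ecg channel")
        peaks = _cardiac.detect_r_peaks(rec.data[ecg_idx[0]], rec.fs)
        rec.data[esg_idx] = _cardiac.remove_cardiac_multichannel(
            rec.data[esg_idx], peaks, n_pcs=config.cardiac_n_pcs
        )
    else:
        peaks = _cardiac.RPeakSeries(np.array([0, 1]), 1.0)
    manifest["stages"].append(
        {"stage": "cardiac", "enabled": config.cardiac_enabled,
         "n_r_peaks": int(len(peaks.peak_samples))}
    )

    if config.reference is not None:
        rec = _pre.rereference(rec, config.reference)
    rec = _pre.filter_zero_phase(rec, band=config.band, notch=config.notch,
                                 comb=config.comb)
    mask, dropped = _pre.reject_timepoints(
        rec, [_pre.RejectionRule(roles=("esg",),
                                 threshold_uv=config.reject_threshold_uv)]
    )

    # --- stage 3: epoching on the grid channels
    grid_labels = [lab for lab in montage.labels if lab not in dropped]
    epochs = _pre.epoch_and_baseline(
        rec, events, config.epoch_ms, config.baseline_ms, mask,
        channel_labels=grid_labels,
    )
    manifest["stages"].append(
        {"stage": "epoch", "n_trials": int(epochs.n_trials),
         "n_retained": int(epochs.retained.sum()),
         "dropped_channels": dropped}
    )

    # --- stage 4: CCA training/selection (or transfer)
    w = config.cca_halfwidth_ms
    cca_window = (config.expected_latency_ms - w, config.expected_latency_ms + w)
    if model is None:
        tm = _cca.build_train_matrices(epochs, cca_window)
        model = _cca.train_ccar(tm)
        model.channel_labels = epochs.labels
        model = _cca.select_component(
            model, epochs, config.expected_latency_ms, config.expected_polarity,
            config.latency_tol_ms, target_channel=montage.target_label
            if montage.target_label in epochs.labels else None,
        )
        transfer = False
    else:
        transfer = True
    traces = _cca.apply_filter(model, epochs)
    manifest["stages"].append(
        {"stage": "cca", "transfer": transfer,
         "selected": int(model.selected), "sign": int(model.sign),
         "corrs": [float(c) for c in model.corrs[:4]]}
    )

    # --- stage 5: metrics on the component and the anatomical target
    times = epochs.times_ms
    comp_avg = _component_average(traces, epochs.retained)
    search = (config.expected_latency_ms - config.latency_tol_ms,
              config.expected_latency_ms + config.latency_tol_ms)
    comp_meas = _metrics.peak_measure(
        comp_avg, times, search, config.expected_polarity,
        group_latency_ms=config.expected_latency_ms, source="cca",
    )
    comp_meas.snr = _metrics.snr(comp_avg, times, comp_meas.latency_ms)
    if montage.target_label in epochs.labels:
        tgt_avg = epochs.average()[epochs.labels.index(montage.target_label)]
        tgt_meas = _metrics.peak_measure(
            tgt_avg, times, search, config.expected_polarity,
            group_latency_ms=config.expected_latency_ms,
            source=montage.target_label,
        )
        tgt_meas.snr = _metrics.snr(tgt_avg, times, tgt_meas.latency_ms)
    else:
        tgt_meas = comp_meas
    manifest["stages"].append(
        {"stage": "metrics",
         "component": {"latency_ms": comp_meas.latency_ms,
                       "amplitude": comp_meas.amplitude, "snr": comp_meas.snr},
         "target": {"latency_ms": tgt_meas.latency_ms,
                    "amplitude": tgt_meas.amplitude, "snr": tgt_meas.snr}}
    )

    # --- stage 6: single-trial amplitudes and group-of-trials t test
    i_pk = epochs.time_index(comp_meas.latency_ms)
    amplitudes = traces[epochs.retained][:, i_pk]
    ttest = _stats.one_sample_t(amplitudes, tail=config.tail)
    manifest["stages"].append(
        {"stage": "stats", "t": ttest.statistic, "p": ttest.p_value,
         "cohens_d": ttest.cohens_d, "n": ttest.n}
    )

    result = PipelineResult(
        artifact_window=window, r_peaks=peaks, dropped_channels=dropped,
        epochs=epochs, model=model, traces=traces, amplitudes=amplitudes,
        component_measure=comp_meas, target_measure=tgt_meas, ttest=ttest,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, out_dir)
    return result


def _write_outputs(res: PipelineResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as f:
        json.dump(res.manifest, f, indent=2, sort_keys=True)
    np.savetxt(os.path.join(out_dir, "amplitudes.tsv"),
               res.amplitudes[:, None], fmt="%.9g", header="amplitude",
               comments="")
    comp_avg = _component_average(res.traces, res.epochs.retained)
    np.savetxt(os.path.join(out_dir, "component_average.tsv"),
               np.column_stack([res.epochs.times_ms, comp_avg]),
               fmt="%.9g", delimiter="\t", header="time_ms\tamplitude",
               comments="")
    with open(os.path.join(out_dir, "measures.tsv"), "w", encoding="utf-8") as f:
        f.write("source\tlatency_ms\tamplitude\tsnr\tvisible\n")
        for m in (res.component_measure, res.target_measure):
            f.write(f"{m.source}\t{m.latency_ms:.9g}\t{m.amplitude:.9g}\t"
                    f"{m.snr:.9g}\t{int(m.visible)}\n")
    w = res.artifact_window
    with open(os.path.join(out_dir, "artifact_window.tsv"), "w",
              encoding="utf-8") as f:
        f.write("patch\tstart_ms\tend_ms\tfallback\n")
        f.write(f"{w.scope}\t{w.start_ms:.9g}\t{w.end_ms:.9g}\t"
                f"{int(w.fallback)}\n")
    with open(os.path.join(out_dir, "rejection.tsv"), "w",
              encoding="utf-8") as f:
        f.write("channel\tdropped\n")
        for lab in res.epochs.labels:
            f.write(f"{lab}\t0\n")
        for lab in res.dropped_channels:
            f.write(f"{lab}\t1\n")


def save_epochs(epochs: _pre.EpochSet, path: str) -> None:
    """Persist an epoch set to HDF5 for the staged command-line flow."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("retained", data=epochs.retained)
        f.create_dataset("events", data=epochs.events)
        f.attrs["window_ms"] = epochs.window_ms
        f.attrs["baseline_ms"] = epochs.baseline_ms
        f.attrs["fs"] = epochs.fs
        f.attrs["labels"] = epochs.labels


def load_epochs(path: str) -> _pre.EpochSet:
    import h5py

    from .io_montage import ChannelInfo

    with h5py.File(path, "r") as f:
        return _pre.EpochSet(
            data=f["data"][()],
            window_ms=tuple(f.attrs["window_ms"]),
            baseline_ms=tuple(f.attrs["baseline_ms"]),
            fs=float(f.attrs["fs"]),
            retained=f["retained"][()].astype(bool),
            events=f["events"][()],
            channels=[ChannelInfo(lab) for lab in f.attrs["labels"]],
        )
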