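"""Shared fixtures: small synthetic study conditions sized for fast tests.

All recordings are generated at 1 kHz (the analysis rate of the pipeline)
with a few hundred trials, which keeps the full suite inside a desk-scale
budget while preserving every qualitative property of the full-scale
protocol (10 kHz, 2000 trials)."""

import warnings

import numpy as np
import pytest

import esgpipe as eg
from esgpipe import preprocess as pre

# the generator warns that 763 ms ISI epochs overlap; that is the emulated
# protocol's own geometry, not a test failure
warnings.filterwarnings("ignore", message=".*epochs overlap")
warnings.filterwarnings("ignore", message=".*samples per feature")


@pytest.fixture(scope="session")
def cervical():
    return eg.builtin_montage("cervical")


def make_config(
    seed=0,
    n_trials=300,
    fs=1000.0,
    amplitude_uv=1.4,
    amplitude_cv=0.3,
    white_sd=5.0,
    pink_sd=3.0,
    line_amp=0.0,
    ref_noise=5.0,
    cardiac=True,
    stim=True,
    center=(0.0, 0.0),
    scale_cm=2.0,
    latency_ms=13.3,
    isi_ms=763.0,
):
    mont = eg.builtin_montage("cervical")
    return eg.SimulationConfig(
        fs=fs,
        n_trials=n_trials,
        isi_ms=isi_ms,
        seed=seed,
        source=eg.SourceSpec(
            eg.dipole_pattern(mont, center, scale_cm),
            latency_ms=latency_ms,
            amplitude_uv=amplitude_uv,
            amplitude_cv=amplitude_cv,
        ),
        noise=eg.NoiseSpec(white_sd_uv=white_sd, pink_sd_uv=pink_sd,
                           line_amp_uv=line_amp, ref_noise_sd_uv=ref_noise),
        cardiac=eg.CardiacSpec(enabled=cardiac),
        stim_artifact=eg.StimArtifactSpec(enabled=stim),
        montage=mont,
    )


def grid_epochs(rec, window=(-200.0, 700.0), baseline=(-110.0, -10.0)):
    """Epoch the 17 grid channels of a synthetic recording."""
    grid = [lab for lab in rec.labels if lab not in ("AC", "AL", "ECG", "TH6")]
    return pre.epoch_and_baseline(rec, rec.event_samples(), window, baseline,
                                  channel_labels=grid)


@pytest.fixture(scope="session")
def default_block():
    """The default test fixture: one mixed-nerve-like stimulation block with
    evoked source, cardiac artifacts, stimulation transients and noise."""
    cfg = make_config(seed=7)
    rec, truth = eg.generate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def clean_block():
    """Artifact-free block (no cardiac, no stimulation transient)."""
    cfg = make_config(seed=11, cardiac=False, stim=False)
    rec, truth = eg.generate_recording(cfg)
    return cfg, rec, truth
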