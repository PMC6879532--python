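"""Seeded synthetic EEG cohorts with known spectral ground truth.

The generating model per scalp channel is a 1/f^alpha Gaussian background
plus fixed-frequency sinusoidal oscillators at the band centers (theta 5 Hz,
alpha 10 Hz, gamma 35 Hz) whose phase is redrawn every second, contaminated
with blink, EMG, spike and saturation artifacts.  Because the model is a sum
of a power-law background and pure tones, the relative band powers implied by
the generating amplitudes are available in closed form and are recorded as
the session's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import signal

from .config import (
    BANDS,
    FRONTAL_CHANNELS,
    GROUPS,
    MASTOID_CHANNELS,
    OSCILLATOR_FREQS,
    SimulationConfig,
)
from .io import MarkerStream, RawRecording, write_edf, write_manifest

#: Frequency range (Hz) covered by the 1-40 Hz analysis bins, bin-edge convention.
_TOTAL_RANGE = (0.5, 40.5)


@dataclass
class SyntheticSession:
    """One simulated recording session with its generating ground truth.

    ``truth`` maps task -> band -> true mean relative PSD per 1-Hz bin of that
    band (the quantity the spectral stage estimates); ``truth[task]["stmli"]``
    is the implied theta/gamma ratio at any scalp channel.
    ``artifact_truth`` lists injected events as (channel_label, class, start,
    end) sample intervals.
    """

    recording: RawRecording
    markers: MarkerStream
    truth: dict
    group_label: str
    participant_id: str
    artifact_truth: list = field(default_factory=list)


def _background_norm(config: SimulationConfig) -> float:
    """Constant c of the background PSD c / f^alpha such that the RMS over the
    generated range [0.5, Nyquist] equals ``background_rms``."""
    alpha = config.background_exponent
    f_lo, f_hi = 0.5, config.sampling_rate / 2
    if abs(alpha - 1.0) < 1e-12:
        integral = np.log(f_hi / f_lo)
    else:
        integral = (f_hi ** (1 - alpha) - f_lo ** (1 - alpha)) / (1 - alpha)
    return config.background_rms**2 / integral


def background_band_power(config: SimulationConfig, f1: float, f2: float) -> float:
    """Analytic background power (uV^2) in the frequency interval [f1, f2)."""
    c = _background_norm(config)
    alpha = config.background_exponent
    if abs(alpha - 1.0) < 1e-12:
        return c * np.log(f2 / f1)
    return c * (f2 ** (1 - alpha) - f1 ** (1 - alpha)) / (1 - alpha)


def analytic_band_truth(
    config: SimulationConfig, amplitudes: dict[str, float]
) -> dict[str, float]:
    """True mean relative PSD per bin for each band, given oscillator RMS
    amplitudes (uV).  Also returns the implied theta/gamma STMLI."""
    osc_power = {band: amp**2 for band, amp in amplitudes.items()}
    total = background_band_power(config, *_TOTAL_RANGE) + sum(osc_power.values())
    truth: dict[str, float] = {}
    for band, (lo, hi) in BANDS.items():
        n_bins = hi - lo + 1
        power = background_band_power(config, lo - 0.5, hi + 0.5)
        for osc_band, f in OSCILLATOR_FREQS.items():
            if lo - 0.5 <= f < hi + 0.5:
                power += osc_power.get(osc_band, 0.0)
        truth[band] = power / total / n_bins
    truth["stmli"] = truth["theta"] / truth["gamma"]
    return truth


def _pink_noise(n: int, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with one-sided PSD c/f^alpha on [0.5, Nyquist] Hz."""
    fs = config.sampling_rate
    c = _background_norm(config)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(freqs)
    in_band = freqs >= 0.5
    # one-sided PSD of filtered white noise: 2|H|^2/fs = c/f^alpha
    shape[in_band] = np.sqrt(c * fs / 2.0 / freqs[in_band] ** config.background_exponent)
    white = rng.standard_normal(n)
    return np.fft.irfft(np.fft.rfft(white) * shape, n=n)


def _oscillator(
    n: int, fs: float, freq: float, rms: float, rng: np.random.Generator
) -> np.ndarray:
    """Sinusoid of given RMS with one random phase per (task) segment.

    The phase is constant within the segment: a phase discontinuity inside an
    analysis window would scatter sidelobe power across all bins and break
    the closed-form band-power ground truth.
    """
    phase = rng.uniform(0, 2 * np.pi)
    if rms == 0.0:
        return np.zeros(n)
    t = np.arange(n) / fs
    return rms * np.sqrt(2.0) * np.sin(2 * np.pi * freq * t + phase)


def _inject_artifacts(
    samples: np.ndarray,
    labels: tuple[str, ...],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple[str, str, int, int]]:
    """Add artifact events in place; return the truth event log."""
    fs = config.sampling_rate
    n = samples.shape[1]
    minutes = n / fs / 60.0
    scalp = [i for i, lbl in enumerate(labels) if lbl not in MASTOID_CHANNELS]
    frontal = [i for i, lbl in enumerate(labels) if lbl in FRONTAL_CHANNELS]
    events: list[tuple[str, str, int, int]] = []

    def _count(cls: str) -> int:
        return rng.poisson(config.artifact_rates.get(cls, 0.0) * minutes)

    for _ in range(_count("blink")):
        dur = int(round(0.4 * fs))
        start = int(rng.integers(0, max(1, n - dur)))
        amp = rng.uniform(100.0, 300.0)
        shape = amp * 0.5 * (1 - np.cos(2 * np.pi * np.arange(dur) / dur))
        for ch in frontal:
            samples[ch, start : start + dur] += shape
            events.append((labels[ch], "blink", start, start + dur))

    for _ in range(_count("emg")):
        dur = int(round(rng.uniform(1.0, 3.0) * fs))
        start = int(rng.integers(0, max(1, n - dur)))
        ch = int(rng.choice(scalp))
        sos = signal.butter(4, [20, 100], btype="bandpass", fs=fs, output="sos")
        burst = signal.sosfilt(sos, rng.standard_normal(dur))
        burst *= 60.0 / max(np.std(burst), 1e-12)
        samples[ch, start : start + dur] += burst
        events.append((labels[ch], "emg", start, start + dur))

    for _ in range(_count("spike")):
        pos = int(rng.integers(1, n - 1))
        ch = int(rng.choice(scalp))
        samples[ch, pos] += rng.choice([-1.0, 1.0]) * 200.0
        events.append((labels[ch], "spike", pos, pos + 1))

    for _ in range(_count("saturation")):
        dur = int(round(0.5 * fs))
        start = int(rng.integers(0, max(1, n - dur)))
        ch = int(rng.choice(scalp))
        rail = config.saturation_rail * rng.choice([-1.0, 1.0])
        samples[ch, start : start + dur] = rail
        events.append((labels[ch], "saturation", start, start + dur))

    return events


def simulate_session(
    config: SimulationConfig, group: str, participant_seed: int, participant_id: str = "P000"
) -> SyntheticSession:
    """Generate one synthetic session: recording + markers + ground truth.

    The layout is an inter-task gap, then each task interval, each followed by
    a gap.  Oscillators are active only inside task intervals; the 1/f
    background runs throughout.  Identical (config, group, seed) arguments
    yield bit-identical output.
    """
    config.validate()
    if group not in GROUPS:
        raise ValueError(f"unknown group label {group!r}")
    rng = np.random.default_rng(participant_seed)
    fs = config.sampling_rate
    gap = int(round(config.inter_task_gap_s * fs))
    task_len = int(round(config.task_duration_s * fs))
    n_tasks = len(config.task_names)
    n = gap + n_tasks * (task_len + gap)
    labels = config.channel_labels
    n_ch = len(labels)

    # per-participant log-normal amplitude multipliers, one per band
    multipliers = {
        band: float(np.exp(config.subject_amp_sigma * rng.standard_normal()))
        for band in OSCILLATOR_FREQS
    }

    samples = np.zeros((n_ch, n))
    for ch, lbl in enumerate(labels):
        if lbl in MASTOID_CHANNELS:
            samples[ch] = config.mastoid_noise_rms * rng.standard_normal(n)
        else:
            samples[ch] = _pink_noise(n, config, rng)

    markers = MarkerStream()
    truth: dict[str, dict[str, float]] = {}
    pos = gap
    for task in config.task_names:
        start, end = pos, pos + task_len
        markers.entries.append((task, start, end))
        base_amps = config.band_amplitudes[group][task]
        amps = {band: base_amps.get(band, 0.0) * multipliers[band] for band in OSCILLATOR_FREQS}
        for ch, lbl in enumerate(labels):
            if lbl in MASTOID_CHANNELS:
                continue
            for band, f in OSCILLATOR_FREQS.items():
                samples[ch, start:end] += _oscillator(task_len, fs, f, amps[band], rng)
        truth[task] = analytic_band_truth(config, amps)
        pos = end + gap

    artifact_truth = _inject_artifacts(samples, labels, config, rng)

    recording = RawRecording(
        samples=samples, channel_labels=labels, sampling_rate=fs, reference="raw"
    )
    markers.validate(recording.n_samples, known_tasks=config.task_names)
    return SyntheticSession(
        recording=recording,
        markers=markers,
        truth=truth,
        group_label=group,
        participant_id=participant_id,
        artifact_truth=artifact_truth,
    )


def cohort_members(config: SimulationConfig) -> list[tuple[str, str, int]]:
    """Deterministic (participant_id, group, seed) roster for a cohort."""
    config.validate()
    n_total = config.n_group_noconc + config.n_group_conc
    seeds = np.random.SeedSequence(config.seed).generate_state(n_total)
    members = []
    for i in range(config.n_group_noconc):
        members.append((f"N{i + 1:03d}", "none", int(seeds[i])))
    for j in range(config.n_group_conc):
        members.append((f"C{j + 1:03d}", "concussion", int(seeds[config.n_group_noconc + j])))
    return members


def iter_cohort_sessions(config: SimulationConfig) -> Iterator[SyntheticSession]:
    """Lazily generate the cohort's sessions (memory-friendly for long runs)."""
    for pid, group, seed in cohort_members(config):
        yield simulate_session(config, group, seed, participant_id=pid)


def simulate_cohort(config: SimulationConfig) -> tuple[list[SyntheticSession], pd.DataFrame]:
    """Materialize all sessions plus the cohort manifest (in-memory paths empty)."""
    sessions = list(iter_cohort_sessions(config))
    manifest = pd.DataFrame(
        {
            "participant_id": [s.participant_id for s in sessions],
            "group": [s.group_label for s in sessions],
            "edf_path": "",
            "markers_path": "",
        }
    )
    return sessions, manifest


def write_cohort(config: SimulationConfig, out_dir: str | Path) -> Path:
    """Write a full cohort to disk: EDF per session, markers/truth CSVs, manifest.

    Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    truth_rows = []
    for session in iter_cohort_sessions(config):
        pid = session.participant_id
        edf_path = out / f"{pid}.edf"
        markers_path = out / f"{pid}_markers.csv"
        write_edf(session.recording, edf_path)
        session.markers.to_csv(markers_path)
        rows.append(
            {
                "participant_id": pid,
                "group": session.group_label,
                "edf_path": str(edf_path),
                "markers_path": str(markers_path),
            }
        )
        for task, bands in session.truth.items():
            truth_rows.append({"participant_id": pid, "task": task, **bands})
    manifest_path = out / "manifest.csv"
    write_manifest(rows, manifest_path)
    pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False)
    return manifest_path
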