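"""Per-epoch relative PSD in 1-Hz bins (1-40 Hz) from decontaminated EEG.

Each 1-second epoch is analyzed through three 50%-overlapping one-second
overlays (256 samples each, Kaiser-tapered FFT).  An overlay containing more
than 128 inserted zeros is rejected; an epoch keeps fewer than two usable
overlays is invalid.  Valid epochs yield 40 relative-PSD bins (bin k covers
[k-0.5, k+0.5) Hz; with 1-second windows each FFT bin falls exactly on an
integer frequency), normalized by the summed 1-40 Hz PSD so that in the
default linear domain the bins sum to exactly 1.

Band values are the means of the constituent relative bins: theta 3-7 Hz,
alpha 8-12 Hz, low beta 13-19 Hz, high beta 20-29 Hz, gamma 30-40 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .config import BANDS
from .io import MarkerStream, RawRecording

N_BINS = 40
WINDOW_SAMPLES = 256
MAX_ZEROS_PER_OVERLAY = 128


@dataclass
class SpectralConfig:
    kaiser_beta: float = 2.0
    rel_domain: str = "linear"  # or "log10"
    log_floor: float = 1e-12  # PSD floor before log10 in log10 mode

    def __post_init__(self) -> None:
        if self.rel_domain not in ("linear", "log10"):
            raise ValueError("rel_domain must be 'linear' or 'log10'")


@dataclass
class OverlaySpectrum:
    """PSD of one 256-sample overlay, plus the zero-insertion count."""

    psd_bins: np.ndarray  # 40 values, uV^2, bins 1..40 Hz
    zero_count: int

    @property
    def valid(self) -> bool:
        return self.zero_count <= MAX_ZEROS_PER_OVERLAY


@dataclass
class EpochSpectrum:
    epoch_index: int
    task_label: str
    rel_psd_bins: np.ndarray | None  # 40 values, None when invalid
    valid: bool
    n_overlays_used: int


@dataclass
class BandRelPSD:
    theta: float
    alpha: float
    low_beta: float
    high_beta: float
    gamma: float

    def as_dict(self) -> dict[str, float]:
        return {
            "theta": self.theta,
            "alpha": self.alpha,
            "low_beta": self.low_beta,
            "high_beta": self.high_beta,
            "gamma": self.gamma,
        }


@lru_cache(maxsize=8)
def _kaiser(beta: float) -> np.ndarray:
    return np.kaiser(WINDOW_SAMPLES, beta)


def _psd_windows(windows: np.ndarray, beta: float) -> np.ndarray:
    """Tapered-FFT power of bins 1..40 for a stack of 256-sample windows.

    Energy (Parseval) normalization: a sinusoid of RMS r contributes total
    power r^2 summed over bins, exactly and regardless of the taper.
    """
    w = _kaiser(beta)
    spec = np.fft.rfft(windows * w, axis=-1)
    power = 2.0 * np.abs(spec) ** 2 / (WINDOW_SAMPLES * (w**2).sum())
    return power[..., 1 : N_BINS + 1]


def overlay_psd(window: np.ndarray, config: SpectralConfig | None = None) -> OverlaySpectrum:
    """PSD of one overlay.  ``zero_count`` is taken before tapering."""
    cfg = config or SpectralConfig()
    window = np.asarray(window, dtype=float)
    if window.shape != (WINDOW_SAMPLES,):
        raise ValueError(f"overlay must contain exactly {WINDOW_SAMPLES} samples")
    zero_count = int(np.count_nonzero(window == 0.0))
    psd = _psd_windows(window[None, :], cfg.kaiser_beta)[0]
    return OverlaySpectrum(psd_bins=psd, zero_count=zero_count)


def epoch_tasks(recording: RawRecording, markers: MarkerStream) -> list[tuple[str, int]]:
    """Tile each task interval with consecutive 1-s epochs; return
    (task_label, epoch_start_sample) pairs.  Trailing partial seconds are
    discarded; sub-second tasks yield no epochs (warned)."""
    markers.validate(recording.n_samples)
    out: list[tuple[str, int]] = []
    for task, start, end in markers.entries:
        n_ep = (end - start) // WINDOW_SAMPLES
        if n_ep == 0:
            warnings.warn(f"task {task}: interval shorter than 1 s, no epochs produced")
            continue
        out.extend((task, start + i * WINDOW_SAMPLES) for i in range(n_ep))
    return out


def epoch_spectrum(
    overlays: list[OverlaySpectrum],
    mode: str = "linear",
    epoch_index: int = 0,
    task_label: str = "",
    log_floor: float = 1e-12,
) -> EpochSpectrum:
    """Combine the epoch's overlays into one relative spectrum.

    Overlays with more than 128 inserted zeros are rejected; fewer than two
    usable overlays invalidates the epoch.
    """
    if not overlays:
        raise ValueError("epoch has no overlays")
    valid = [o for o in overlays if o.valid]
    if len(valid) < 2:
        return EpochSpectrum(epoch_index, task_label, None, False, len(valid))
    mean_psd = np.mean([o.psd_bins for o in valid], axis=0)
    rel = _relative(mean_psd, mode, log_floor)
    if rel is None:
        return EpochSpectrum(epoch_index, task_label, None, False, len(valid))
    return EpochSpectrum(epoch_index, task_label, rel, True, len(valid))


def _relative(psd: np.ndarray, mode: str, log_floor: float) -> np.ndarray | None:
    if mode == "linear":
        total = psd.sum()
        if total <= 0:
            return None
        return psd / total
    logp = np.log10(np.maximum(psd, log_floor))
    total = logp.sum()
    if abs(total) < 1e-9:
        return None
    return logp / total


def band_average(epoch: EpochSpectrum) -> BandRelPSD:
    """Mean relative PSD over each band's constituent 1-Hz bins."""
    if not epoch.valid or epoch.rel_psd_bins is None:
        raise ValueError("cannot band-average an invalid epoch")
    vals = {}
    for band, (lo, hi) in BANDS.items():
        vals[band] = float(epoch.rel_psd_bins[lo - 1 : hi].mean())
    return BandRelPSD(**vals)


def compute_band_table(
    recording: RawRecording,
    markers: MarkerStream,
    config: SpectralConfig | None = None,
) -> pd.DataFrame:
    """Per-epoch, per-channel band table for a decontaminated recording.

    Columns: task, epoch (index within task), channel, theta..gamma, valid,
    n_overlays.  Band columns are NaN for invalid epochs.
    """
    cfg = config or SpectralConfig()
    markers.validate(recording.n_samples)
    half = WINDOW_SAMPLES // 2
    band_names = list(BANDS)
    # 5 x 40 band-averaging matrix: row b averages the band's constituent bins
    bmat = np.zeros((len(band_names), N_BINS))
    for b, (lo, hi) in enumerate(BANDS.values()):
        bmat[b, lo - 1 : hi] = 1.0 / (hi - lo + 1)

    acc = {c: [] for c in ("task", "epoch", "channel", "valid", "n_overlays", "bands")}
    for task, start, end in markers.entries:
        n_ep = (end - start) // WINDOW_SAMPLES
        if n_ep == 0:
            warnings.warn(f"task {task}: interval shorter than 1 s, no epochs produced")
            continue
        # all half-step overlay start offsets that fit inside the task interval
        n_overlay = (end - start - WINDOW_SAMPLES) // half + 1
        # overlay indices (2i-1, 2i, 2i+1) per epoch, with availability mask
        cand = np.stack(
            [2 * np.arange(n_ep) - 1, 2 * np.arange(n_ep), 2 * np.arange(n_ep) + 1], axis=1
        )
        avail = (cand >= 0) & (cand < n_overlay)
        cand_c = np.clip(cand, 0, n_overlay - 1)
        for ch_i, ch_label in enumerate(recording.channel_labels):
            seg = recording.samples[ch_i, start:end]
            windows = sliding_window_view(seg, WINDOW_SAMPLES)[::half][:n_overlay]
            zero_counts = (windows == 0.0).sum(axis=1)
            psds = _psd_windows(windows, cfg.kaiser_beta)
            ok = zero_counts <= MAX_ZEROS_PER_OVERLAY
            usable = avail & ok[cand_c]  # (n_ep, 3)
            n_used = usable.sum(axis=1)
            valid = n_used >= 2
            # mean over usable overlays
            weighted = (psds[cand_c] * usable[..., None]).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                mean_psd = weighted / n_used[:, None]
            bands = np.full((n_ep, len(band_names)), np.nan)
            for i in np.flatnonzero(valid):
                rel = _relative(mean_psd[i], cfg.rel_domain, cfg.log_floor)
                if rel is None:
                    valid[i] = False
                else:
                    bands[i] = bmat @ rel
            acc["task"].append(np.repeat(task, n_ep))
            acc["epoch"].append(np.arange(n_ep))
            acc["channel"].append(np.repeat(ch_label, n_ep))
            acc["valid"].append(valid)
            acc["n_overlays"].append(n_used)
            acc["bands"].append(bands)

    cols = ["task", "epoch", "channel"] + band_names + ["valid", "n_overlays"]
    if not acc["task"]:
        return pd.DataFrame(columns=cols)
    band_block = np.concatenate(acc["bands"])
    df = pd.DataFrame(
        {
            "task": np.concatenate(acc["task"]),
            "epoch": np.concatenate(acc["epoch"]),
            "channel": np.concatenate(acc["channel"]),
            **{b: band_block[:, i] for i, b in enumerate(band_names)},
            "valid": np.concatenate(acc["valid"]),
            "n_overlays": np.concatenate(acc["n_overlays"]),
        }
    )
    return df[cols]
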