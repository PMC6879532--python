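"""Shared constants and configuration containers.

The nine timed visuo-motor tasks of the sensory-station battery, the
9-channel frontal/central/parietal montage with linked-mastoid references,
and the five canonical EEG bands (in 1-Hz relative-PSD bins) are fixed
vocabulary used across every module.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: The nine station tasks, in administration order.
TASKS: tuple[str, ...] = ("VC", "CS", "DP", "NFQ", "PS", "HRT", "EHC", "TC", "GNG")

#: Tasks with a dominant visuo-motor-control component (significant working
#: memory + temporal processing demands driving a motor response).
VISUOMOTOR_TASKS: tuple[str, ...] = ("PS", "HRT", "EHC", "GNG")

#: Scalp montage (frontal, central, parietal-occipital) and mastoid references.
SCALP_CHANNELS: tuple[str, ...] = ("Fz", "F3", "F4", "Cz", "C3", "C4", "POz", "P3", "P4")
MASTOID_CHANNELS: tuple[str, ...] = ("M1", "M2")
FRONTAL_CHANNELS: tuple[str, ...] = ("Fz", "F3", "F4")

#: Band name -> inclusive (low_bin, high_bin) range of 1-Hz relative-PSD bins.
BANDS: dict[str, tuple[int, int]] = {
    "theta": (3, 7),
    "alpha": (8, 12),
    "low_beta": (13, 19),
    "high_beta": (20, 29),
    "gamma": (30, 40),
}

GROUP_NONE = "none"
GROUP_CONCUSSION = "concussion"
GROUPS = (GROUP_NONE, GROUP_CONCUSSION)

#: Center frequencies (Hz) of the band-limited oscillators the simulator injects.
OSCILLATOR_FREQS: dict[str, float] = {"theta": 5.0, "alpha": 10.0, "gamma": 35.0}

ARTIFACT_CLASSES = ("blink", "emg", "spike", "saturation")


def default_band_amplitudes(
    theta: float = 6.0,
    alpha: float = 6.0,
    gamma: float = 5.0,
    gamma_contrast: float = 0.25,
    contrast_tasks: tuple[str, ...] = VISUOMOTOR_TASKS,
) -> dict[str, dict[str, dict[str, float]]]:
    """Build the group -> task -> band oscillator RMS amplitude map (uV).

    The concussion-history group carries ``(1 + gamma_contrast)`` times the
    gamma-oscillator amplitude on the visuo-motor-control tasks, emulating the
    relatively larger frontal gamma power (hence lower theta/gamma ratio)
    reported for athletes with a concussion history.
    """
    base = {"theta": theta, "alpha": alpha, "gamma": gamma}
    amplitudes: dict[str, dict[str, dict[str, float]]] = {}
    for group in GROUPS:
        amplitudes[group] = {}
        for task in TASKS:
            amps = dict(base)
            if group == GROUP_CONCUSSION and task in contrast_tasks:
                amps["gamma"] = gamma * (1.0 + gamma_contrast)
            amplitudes[group][task] = amps
    return amplitudes


def default_artifact_rates() -> dict[str, float]:
    """Events per minute per artifact class (cohort-level defaults)."""
    return {"blink": 12.0, "emg": 1.0, "spike": 0.5, "saturation": 0.2}


@dataclass
class SimulationConfig:
    """Ground-truth generating model for a synthetic EEG cohort.

    Each scalp channel is a 1/f^alpha Gaussian background plus fixed-frequency
    sinusoidal oscillators at the band centers (theta 5 Hz, alpha 10 Hz,
    gamma 35 Hz) with a random phase per task interval, contaminated by
    blink, EMG, spike and saturation artifacts at the configured rates.

    Amplitudes are RMS in microvolts.  ``subject_amp_sigma`` is the standard
    deviation of a per-participant, per-band log-normal amplitude multiplier
    (constant across tasks) modelling inter-individual variability.
    """

    sampling_rate: float = 256.0
    channel_labels: tuple[str, ...] = SCALP_CHANNELS + MASTOID_CHANNELS
    n_group_noconc: int = 56
    n_group_conc: int = 17
    task_names: tuple[str, ...] = TASKS
    task_duration_s: float = 60.0
    inter_task_gap_s: float = 2.0
    background_exponent: float = 1.0
    background_rms: float = 15.0
    band_amplitudes: dict = field(default_factory=default_band_amplitudes)
    artifact_rates: dict = field(default_factory=default_artifact_rates)
    subject_amp_sigma: float = 0.05
    mastoid_noise_rms: float = 0.5
    saturation_rail: float = 1000.0
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.task_duration_s <= 2.0:
            raise ValueError("task_duration_s must exceed 2 s")
        if self.inter_task_gap_s < 0:
            raise ValueError("inter_task_gap_s must be non-negative")
        if len(self.task_names) != 9:
            raise ValueError("exactly 9 tasks are required")
        if self.n_group_noconc < 2 and self.n_group_noconc != 0:
            raise ValueError("n_group_noconc must be >= 2 (or 0 for a single-group cohort)")
        if self.n_group_conc < 2 and self.n_group_conc != 0:
            raise ValueError("n_group_conc must be >= 2 (or 0 for a single-group cohort)")
        if self.n_group_conc == 0 and self.n_group_noconc == 0:
            raise ValueError("cohort must contain at least one group")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        for group, tasks in self.band_amplitudes.items():
            if group not in GROUPS:
                raise ValueError(f"unknown group label {group!r}")
            for task, bands in tasks.items():
                for band, amp in bands.items():
                    if amp < 0:
                        raise ValueError(f"negative amplitude for {group}/{task}/{band}")
        for cls, rate in self.artifact_rates.items():
            if rate < 0:
                raise ValueError(f"negative artifact rate for {cls!r}")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["channel_labels"] = list(self.channel_labels)
        d["task_names"] = list(self.task_names)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("channel_labels", "task_names"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg
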