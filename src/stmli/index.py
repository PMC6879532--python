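"""The short-term memory load index (STMLI) and its robust aggregation.

STMLI is the ratio of relative theta (3-7 Hz) to relative gamma (30-40 Hz)
PSD at the frontal midline electrode Fz, computed for every valid 1-second
epoch.  Per participant and task, epochs are aggregated with a 5% trimmed
mean (5% per tail, the EXAMINE convention: floor(0.05 n) values dropped from
each end, so no trimming occurs below n = 20), eliminating epochs with
extreme values.

Because STMLI is a within-epoch ratio of two relative-PSD values, it is
invariant to any common rescaling of the relative spectrum (including a x100
percentage convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import TASKS
from .io import ChannelMissingError
from .spectral import BandRelPSD


@dataclass
class StmliRecord:
    participant_id: str
    task_label: str
    epoch_index: int
    stmli: float


@dataclass
class ParticipantTaskSummary:
    participant_id: str
    group_label: str
    task_label: str
    stmli_trimmed_mean: float
    n_epochs_used: int
    n_epochs_trimmed: int


def stmli(band: BandRelPSD) -> float:
    """Relative theta over relative gamma for one epoch at Fz."""
    if band.gamma == 0:
        raise ZeroDivisionError("relative gamma power is zero for this epoch")
    return band.theta / band.gamma


def trimmed_mean_5(values, proportion: float = 0.05) -> float:
    """Per-tail trimmed mean: drop floor(proportion*n) values from each end."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot aggregate an empty sequence")
    return float(stats.trim_mean(values, proportion))


def epoch_stmli_table(band_table: pd.DataFrame, channel: str = "Fz") -> pd.DataFrame:
    """Per-epoch STMLI at the given channel from a spectral band table.

    Valid epochs with exactly zero relative gamma power (degenerate synthetic
    input only) are dropped and counted in the ``n_dropped_zero_gamma`` attr.
    """
    if channel not in set(band_table["channel"]):
        raise ChannelMissingError(f"channel {channel!r} absent from band table")
    sel = band_table[(band_table["channel"] == channel) & band_table["valid"]].copy()
    zero_gamma = sel["gamma"] == 0
    n_dropped = int(zero_gamma.sum())
    sel = sel[~zero_gamma]
    out = sel[["task", "epoch"]].copy()
    out["stmli"] = (sel["theta"] / sel["gamma"]).to_numpy()
    out.attrs["n_dropped_zero_gamma"] = n_dropped
    return out.reset_index(drop=True)


def summarize_participant(
    stmli_table: pd.DataFrame,
    participant_id: str,
    group_label: str,
    proportion: float = 0.05,
) -> list[ParticipantTaskSummary]:
    """5%-trimmed-mean STMLI per task for one participant."""
    summaries = []
    for task, grp in stmli_table.groupby("task", sort=False):
        vals = grp["stmli"].to_numpy()
        if vals.size == 0:
            continue
        k = math.floor(proportion * vals.size)
        summaries.append(
            ParticipantTaskSummary(
                participant_id=participant_id,
                group_label=group_label,
                task_label=str(task),
                stmli_trimmed_mean=trimmed_mean_5(vals, proportion),
                n_epochs_used=vals.size - 2 * k,
                n_epochs_trimmed=2 * k,
            )
        )
    return summaries


def build_cohort_table(summaries: list[ParticipantTaskSummary]) -> pd.DataFrame:
    """Wide participants x tasks STMLI matrix with a ``group`` column.

    Tasks without a reported summary are explicit NaN cells; duplicate
    (participant, task) summaries are an error.
    """
    if not summaries:
        return pd.DataFrame(columns=["group", *TASKS])
    long = pd.DataFrame(
        {
            "participant_id": [s.participant_id for s in summaries],
            "group": [s.group_label for s in summaries],
            "task": [s.task_label for s in summaries],
            "stmli": [s.stmli_trimmed_mean for s in summaries],
        }
    )
    dup = long.duplicated(subset=["participant_id", "task"])
    if dup.any():
        bad = long.loc[dup, ["participant_id", "task"]].to_records(index=False)
        raise ValueError(f"duplicate (participant, task) summaries: {list(bad)[:5]}")
    wide = long.pivot(index="participant_id", columns="task", values="stmli")
    wide = wide.reindex(columns=[t for t in TASKS if t in wide.columns])
    groups = long.drop_duplicates("participant_id").set_index("participant_id")["group"]
    wide.insert(0, "group", groups)
    wide.columns.name = None
    return wide
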