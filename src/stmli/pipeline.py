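"""End-to-end orchestration: simulate/read -> preprocess -> spectra -> STMLI
-> group statistics, with a structured, reproducible run report.

Stages communicate through plain CSV/EDF artifacts so each is independently
re-runnable; the run report records the configuration hash and every
exclusion (overlay, epoch, participant) with its reason.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .config import TASKS, SimulationConfig
from .index import build_cohort_table, epoch_stmli_table, summarize_participant
from .io import (
    MarkerStream,
    RawRecording,
    read_edf,
    read_manifest,
    rereference_linked_mastoids,
)
from .preprocess import PreprocessConfig, preprocess_recording
from .simulate import SyntheticSession, iter_cohort_sessions
from .spectral import SpectralConfig, compute_band_table
from .stats import (
    MixedAnovaReport,
    component_mixed_anova,
    anderson_rubin_scores,
    levene_gated_ttest,
    mahalanobis_screen,
    mixed_anova,
    pca_varimax,
)

log = logging.getLogger("stmli")


@dataclass
class RunConfig:
    manifest: str = ""
    out_dir: str = "stmli_out"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    alpha: float = 0.05
    trim: float = 0.05
    mahalanobis_p: float = 0.001
    eigen_cutoff: float = 0.80
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not (0 <= self.trim < 0.5):
            raise ValueError("trim must be in [0, 0.5)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.mahalanobis_p < 1):
            raise ValueError("mahalanobis_p must be in (0, 1)")
        if self.eigen_cutoff <= 0:
            raise ValueError("eigen_cutoff must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "preprocess" in d:
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        if "spectral" in d:
            d["spectral"] = SpectralConfig(**d["spectral"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def hash(self) -> str:
        """Digest of the analysis-relevant configuration (not output paths)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def process_session(
    recording: RawRecording,
    markers: MarkerStream,
    pre_cfg: PreprocessConfig | None = None,
    spec_cfg: SpectralConfig | None = None,
) -> pd.DataFrame:
    """Re-reference, filter, decontaminate and spectrally analyze one session."""
    rec = rereference_linked_mastoids(recording) if recording.reference == "raw" else recording
    clean, _mask = preprocess_recording(rec, pre_cfg)
    return compute_band_table(clean, markers, spec_cfg)


def analyze_sessions(
    sessions: Iterable[SyntheticSession],
    pre_cfg: PreprocessConfig | None = None,
    spec_cfg: SpectralConfig | None = None,
    trim: float = 0.05,
) -> pd.DataFrame:
    """In-memory pipeline: synthetic sessions -> wide cohort STMLI table."""
    summaries = []
    for session in sessions:
        band_table = process_session(session.recording, session.markers, pre_cfg, spec_cfg)
        stmli_tab = epoch_stmli_table(band_table)
        summaries.extend(
            summarize_participant(stmli_tab, session.participant_id, session.group_label, trim)
        )
    return build_cohort_table(summaries)


def analyze_synthetic_cohort(
    sim_config: SimulationConfig,
    pre_cfg: PreprocessConfig | None = None,
    spec_cfg: SpectralConfig | None = None,
    trim: float = 0.05,
) -> pd.DataFrame:
    """Simulate a full cohort (lazily, one session at a time) and reduce it to
    the wide participants x tasks STMLI table."""
    return analyze_sessions(iter_cohort_sessions(sim_config), pre_cfg, spec_cfg, trim)


def _anova_dict(report: MixedAnovaReport) -> dict:
    d = {
        name: {
            "SS": e.ss,
            "df1": e.df1,
            "df2": e.df2,
            "F": e.F,
            "p": e.p,
            "partial_eta_sq": e.partial_eta_sq,
            "gg_adjusted": e.gg_adjusted,
        }
        for name, e in report.effects.items()
    }
    d["mauchly_w"] = report.mauchly_w
    d["mauchly_p"] = report.mauchly_p
    d["gg_epsilon"] = report.gg_epsilon
    d["sphericity_assumed"] = report.sphericity_assumed
    d["n_per_group"] = report.n_per_group
    return d


def cohort_statistics(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    mahalanobis_p: float = 0.001,
    eigen_cutoff: float = 0.80,
) -> dict:
    """The full statistical chain on a wide STMLI cohort table.

    Steps: listwise completion, Mahalanobis outlier screening, 2 x k mixed
    ANOVA, per-task descriptives and group comparisons, PCA with varimax and
    Anderson-Rubin scores, and (when two components are retained) the 2 x 2
    component-score mixed ANOVA.
    """
    if cohort.empty:
        raise ValueError("cohort table is empty")
    task_cols = [c for c in cohort.columns if c != "group"]
    complete = cohort.dropna(subset=task_cols)
    n_dropped = len(cohort) - len(complete)
    groups = complete["group"].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("group statistics require at least 2 groups")

    X = complete[task_cols].to_numpy(dtype=float)
    screen = mahalanobis_screen(X, index=list(complete.index), p_cut=mahalanobis_p)
    retained = complete.loc[screen.retained]
    Xr = retained[task_cols].to_numpy(dtype=float)
    gr = retained["group"].to_numpy()
    if len(np.unique(gr)) < 2:
        raise ValueError("outlier screening removed an entire group")

    anova = mixed_anova(Xr, gr, correction="auto", alpha=alpha)

    descriptives = {}
    per_task_tests = {}
    glabels = sorted(np.unique(gr))
    for j, task in enumerate(task_cols):
        descriptives[task] = {
            g: {
                "mean": float(Xr[gr == g, j].mean()),
                "se": float(Xr[gr == g, j].std(ddof=1) / np.sqrt((gr == g).sum())),
            }
            for g in glabels
        }
        row = levene_gated_ttest(Xr[gr == glabels[0], j], Xr[gr == glabels[1], j], measure=task)
        per_task_tests[task] = {"t": row.t, "df": row.df, "p": row.p, "variant": row.variant}

    pca = pca_varimax(Xr, eigen_cutoff=eigen_cutoff, variable_names=task_cols)
    result = {
        "n_listwise_dropped": n_dropped,
        "mahalanobis": {
            "cutoff": screen.cutoff,
            "excluded": [str(i) for i in screen.excluded_indices],
        },
        "mixed_anova": _anova_dict(anova),
        "descriptives": descriptives,
        "per_task_tests": per_task_tests,
        "pca": {
            "kmo": pca.kmo,
            "bartlett_chi2": pca.bartlett_chi2,
            "bartlett_df": pca.bartlett_df,
            "bartlett_p": pca.bartlett_p,
            "eigenvalues": pca.eigenvalues.tolist(),
            "n_components": pca.n_components,
            "variance_explained_pct": pca.variance_explained_pct,
            "loadings": {
                task: pca.loadings[i].tolist() for i, task in enumerate(pca.variable_names)
            },
        },
    }
    if pca.n_components == 2:
        scores = anderson_rubin_scores(Xr, pca.loadings)
        comp_anova = component_mixed_anova(scores, gr)
        result["component_anova"] = _anova_dict(comp_anova)
        result["component_scores_group_means"] = {
            g: scores[gr == g].mean(axis=0).tolist() for g in glabels
        }
    else:
        result["component_anova"] = None
    return result


def run(config: RunConfig) -> dict:
    """Disk-based run: manifest of EDF + marker files -> report JSON + CSVs."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(config.manifest)
    if manifest.empty:
        raise ValueError("manifest is empty")

    summaries = []
    exclusions = []
    for row in manifest.itertuples():
        try:
            recording = read_edf(row.edf_path)
            markers = MarkerStream.from_csv(row.markers_path)
            band_table = process_session(recording, markers, config.preprocess, config.spectral)
        except Exception as exc:
            raise RuntimeError(
                f"stage=session participant={row.participant_id} file={row.edf_path}: {exc}"
            ) from exc
        stmli_tab = epoch_stmli_table(band_table)
        if stmli_tab.empty:
            exclusions.append(
                {"participant_id": row.participant_id, "reason": "no valid STMLI epochs"}
            )
            log.warning("participant %s yielded no valid STMLI epochs", row.participant_id)
            continue
        summaries.extend(
            summarize_participant(stmli_tab, row.participant_id, row.group, config.trim)
        )

    cohort = build_cohort_table(summaries)
    cohort.to_csv(out / "cohort_stmli.csv")
    try:
        statistics = cohort_statistics(
            cohort, config.alpha, config.mahalanobis_p, config.eigen_cutoff
        )
    except ValueError as exc:
        raise RuntimeError(f"stage=group_stats: {exc}") from exc

    report = {
        "config_hash": config.hash(),
        "manifest": str(config.manifest),
        "n_sessions": int(len(manifest)),
        "exclusions": exclusions,
        "statistics": statistics,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def make_figures(statistics: dict, out_dir: str | Path) -> list[Path]:
    """Interaction plot of group x task STMLI means, and the PCA scree plot."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    desc = statistics["descriptives"]
    tasks = [t for t in TASKS if t in desc]
    fig, ax = plt.subplots(figsize=(7, 4))
    for group in sorted(next(iter(desc.values())).keys()):
        means = [desc[t][group]["mean"] for t in tasks]
        ses = [desc[t][group]["se"] for t in tasks]
        ax.errorbar(tasks, means, yerr=ses, marker="o", capsize=3, label=group)
    ax.set_xlabel("Task")
    ax.set_ylabel("STMLI (trimmed mean)")
    ax.legend(title="Concussion history")
    fig.tight_layout()
    p = out / "stmli_by_task.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    paths.append(p)

    eig = statistics["pca"]["eigenvalues"]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(range(1, len(eig) + 1), eig, "o-")
    ax.axhline(0.80, ls="--", color="gray", lw=1)
    ax.set_xlabel("Component")
    ax.set_ylabel("Eigenvalue")
    fig.tight_layout()
    p = out / "scree.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    paths.append(p)
    return paths
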