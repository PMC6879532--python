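"""Group-comparison statistics for STMLI cohorts.

The chain mirrors a classical SPSS-style analysis: variance-gated independent
t-tests with Dunn-Bonferroni control for the behavioral measures; Mahalanobis
outlier screening; a 2 (group) x 9 (task) mixed between-within ANOVA with
Mauchly's sphericity test, Greenhouse-Geisser adjustment and partial eta
squared; and a PCA of the 9 task STMLI variables (KMO and Bartlett
diagnostics, eigenvalue retention, Kaiser-normalized varimax rotation,
Anderson-Rubin component scores) followed by a 2 x 2 mixed ANOVA on the
scores.

The mixed ANOVA uses the classical partitioned sums of squares for one
between- and one within-subject factor (complete cases only); Mauchly's W and
the Greenhouse-Geisser epsilon are computed from the within-group pooled
covariance of the repeated measures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# t-tests


@dataclass
class TTestRow:
    """One Table-style row of an independent-groups comparison."""

    measure: str
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    mean_difference: float  # mean1 - mean2
    ci_low: float
    ci_high: float
    t: float
    df: float
    p: float
    levene_f: float
    levene_p: float
    variant: str  # "pooled" or "welch"
    significant_adjusted: bool | None = None


def trim_tails(values, proportion: float = 0.05) -> np.ndarray:
    """Drop floor(proportion*n) values from each end of the sorted sample."""
    values = np.sort(np.asarray(values, dtype=float))
    k = math.floor(proportion * values.size)
    return values[k : values.size - k] if k else values


def levene_gated_ttest(
    group1,
    group2,
    measure: str = "",
    alpha: float = 0.05,
    trim: float = 0.0,
) -> TTestRow:
    """Independent-samples t-test with the variant chosen by Levene's test.

    Levene's test (mean-centered) at ``alpha`` decides between the pooled
    (equal-variance) and Welch statistics.  ``trim`` > 0 first applies a
    per-tail trim to each group (robust descriptives convention).
    """
    g1 = trim_tails(group1, trim) if trim > 0 else np.asarray(group1, dtype=float)
    g2 = trim_tails(group2, trim) if trim > 0 else np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least 2 observations")
    v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise ValueError("both groups have zero variance")
    lev_f, lev_p = stats.levene(g1, g2, center="mean")
    equal_var = lev_p >= alpha
    n1, n2 = g1.size, g2.size
    diff = g1.mean() - g2.mean()
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
        variant = "pooled"
    else:
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
        variant = "welch"
    tval = diff / se if se > 0 else 0.0
    p = 2 * stats.t.sf(abs(tval), df)
    tcrit = stats.t.ppf(0.975, df)
    return TTestRow(
        measure=measure,
        mean1=float(g1.mean()),
        sd1=float(np.sqrt(v1)),
        n1=n1,
        mean2=float(g2.mean()),
        sd2=float(np.sqrt(v2)),
        n2=n2,
        mean_difference=float(diff),
        ci_low=float(diff - tcrit * se),
        ci_high=float(diff + tcrit * se),
        t=float(tval),
        df=float(df),
        p=float(p),
        levene_f=float(lev_f),
        levene_p=float(lev_p),
        variant=variant,
    )


def dunn_bonferroni(
    t_values, m: int, df: float, alpha: float = 0.05
) -> tuple[float, np.ndarray]:
    """Bonferroni-adjusted two-tailed decisions over m comparisons.

    Returns the critical |t| at per-comparison alpha/m and the boolean
    decision vector |t| >= critical.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if df <= 0:
        raise ValueError("df must be positive")
    critical = float(stats.t.ppf(1 - alpha / (2 * m), df))
    decisions = np.abs(np.asarray(t_values, dtype=float)) >= critical
    return critical, decisions


# ---------------------------------------------------------------------------
# multivariate outlier screening


@dataclass
class MahalanobisScreen:
    distances_sq: np.ndarray
    cutoff: float
    retained: np.ndarray  # boolean mask
    excluded_indices: list


def mahalanobis_screen(X, index=None, p_cut: float = 0.001) -> MahalanobisScreen:
    """Exclude rows whose squared Mahalanobis distance exceeds the
    chi-square(p) quantile at ``p_cut`` (p = number of columns)."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than columns ({p})")
    center = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    try:
        cov_inv = np.linalg.inv(cov)
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "covariance matrix is singular; cannot screen outliers"
        ) from None
    delta = X - center
    d2 = np.einsum("ij,jk,ik->i", delta, cov_inv, delta)
    cutoff = float(stats.chi2.ppf(1 - p_cut, df=p))
    retained = d2 <= cutoff
    idx = list(range(n)) if index is None else list(index)
    excluded = [idx[i] for i in np.flatnonzero(~retained)]
    return MahalanobisScreen(
        distances_sq=d2, cutoff=cutoff, retained=retained, excluded_indices=excluded
    )


# ---------------------------------------------------------------------------
# mixed between-within ANOVA


@dataclass
class EffectResult:
    name: str
    ss: float
    df1: float
    df2: float
    F: float
    p: float
    partial_eta_sq: float
    gg_adjusted: bool = False


@dataclass
class MixedAnovaReport:
    between: EffectResult
    within: EffectResult
    interaction: EffectResult
    mauchly_w: float | None
    mauchly_p: float | None
    gg_epsilon: float | None
    sphericity_assumed: bool
    n_per_group: dict = field(default_factory=dict)

    @property
    def effects(self) -> dict[str, EffectResult]:
        return {"between": self.between, "within": self.within,
                "interaction": self.interaction}


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows orthogonal to the mean)."""
    helmert = np.zeros((k - 1, k))
    for i in range(k - 1):
        helmert[i, : i + 1] = 1.0
        helmert[i, i + 1] = -(i + 1.0)
        helmert[i] /= np.linalg.norm(helmert[i])
    return helmert


def _pooled_within_cov(Y: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, int]:
    levels = np.unique(groups)
    k = Y.shape[1]
    pooled = np.zeros((k, k))
    df = 0
    for g in levels:
        Yi = Y[groups == g]
        if Yi.shape[0] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
        pooled += (Yi.shape[0] - 1) * np.cov(Yi, rowvar=False, ddof=1)
        df += Yi.shape[0] - 1
    return pooled / df, df


def sphericity_mauchly(Y: np.ndarray, groups: np.ndarray) -> tuple[float, float, float]:
    """Mauchly's W and its chi-square p-value, plus the GG epsilon, computed
    from the within-group pooled covariance of the repeated measures."""
    Y = np.asarray(Y, dtype=float)
    k = Y.shape[1]
    S, df_err = _pooled_within_cov(Y, np.asarray(groups))
    C = _orthonormal_contrasts(k)
    M = C @ S @ C.T
    eigvals = np.linalg.eigvalsh(M)
    eigvals = np.clip(eigvals, 1e-300, None)
    km1 = k - 1
    W = float(np.prod(eigvals) / (eigvals.mean() ** km1))
    eps = float(eigvals.sum() ** 2 / (km1 * (eigvals**2).sum()))
    eps = min(1.0, max(eps, 1.0 / km1))
    if km1 < 2:
        return 1.0, 1.0, 1.0
    d = 1 - (2 * km1**2 + km1 + 2) / (6 * km1 * df_err)
    chi2 = -df_err * d * np.log(max(W, 1e-300))
    df_m = k * km1 / 2 - 1
    p = float(stats.chi2.sf(chi2, df_m))
    return W, p, eps


def mixed_anova(
    data: pd.DataFrame | np.ndarray,
    groups=None,
    correction: str | bool = "auto",
    alpha: float = 0.05,
) -> MixedAnovaReport:
    """Two-factor mixed ANOVA: one between-subject factor, one repeated factor.

    ``data`` is a wide subjects x levels matrix (or a DataFrame with a
    ``group`` column); rows with missing cells are dropped (listwise).
    ``correction='auto'`` applies the Greenhouse-Geisser df adjustment to the
    within and interaction effects when Mauchly's test rejects sphericity at
    ``alpha``; ``True`` forces it, ``False`` disables it.
    """
    if isinstance(data, pd.DataFrame):
        if groups is None:
            if "group" not in data.columns:
                raise ValueError("DataFrame input requires a 'group' column")
            groups = data["group"].to_numpy()
            Y = data.drop(columns="group").to_numpy(dtype=float)
        else:
            Y = data.to_numpy(dtype=float)
            groups = np.asarray(groups)
    else:
        Y = np.asarray(data, dtype=float)
        groups = np.asarray(groups)
    complete = ~np.isnan(Y).any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        warnings.warn(f"mixed_anova: {n_dropped} subject(s) dropped listwise")
    Y, groups = Y[complete], groups[complete]
    levels = np.unique(groups)
    a = len(levels)
    N, k = Y.shape
    if a < 2:
        raise ValueError("between factor needs at least 2 groups")
    if k < 2:
        raise ValueError("within factor needs at least 2 levels")

    grand = Y.mean()
    ss_total = ((Y - grand) ** 2).sum()
    # within main effect (level means over all subjects)
    level_means = Y.mean(axis=0)
    ss_with = N * ((level_means - grand) ** 2).sum()
    # between main effect (group means over all observations)
    n_i = np.array([(groups == g).sum() for g in levels])
    group_means = np.array([Y[groups == g].mean() for g in levels])
    ss_betw = k * (n_i * (group_means - grand) ** 2).sum()
    # cell residuals
    ss_resall = 0.0
    for g in levels:
        Yi = Y[groups == g]
        ss_resall += ((Yi - Yi.mean(axis=0)) ** 2).sum()
    ss_inter = ss_total - ss_resall - ss_with - ss_betw
    # repeated-measures error ignoring group, minus the interaction
    subj_means = Y.mean(axis=1, keepdims=True)
    ss_rm_err = ((Y - subj_means - level_means + grand) ** 2).sum()
    ss_reswith = ss_rm_err - ss_inter
    ss_resbetw = ss_total - ss_with - ss_betw - ss_reswith - ss_inter

    df_betw, df_resbetw = a - 1, N - a
    df_with = k - 1
    df_reswith = df_with * df_resbetw
    df_inter = df_betw * df_with

    ms = lambda ss, df: ss / df
    f_betw = ms(ss_betw, df_betw) / ms(ss_resbetw, df_resbetw)
    f_with = ms(ss_with, df_with) / ms(ss_reswith, df_reswith)
    f_inter = ms(ss_inter, df_inter) / ms(ss_reswith, df_reswith)

    if correction is False or k == 2:
        W, p_sph, eps = (None, None, None) if k > 2 else (1.0, 1.0, 1.0)
        apply_gg = False
        sphericity_ok = True
    else:
        W, p_sph, eps = sphericity_mauchly(Y, groups)
        sphericity_ok = p_sph >= alpha
        apply_gg = correction is True or (correction == "auto" and not sphericity_ok)

    def _effect(name, ss, df1, df2, F, err_ss, adjust):
        if adjust:
            d1, d2 = df1 * eps, df2 * eps
        else:
            d1, d2 = df1, df2
        p = float(stats.f.sf(F, d1, d2))
        return EffectResult(
            name=name,
            ss=float(ss),
            df1=float(d1),
            df2=float(d2),
            F=float(F),
            p=p,
            partial_eta_sq=float(ss / (ss + err_ss)),
            gg_adjusted=bool(adjust),
        )

    report = MixedAnovaReport(
        between=_effect("between", ss_betw, df_betw, df_resbetw, f_betw, ss_resbetw, False),
        within=_effect("within", ss_with, df_with, df_reswith, f_with, ss_reswith, apply_gg),
        interaction=_effect(
            "interaction", ss_inter, df_inter, df_reswith, f_inter, ss_reswith, apply_gg
        ),
        mauchly_w=W,
        mauchly_p=p_sph,
        gg_epsilon=eps,
        sphericity_assumed=sphericity_ok,
        n_per_group={str(g): int(n) for g, n in zip(levels, n_i)},
    )
    return report


# ---------------------------------------------------------------------------
# PCA with varimax rotation and Anderson-Rubin scores


@dataclass
class PcaReport:
    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    eigenvalues: np.ndarray
    n_components: int
    loadings: np.ndarray  # p x k, varimax-rotated
    variance_explained_pct: float
    variable_names: list


def kmo_bartlett(R: np.ndarray, n_obs: int) -> tuple[float, float, int, float]:
    """Kaiser-Meyer-Olkin sampling adequacy and Bartlett's sphericity test.

    KMO compares squared correlations with squared anti-image partial
    correlations; Bartlett's statistic is
    -(n - 1 - (2p + 5)/6) * ln det(R) on p(p-1)/2 degrees of freedom.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if R.shape != (p, p) or not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("R must be a symmetric correlation matrix")
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("correlation matrix is not positive definite") from None
    V = np.linalg.inv(R)
    d = np.sqrt(np.diag(V))
    partial = -V / np.outer(d, d)
    off = ~np.eye(p, dtype=bool)
    denom = (R[off] ** 2).sum() + (partial[off] ** 2).sum()
    # undefined when there are no correlations at all (identity matrix)
    kmo = float((R[off] ** 2).sum() / denom) if denom > 0 else float("nan")
    sign, logdet = np.linalg.slogdet(R)
    chi2 = float(-(n_obs - 1 - (2 * p + 5) / 6) * logdet)
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return kmo, chi2, df, pval


def varimax(
    loadings: np.ndarray,
    normalize: bool = True,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> np.ndarray:
    """Kaiser-normalized varimax rotation of a p x k loading matrix."""
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L
    if normalize:
        h = np.sqrt((L**2).sum(axis=1))
        h[h == 0] = 1.0
        L = L / h[:, None]
    R = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        B = L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        U, s, Vt = np.linalg.svd(B)
        R = U @ Vt
        d_new = s.sum()
        if d_new - d_old < tol * max(d_new, 1.0):
            break
        d_old = d_new
    out = L @ R
    if normalize:
        out = out * h[:, None]
    # orient each component so its largest loading is positive
    for j in range(k):
        if out[np.argmax(np.abs(out[:, j])), j] < 0:
            out[:, j] = -out[:, j]
    return out


def pca_varimax(
    X: pd.DataFrame | np.ndarray,
    eigen_cutoff: float = 0.80,
    variable_names: list | None = None,
) -> PcaReport:
    """PCA of the correlation matrix with eigenvalue retention and varimax.

    Components with eigenvalue > ``eigen_cutoff`` are retained; their
    loadings (eigenvector x sqrt(eigenvalue)) are varimax-rotated.
    """
    if isinstance(X, pd.DataFrame):
        variable_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than variables")
    if variable_names is None:
        variable_names = [f"v{i + 1}" for i in range(p)]
    R = np.corrcoef(X, rowvar=False)
    kmo, chi2, df, pval = kmo_bartlett(R, n)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = eigvals > eigen_cutoff
    k = int(keep.sum())
    if k == 0:
        raise ValueError(f"no eigenvalue exceeds the cutoff {eigen_cutoff}")
    if np.allclose(eigvals, 1.0, atol=0.05):
        warnings.warn("correlation matrix is near-spherical; retention is not meaningful")
    loadings = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    rotated = varimax(loadings) if k >= 2 else np.abs(loadings) * np.sign(loadings.sum())
    return PcaReport(
        kmo=kmo,
        bartlett_chi2=chi2,
        bartlett_df=df,
        bartlett_p=pval,
        eigenvalues=eigvals,
        n_components=k,
        loadings=rotated,
        variance_explained_pct=float(eigvals[:k].sum() / p * 100.0),
        variable_names=variable_names,
    )


def anderson_rubin_scores(
    X: pd.DataFrame | np.ndarray,
    loadings: np.ndarray,
    R: np.ndarray | None = None,
) -> np.ndarray:
    """Anderson-Rubin component scores: exactly zero mean and identity
    sample covariance, by construction W = R^-1 L (L' R^-1 L)^-1/2."""
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    if R is None:
        R = np.corrcoef(X, rowvar=False)
    L = np.atleast_2d(np.asarray(loadings, dtype=float))
    if L.shape[0] != R.shape[0]:
        raise ValueError("loadings rows must match the number of variables")
    Rinv = np.linalg.inv(R)
    A = L.T @ Rinv @ L
    w, V = np.linalg.eigh(A)
    if np.any(w <= 0):
        raise np.linalg.LinAlgError("loadings are collinear under R^-1 metric")
    A_isqrt = V @ np.diag(1.0 / np.sqrt(w)) @ V.T
    return Z @ Rinv @ L @ A_isqrt


def component_mixed_anova(scores: np.ndarray, groups) -> MixedAnovaReport:
    """2 x 2 mixed ANOVA on two component scores (no sphericity correction
    is needed or applied at two within levels)."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("exactly 2 component-score columns are required")
    return mixed_anova(scores, groups, correction=False)
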