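"""Morphotype delineation and group testing.

PCA of the nine size-adjusted measurements (correlation-matrix PCA by
default, appropriate for mixed-magnitude measurements), silhouette-based
choice of the number of clusters, k-means (Lloyd's algorithm with seeded
restarts), one-way MANOVA via Pillai's trace, and Bonferroni-corrected
post hoc two-sample tests per measurement.

The post hoc default is Welch's unequal-variance t (the fractional degrees
of freedom this produces match how such comparisons are conventionally
reported); a pooled-variance Student variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_score


# ---------------------------------------------------------------- PCA

@dataclass
class MeasurementPCA:
    scores: np.ndarray            # (n, p)
    percent_variance: np.ndarray  # non-increasing, sums to 100
    eigenvalues: np.ndarray
    loadings: np.ndarray          # (p, p): columns are components
    variables: tuple[str, ...]


def measurement_pca(
    table: pd.DataFrame,
    variables: tuple[str, ...],
    use_correlation: bool = True,
) -> MeasurementPCA:
    """PCA of the size-adjusted measurements.

    Standardizes each variable to unit variance (eigendecomposition of the
    correlation matrix) unless ``use_correlation`` is False.  Component
    signs follow a deterministic convention: the largest-magnitude loading
    of each component is positive.
    """
    if len(table) < 3:
        raise ValueError("PCA needs >= 3 specimens")
    X = table.loc[:, list(variables)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values in measurement table")
    sd = X.std(axis=0, ddof=1)
    constant = [v for v, s in zip(variables, sd) if s == 0]
    if constant:
        raise ValueError(f"constant variable(s): {constant}")
    centered = X - X.mean(axis=0)
    Z = centered / sd if use_correlation else centered
    cov = (Z.T @ Z) / (len(Z) - 1)
    eigenvalues, vecs = np.linalg.eigh(cov)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = np.clip(eigenvalues[order], 0, None)
    vecs = vecs[:, order]
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(vecs.shape[1]):
        if vecs[np.argmax(np.abs(vecs[:, j])), j] < 0:
            vecs[:, j] *= -1
    percent = 100.0 * eigenvalues / eigenvalues.sum()
    return MeasurementPCA(
        scores=Z @ vecs,
        percent_variance=percent,
        eigenvalues=eigenvalues,
        loadings=vecs,
        variables=tuple(variables),
    )


# ---------------------------------------------------------------- k-means

@dataclass
class KMeansResult:
    assignments: np.ndarray   # labels in 1..k
    centers: np.ndarray       # (k, d)
    inertia: float            # best within-cluster sum of squares
    objective_trace: list[float] = field(default_factory=list)


def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator) -> KMeansResult:
    n = len(X)
    centers = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.zeros(n, dtype=int)
    trace: list[float] = []
    for _ in range(300):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        obj = float(d2[np.arange(n), labels].sum())
        if trace and trace[-1] - obj < 1e-12 * max(1.0, trace[-1]):
            trace.append(obj)
            break
        trace.append(obj)
        for j in range(k):
            members = X[labels == j]
            if len(members) == 0:
                # re-seed an emptied cluster at the point farthest from its center
                far = int(d2.min(axis=1).argmax())
                centers[j] = X[far]
            else:
                centers[j] = members.mean(axis=0)
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(n), labels].sum())
    return KMeansResult(labels + 1, centers, inertia, trace)


def kmeans_cluster(
    scores: np.ndarray,
    k: int,
    restarts: int = 50,
    seed: int = 0,
) -> KMeansResult:
    """Lloyd's k-means with seeded random restarts; best inertia kept.

    Labels are 1-based.  The per-iteration objective trace of the winning
    restart is retained (it is non-increasing by construction of the
    assign/update steps; tests assert this).
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(X):
        raise ValueError(f"k={k} exceeds n={len(X)}")
    root = np.random.SeedSequence(seed)
    best: KMeansResult | None = None
    for child in root.spawn(restarts):
        res = _lloyd(X, k, np.random.default_rng(child))
        if best is None or res.inertia < best.inertia:
            best = res
    assert best is not None
    return best


def select_k_silhouette(
    scores: np.ndarray,
    k_range: tuple[int, ...] = (2, 3, 4, 5),
    restarts: int = 50,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose k by maximising the mean silhouette width (Euclidean).

    Runs :func:`kmeans_cluster` for each candidate k and scores the
    partition; ties resolve to the smaller k.  Returns the chosen k and the
    silhouette-by-k table.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(X) < 3:
        raise ValueError("silhouette selection needs >= 3 points")
    rows = []
    for k in sorted(k_range):
        if not 2 <= k <= len(X) - 1:
            raise ValueError(f"k={k} outside [2, n-1]")
        res = kmeans_cluster(X, k, restarts=restarts, seed=seed)
        width = float(silhouette_score(X, res.assignments, metric="euclidean"))
        rows.append({"k": k, "mean_silhouette": width})
    table = pd.DataFrame(rows)
    chosen = int(table.loc[table["mean_silhouette"].idxmax(), "k"])
    return chosen, table


# ---------------------------------------------------------------- MANOVA

@dataclass
class GroupComparison:
    statistic_name: str
    statistic: float
    df1: float
    df2: float
    p_value: float
    f_statistic: float | None = None   # F approximation (MANOVA)
    rows: pd.DataFrame | None = None   # per-measurement post hoc rows
    adjusted_alpha: float | None = None


def manova_pillai(
    table: pd.DataFrame,
    variables: tuple[str, ...],
    assignments: np.ndarray,
) -> GroupComparison:
    """One-way MANOVA via Pillai's trace.

    V = trace(H (H + E)^-1) with H the between-group and E the
    within-group cross-product matrices, and the standard F approximation
    F = ((2n + s + 1) / (2m + s + 1)) * (V / (s - V)) on
    (s(2m + s + 1), s(2n + s + 1)) degrees of freedom.
    """
    X = table.loc[:, list(variables)].to_numpy(dtype=float)
    labels = np.asarray(assignments)
    groups = np.unique(labels)
    g, (N, p) = len(groups), X.shape
    if g < 2:
        raise ValueError("need >= 2 groups")
    grand = X.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for lab in groups:
        sub = X[labels == lab]
        diff = sub.mean(axis=0) - grand
        H += len(sub) * np.outer(diff, diff)
        resid = sub - sub.mean(axis=0)
        E += resid.T @ resid
    T = H + E
    if np.linalg.matrix_rank(T) < p:
        raise np.linalg.LinAlgError("singular total cross-product matrix")
    V = float(np.trace(H @ np.linalg.inv(T)))
    s = min(p, g - 1)
    m = (abs(p - g + 1) - 1) / 2
    n_ = (N - g - p - 1) / 2
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * n_ + s + 1)
    F = (df2 / df1) * (V / (s - V))
    p_value = float(stats.f.sf(F, df1, df2))
    return GroupComparison("Pillai", V, df1, df2, p_value, f_statistic=float(F))


# ---------------------------------------------------------------- post hoc

def welch_t_from_stats(
    mean1: float, se1: float, n1: int, mean2: float, se2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's t from summary statistics (means, standard errors, sizes).

    Returns (t, Welch-Satterthwaite df, two-sided p).  Useful for
    recomputing published comparisons from printed summary tables.
    """
    v1, v2 = se1**2, se2**2  # variances of the means
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def posthoc_welch(
    table: pd.DataFrame,
    variables: tuple[str, ...],
    assignments: np.ndarray,
    m_tests: int | None = None,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> GroupComparison:
    """Per-measurement two-sample t tests between exactly two groups.

    Welch's unequal-variance t by default (``equal_var=True`` gives the
    pooled Student variant).  Bonferroni control is reported both ways:
    adjusted alpha = alpha / m and adjusted p = min(1, m p).  The group
    with the smaller label is the first term of the difference.
    """
    labels = np.asarray(assignments)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"exactly 2 groups required, got {len(groups)}")
    m = m_tests if m_tests is not None else len(variables)
    rows = []
    for v in variables:
        a = table.loc[labels == groups[0], v].to_numpy(dtype=float)
        b = table.loc[labels == groups[1], v].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"{v}: each group needs >= 2 observations")
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append(
            {
                "measurement": v,
                "mean_1": a.mean(),
                "mean_2": b.mean(),
                "t": float(res.statistic),
                "df": float(res.df),
                "p": float(res.pvalue),
                "p_bonferroni": min(1.0, m * float(res.pvalue)),
                "significant": float(res.pvalue) < alpha / m,
            }
        )
    df_rows = pd.DataFrame(rows)
    top = df_rows.loc[df_rows["t"].abs().idxmax()]
    return GroupComparison(
        statistic_name="Welch-t" if not equal_var else "Student-t",
        statistic=float(top["t"]),
        df1=1.0,
        df2=float(top["df"]),
        p_value=float(top["p"]),
        rows=df_rows,
        adjusted_alpha=alpha / m,
    )


# ---------------------------------------------------------------- checks

def assumption_checks(
    table: pd.DataFrame,
    variables: tuple[str, ...],
    assignments: np.ndarray,
) -> pd.DataFrame:
    """Shapiro-Wilk normality (per group) and Levene equal-variance checks.

    Diagnostic report only; results never gate the pipeline.  Degenerate
    samples (constant values) are reported as not applicable (NaN).
    """
    labels = np.asarray(assignments)
    groups = np.unique(labels)
    rows = []
    for v in variables:
        samples = [table.loc[labels == g, v].to_numpy(dtype=float) for g in groups]
        for g, s in zip(groups, samples):
            if len(s) < 3 or np.ptp(s) == 0:
                rows.append({"variable": v, "test": "shapiro", "group": g,
                             "statistic": np.nan, "p": np.nan, "note": "not applicable"})
            else:
                w, p = stats.shapiro(s)
                rows.append({"variable": v, "test": "shapiro", "group": g,
                             "statistic": float(w), "p": float(p), "note": ""})
        if len(groups) >= 2 and all(len(s) >= 2 for s in samples) and any(np.ptp(s) > 0 for s in samples):
            w, p = stats.levene(*samples)
            rows.append({"variable": v, "test": "levene", "group": "all",
                         "statistic": float(w), "p": float(p), "note": ""})
        else:
            rows.append({"variable": v, "test": "levene", "group": "all",
                         "statistic": np.nan, "p": np.nan, "note": "not applicable"})
    return pd.DataFrame(rows)
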