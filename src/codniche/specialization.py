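"""Individual-specialization statistics from repeated isotope measurements.

The core decomposition treats the two blood tissues of each fish as
repeated measures of its isotopic niche and fits the random-intercept
mixed model

    y_it = b0 + b1 * FL_i + b2 * tissue_t + u_i + e_it,
    u_i ~ N(0, sigma2_B),  e_it ~ N(0, sigma2_W),

by restricted maximum likelihood (REML).  The residual variance sigma2_W
is the within-individual component (WIC: isotopic variation of one fish
across tissues/time, i.e. diet/habitat switching), the random-intercept
variance sigma2_B is the between-individual component (BIC: spread of
individual mean niches), TNW = WIC + BIC is the total niche width, and
IS = WIC / TNW in [0, 1] is the individual specialization index: values
near 0 mean a population of individual specialists, values near 1 mean
every individual is as generalist as the population.

The REML fit is native: the criterion is profiled over the variance ratio
lambda = sigma2_B / sigma2_W with generalized-least-squares fixed effects
at each lambda, a 1-D bounded search on log(lambda), and the boundary
lambda = 0 admitted explicitly (published decompositions report BIC = 0.00
cases, so boundary solutions are expected and flagged).

Individual-level WIC values come from an ordinary regression between the
two tissues (plasma predicted from RBC by default): the absolute residual
of each fish is its individual WIC, log10-transformed before GLM testing
against morphotype cluster, fork length and sampling year, with
non-significant interaction terms dropped sequentially by smallest |t|
unless removal raises AIC by more than 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.optimize import brentq, minimize_scalar

logger = logging.getLogger(__name__)


# ------------------------------------------------------------- REML core

@dataclass
class VarianceDecomposition:
    isotope: str
    group: str
    wic: float                  # sigma2_W, per-mil squared
    bic: float                  # sigma2_B, per-mil squared
    n_fish: int
    n_obs: int
    fixed_effects: dict[str, float] = field(default_factory=dict)
    boundary: bool = False      # lambda converged to 0
    lambda_hat: float = 0.0
    reml_criterion: float = np.nan

    @property
    def tnw(self) -> float:
        return self.wic + self.bic

    @property
    def is_index(self) -> float:
        return is_index(self.wic, self.bic)


def is_index(wic: float, bic: float) -> float:
    """Individual specialization index IS = WIC / (WIC + BIC), in [0, 1]."""
    if wic < 0 or bic < 0:
        raise ValueError("variance components must be non-negative")
    tnw = wic + bic
    if tnw == 0:
        raise ZeroDivisionError("TNW = 0: IS undefined")
    return wic / tnw


class _GroupStats:
    """Per-fish sufficient statistics for O(G p^2) criterion evaluations.

    With V0 = I + lam Z Z', the per-fish block inverse is closed form,
    (I + lam J)^-1 = I - lam/(1 + lam n_g) J, so every quadratic form the
    REML criterion needs reduces to group sums computed once up front.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        # canonical content-based row order: summation order (and hence the
        # floating-point result) is invariant to fish relabeling and row
        # shuffling, which the estimates are required to be
        M = np.column_stack([y, X])
        global_rank = np.empty(len(y), dtype=int)
        global_rank[np.lexsort(M.T[::-1])] = np.arange(len(y))
        _, codes = np.unique(groups, return_inverse=True)
        group_rank = np.full(codes.max() + 1, len(y), dtype=int)
        np.minimum.at(group_rank, codes, global_rank)
        order = np.lexsort((global_rank, group_rank[codes]))
        y, X, groups = y[order], X[order], groups[order]
        change = np.empty(len(groups), dtype=bool)
        change[0] = True
        change[1:] = groups[1:] != groups[:-1]
        starts = np.flatnonzero(change)
        counts = np.diff(np.append(starts, len(groups)))
        self.n, self.p = X.shape
        self.n_groups = len(counts)
        self.counts = counts.astype(float)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.sx = np.add.reduceat(X, starts, axis=0)        # (G, p)
        self.sy = np.add.reduceat(y, starts)                # (G,)

    def criterion(self, lam: float) -> tuple[float, np.ndarray, float]:
        """(criterion, beta_gls, sigma2_W_hat) at variance ratio lam.

        The criterion is (n-p) log q + log|V0| + log|X' V0^-1 X| with q
        the GLS residual quadratic form (additive constants dropped).
        """
        c = lam / (1.0 + lam * self.counts)                 # (G,)
        XtViX = self.XtX - (self.sx * c[:, None]).T @ self.sx
        XtViy = self.Xty - self.sx.T @ (c * self.sy)
        ytViy = self.yty - float(c @ self.sy**2)
        logdet_v0 = float(np.log1p(lam * self.counts).sum())
        beta = np.linalg.solve(XtViX, XtViy)
        q = max(float(ytViy - beta @ XtViy), 1e-300)
        sign, logdet_xvx = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise np.linalg.LinAlgError("singular fixed-effect design")
        crit = (self.n - self.p) * np.log(q) + logdet_v0 + logdet_xvx
        return crit, beta, q / (self.n - self.p)

    def gradient(self, lam: float) -> float:
        """Analytic d(criterion)/d(lambda), for root-polishing the optimum.

        Function-value search alone cannot localise lambda beyond the
        flatness floor of the criterion; the stationarity condition can.
        """
        denom = 1.0 + lam * self.counts
        c = lam / denom
        dc = 1.0 / denom**2
        XtViX = self.XtX - (self.sx * c[:, None]).T @ self.sx
        XtViy = self.Xty - self.sx.T @ (c * self.sy)
        beta = np.linalg.solve(XtViX, XtViy)
        sr = self.sy - self.sx @ beta              # group residual sums
        ytViy = self.yty - float(c @ self.sy**2)
        q = max(float(ytViy - beta @ XtViy), 1e-300)
        dq = -float(dc @ sr**2)
        d_logdet_v0 = float((self.counts / denom).sum())
        sol = np.linalg.solve(XtViX, self.sx.T)    # (p, G)
        d_logdet_xvx = -float(dc @ np.einsum("gp,pg->g", self.sx, sol))
        return (self.n - self.p) * dq / q + d_logdet_v0 + d_logdet_xvx


def reml_profile(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    lambda_bounds: tuple[float, float] = (1e-8, 1e8),
    xtol: float = 1e-10,
) -> tuple[float, float, float, np.ndarray, float]:
    """Minimise the profiled REML criterion over lambda >= 0.

    Coarse log-spaced scan (multistart) followed by bounded scalar search
    on log(lambda) in the best bracket, compared against the lambda = 0
    boundary.  Returns (lambda_hat, sigma2_W, sigma2_B, beta, criterion).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("need >= 2 fish (grouping levels)")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("singular fixed-effect design")
    stats = _GroupStats(y, X, groups)

    def crit_log(loglam: float) -> float:
        return stats.criterion(np.exp(loglam))[0]

    lo, hi = np.log(lambda_bounds[0]), np.log(lambda_bounds[1])
    grid = np.linspace(lo, hi, 65)
    vals = np.array([crit_log(g) for g in grid])
    j = int(vals.argmin())
    bl = grid[max(j - 1, 0)]
    bh = grid[min(j + 1, len(grid) - 1)]
    res = minimize_scalar(crit_log, bounds=(bl, bh), method="bounded",
                          options={"xatol": xtol})
    lam_int = float(np.exp(res.x))
    # polish with the analytic stationarity condition: the criterion is too
    # flat near the optimum for value-based search alone
    g_lo, g_hi = stats.gradient(np.exp(bl)), stats.gradient(np.exp(bh))
    if g_lo < 0 < g_hi:
        lam_int = float(brentq(stats.gradient, np.exp(bl), np.exp(bh),
                               xtol=1e-14 * max(lam_int, 1e-10), rtol=1e-15))
    crit_int = float(stats.criterion(lam_int)[0])
    crit0, beta0, s2w0 = stats.criterion(0.0)
    if crit0 <= crit_int:
        return 0.0, s2w0, 0.0, beta0, float(crit0)
    _, beta, s2w = stats.criterion(lam_int)
    return lam_int, s2w, lam_int * s2w, beta, crit_int


def fit_random_intercept_reml(
    data: pd.DataFrame,
    value_col: str,
    group_col: str = "fish_id",
    numeric_effects: tuple[str, ...] = ("fork_length_mm",),
    categorical_effects: tuple[str, ...] = ("tissue",),
    isotope: str = "",
    group_label: str = "population",
) -> VarianceDecomposition:
    """REML variance decomposition of one isotope for one morphotype group.

    Fixed effects: an intercept, the listed numeric covariates, and
    treatment contrasts for the listed categorical covariates (reference =
    first sorted level, so tissue defaults to RBC-referenced).  The random
    effect is a per-fish intercept.
    """
    df = data.dropna(subset=[value_col]).copy()
    if df[group_col].nunique() < 2:
        raise ValueError("need >= 2 fish")
    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["intercept"]
    for c in numeric_effects:
        cols.append(df[c].to_numpy(dtype=float))
        names.append(c)
    for c in categorical_effects:
        levels = sorted(df[c].unique())
        for lev in levels[1:]:
            cols.append((df[c] == lev).to_numpy(dtype=float))
            names.append(f"{c}[{lev}]")
    X = np.column_stack(cols)
    y = df[value_col].to_numpy(dtype=float)
    lam, s2w, s2b, beta, crit = reml_profile(y, X, df[group_col].to_numpy())
    return VarianceDecomposition(
        isotope=isotope,
        group=group_label,
        wic=float(s2w),
        bic=float(s2b),
        n_fish=int(df[group_col].nunique()),
        n_obs=len(df),
        fixed_effects=dict(zip(names, map(float, beta))),
        boundary=lam == 0.0,
        lambda_hat=float(lam),
        reml_criterion=float(crit),
    )


def decomposition_table(
    records: pd.DataFrame,
    clusters: pd.Series | None = None,
    value_suffix: str = "_corr",
) -> pd.DataFrame:
    """WIC/BIC/TNW/IS per isotope for each morphotype cluster and the
    pooled population.

    ``records`` is the long isotope table (fish_id, tissue, values,
    fork_length_mm); ``clusters`` maps fish_id -> morphotype label.
    """
    rows = []
    groupings: list[tuple[str, pd.DataFrame]] = [("population", records)]
    if clusters is not None:
        for lab in sorted(clusters.unique()):
            fish = clusters.index[clusters == lab]
            groupings.append(
                (f"cluster{lab}", records[records["fish_id"].isin(fish)])
            )
    for iso in ("d13C", "d15N"):
        col = f"{iso}{value_suffix}"
        for name, sub in groupings:
            dec = fit_random_intercept_reml(
                sub, col, isotope=iso, group_label=name
            )
            rows.append(
                {
                    "isotope": iso,
                    "group": name,
                    "WIC": dec.wic,
                    "BIC": dec.bic,
                    "TNW": dec.tnw,
                    "IS": dec.is_index,
                    "n_fish": dec.n_fish,
                    "n_obs": dec.n_obs,
                    "boundary": dec.boundary,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------- individual WIC + GLM

def individual_wic(
    paired: pd.DataFrame,
    isotope: str,
    value_suffix: str = "_corr",
    direction: str = "plasma_on_rbc",
) -> pd.DataFrame:
    """Per-fish WIC values from the between-tissue regression.

    Fits an OLS line between the two tissues pooled across fish
    (default: plasma predicted from RBC, the fast tissue from the slow)
    and takes each fish's absolute residual as its individual WIC (‰).
    ``paired`` is wide: one row per fish with ``<iso><suffix>_RBC`` and
    ``<iso><suffix>_plasma`` columns (see :func:`paired_wide`).
    """
    xcol, ycol = f"{isotope}{value_suffix}_RBC", f"{isotope}{value_suffix}_plasma"
    if direction == "rbc_on_plasma":
        xcol, ycol = ycol, xcol
    elif direction != "plasma_on_rbc":
        raise ValueError(f"unknown regression direction {direction!r}")
    df = paired.dropna(subset=[xcol, ycol])
    if len(df) < 3:
        raise ValueError("need >= 3 paired fish")
    x = df[xcol].to_numpy(dtype=float)
    y = df[ycol].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor tissue")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    out = pd.DataFrame(
        {
            "fish_id": df["fish_id"].to_numpy(),
            "isotope": isotope,
            "wic_value": np.abs(resid),
        }
    )
    for c in ("cluster", "fork_length_mm", "year"):
        if c in df.columns:
            out[c] = df[c].to_numpy()
    out.attrs["slope"] = float(slope)
    out.attrs["intercept"] = float(intercept)
    out.attrs["direction"] = direction
    return out


def paired_wide(records: pd.DataFrame, value_suffix: str = "_corr") -> pd.DataFrame:
    """Wide per-fish table of both tissues; fish missing one tissue dropped."""
    cols = [f"d13C{value_suffix}", f"d15N{value_suffix}"]
    wide = records.pivot_table(
        index="fish_id", columns="tissue", values=cols, aggfunc="first"
    )
    wide = wide.loc[wide.notna().all(axis=1)]
    wide.columns = [f"{c}_{t}" for c, t in wide.columns]
    meta_cols = [c for c in ("cluster", "year", "fork_length_mm") if c in records.columns]
    if meta_cols:
        meta = records.drop_duplicates("fish_id").set_index("fish_id")[meta_cols]
        wide = wide.join(meta)
    return wide.reset_index()


def log10_wic(values: np.ndarray) -> tuple[np.ndarray, int]:
    """log10 transform with a floor for exact zeros.

    Zeros are floored at half the smallest positive value (count returned
    and logged) so the transform is defined everywhere.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("WIC values must be non-negative")
    positive = v[v > 0]
    if len(positive) == 0:
        raise ValueError("all WIC values are zero")
    n_floored = int((v == 0).sum())
    if n_floored:
        logger.info("log10_wic: %d zero value(s) floored", n_floored)
        v = np.where(v == 0, positive.min() / 2.0, v)
    return np.log10(v), n_floored


def wic_glm(
    wic_table: pd.DataFrame,
    interactions: tuple[str, ...] = (),
) -> tuple[object, pd.DataFrame]:
    """Gaussian GLM of log10 individual WIC on cluster, fork length, year.

    Year and cluster are categorical; estimates and standard errors are
    also reported back-transformed (10^value) the way such tables are
    conventionally printed.  Returns (statsmodels results, coefficient
    table).
    """
    if len(wic_table) < 10:
        raise ValueError("need >= 10 observations")
    df = wic_table.copy()
    df["log10_wic"], _ = log10_wic(df["wic_value"].to_numpy())
    terms = ["C(cluster)", "fork_length_mm", "C(year)"] + list(interactions)
    formula = "log10_wic ~ " + " + ".join(terms)
    res = smf.ols(formula, data=df).fit()
    if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
        aliased = [n for n, ok in zip(res.model.exog_names,
                                      np.ptp(res.model.exog, axis=0) > 0) if not ok]
        raise np.linalg.LinAlgError(f"rank-deficient design (aliased: {aliased})")
    table = pd.DataFrame(
        {
            "term": res.params.index,
            "estimate_log10": res.params.values,
            "se_log10": res.bse.values,
            "estimate_backtransformed": 10.0 ** res.params.values,
            "se_backtransformed": 10.0 ** res.bse.values,
            "t": res.tvalues.values,
            "p": res.pvalues.values,
        }
    )
    return res, table


def simplify_by_aic(
    wic_table: pd.DataFrame,
    interactions: tuple[str, ...],
    alpha: float = 0.05,
    delta_aic: float = 2.0,
) -> tuple[object, pd.DataFrame, list[dict]]:
    """Sequential interaction-term dropping guarded by AIC.

    Iteratively removes the non-significant (p >= alpha) interaction term
    with the smallest |t|; if removal raises AIC by more than ``delta_aic``
    the term is restored and no longer considered.  Main effects are never
    dropped.  AIC is the Gaussian-likelihood AIC, equivalent to
    n ln(RSS/n) + 2k up to an additive constant.  Returns the final fitted
    model, its coefficient table, and the decision log.
    """
    current = list(interactions)
    log: list[dict] = []
    res, table = wic_glm(wic_table, tuple(current))
    protected: set[str] = set()
    while True:
        candidates = []
        for term in current:
            if term in protected:
                continue
            cols = [i for i, n in enumerate(res.params.index) if _matches_term(n, term)]
            if not cols:
                continue
            tmin = float(np.min(np.abs(res.tvalues.iloc[cols])))
            pterm = float(np.max(res.pvalues.iloc[cols]))
            if pterm >= alpha:
                candidates.append((tmin, term))
        if not candidates:
            break
        _, drop = min(candidates)
        reduced = [t for t in current if t != drop]
        res_red, table_red = wic_glm(wic_table, tuple(reduced))
        d_aic = res_red.aic - res.aic
        if d_aic > delta_aic:
            protected.add(drop)
            log.append({"term": drop, "action": "retained",
                        "delta_aic": float(d_aic)})
        else:
            current = reduced
            res, table = res_red, table_red
            log.append({"term": drop, "action": "dropped",
                        "delta_aic": float(d_aic)})
    return res, table, log


def _matches_term(coef_name: str, term: str) -> bool:
    """Match a patsy coefficient name to a formula term, ignoring level tags."""
    def strip(s: str) -> list[str]:
        return sorted(p.split("[")[0] for p in s.split(":"))
    return strip(coef_name) == strip(term)
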