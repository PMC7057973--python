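"""NBSS fitting, diagnostics and cross-site comparison.

The normalized biomass size spectrum (NBSS) is the ordinary least-squares
regression of log2 normalized biomass on the integer size-class index.
For a community in energetic steady state the slope is expected near -1;
shallower slopes indicate subsidised systems, steeper ones a deficit of
large organisms.  Sites are compared with an ANCOVA: size class as the
continuous covariate, site as a factor.  If the class-by-site interaction
(slope heterogeneity) is not significant, a common-slope model yields
per-site intercepts which are compared pairwise with Tukey
studentized-range adjusted p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .spectra import NormalizedSpectrum, SizeSpectrum, class_width, normalize

__all__ = [
    "NBSSFit",
    "FitDiagnostics",
    "SlopeComparison",
    "CorrelationResult",
    "fit_nbss",
    "diagnose_fit",
    "compare_slopes",
    "pairwise_intercepts",
    "intercept_biomass_correlation",
]

LOG_BASE = 2  # NB is logged base 2 so the y-axis matches the class axis


def _as_points(points) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(points, NormalizedSpectrum):
        return points.points()
    ns, nb = points
    return np.asarray(ns, dtype=float), np.asarray(nb, dtype=float)


@dataclass
class NBSSFit:
    """OLS fit of log2(NB) on size class index; intercept at class 0 (1 ug)."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r2: float
    n_points: int
    class_indices: np.ndarray
    residuals: np.ndarray
    cooks_d: np.ndarray
    log_base: int = LOG_BASE

    def confint_slope(self, alpha: float = 0.05) -> tuple[float, float]:
        t = stats.t.ppf(1 - alpha / 2, self.n_points - 2)
        return self.slope - t * self.slope_se, self.slope + t * self.slope_se

    def predict(self, n: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(n, dtype=float)


def fit_nbss(points: NormalizedSpectrum | tuple) -> NBSSFit:
    """Fit the NBSS line to (class index, NB) points.

    ``points`` is a :class:`NormalizedSpectrum` or an ``(indices, nb)``
    pair.  Requires at least three strictly positive NB values (log of a
    zero or negative NB is undefined).
    """
    ns, nb = _as_points(points)
    if ns.size < 3:
        raise ValueError(f"NBSS regression needs >= 3 points, got {ns.size}")
    if np.any(~(nb > 0)):
        raise ValueError("all NB values must be positive for log2 transformation")
    y = np.log2(nb)
    X = sm.add_constant(ns)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sm.OLS(y, X).fit()
        infl = res.get_influence()
        cooks = np.nan_to_num(np.asarray(infl.cooks_distance[0]))
        r2 = float(res.rsquared)
    if not np.isfinite(r2):  # constant y: the line fits perfectly
        r2 = 1.0 if res.ssr < 1e-12 else 0.0
    return NBSSFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        intercept_se=float(res.bse[0]),
        r2=r2,
        n_points=int(ns.size),
        class_indices=ns,
        residuals=np.asarray(res.resid),
        cooks_d=cooks,
    )


@dataclass
class FitDiagnostics:
    threshold: float
    influential: list[tuple[int, float]]  # (class index, Cook's D)
    extreme_class_flagged: bool  # an influential point sits at the spectrum edge
    shapiro_p: float | None


def diagnose_fit(fit: NBSSFit, threshold: float | None = None) -> FitDiagnostics:
    """Influence diagnostics for an NBSS fit.

    Points with Cook's distance above ``threshold`` (default 4/n) are
    listed; the lowest and highest size classes get special attention
    since undersampling at the spectrum edges is the usual source of
    influential points.
    """
    if threshold is None:
        threshold = 4.0 / fit.n_points
    flagged = [
        (int(fit.class_indices[i]), float(d))
        for i, d in enumerate(fit.cooks_d)
        if d > threshold
    ]
    edges = {int(fit.class_indices.min()), int(fit.class_indices.max())}
    extreme = any(n in edges for n, _ in flagged)
    shapiro_p = None
    if fit.n_points >= 3 and np.ptp(fit.residuals) > 0:
        shapiro_p = float(stats.shapiro(fit.residuals).pvalue)
    return FitDiagnostics(
        threshold=threshold,
        influential=flagged,
        extreme_class_flagged=extreme,
        shapiro_p=shapiro_p,
    )


@dataclass
class SlopeComparison:
    """ANCOVA of log2(NB) ~ class * site, plus the common-slope refit."""

    groups: list[str]
    interaction_F: float
    df_num: int
    df_den: int
    p_interaction: float
    common_slope: float
    common_slope_se: float
    intercepts: dict[str, tuple[float, float]]  # group -> (estimate, SE)
    n_points: int
    df_resid_common: int
    _cov_intercepts: np.ndarray | None = None


def _stack_groups(
    groups: Mapping[str, Sequence[NormalizedSpectrum] | NormalizedSpectrum | tuple]
) -> pd.DataFrame:
    rows = []
    for name, specs in groups.items():
        if isinstance(specs, (NormalizedSpectrum, tuple)):
            specs = [specs]
        for spec in specs:
            ns, nb = _as_points(spec)
            if np.any(~(nb > 0)):
                raise ValueError(f"group {name!r} has non-positive NB values")
            for x, v in zip(ns, nb):
                rows.append({"group": name, "x": float(x), "y": float(np.log2(v))})
    return pd.DataFrame(rows)


def compare_slopes(
    groups: Mapping[str, Sequence[NormalizedSpectrum] | NormalizedSpectrum | tuple]
) -> SlopeComparison:
    """Test slope homogeneity across sites and estimate common-slope intercepts.

    ``groups`` maps a site label to one or more sets of NBSS points (e.g.
    the three replicate stations of a fjord).  The interaction F compares
    the separate-slopes model against the common-slope model; the
    common-slope ("fixed slope") refit provides the pooled slope with its
    SE and one adjusted intercept per site.  With a single group this
    reduces exactly to :func:`fit_nbss`.
    """
    df = _stack_groups(groups)
    names = sorted(df["group"].unique())
    k = len(names)
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    n = len(df)
    dummies = np.column_stack([(df["group"] == g).to_numpy(float) for g in names])

    # common-slope model: y = slope * x + intercept_g  (one-hot, no constant)
    X_common = np.column_stack([x, dummies])
    res_common = sm.OLS(y, X_common).fit()

    if k == 1:
        fit = fit_nbss((x, y_to_nb(y)))
        return SlopeComparison(
            groups=names,
            interaction_F=float("nan"),
            df_num=0,
            df_den=n - 2,
            p_interaction=float("nan"),
            common_slope=fit.slope,
            common_slope_se=fit.slope_se,
            intercepts={names[0]: (fit.intercept, fit.intercept_se)},
            n_points=n,
            df_resid_common=n - 2,
        )

    # separate-slopes model: per-group slope and intercept
    X_full = np.column_stack([dummies * x[:, None], dummies])
    res_full = sm.OLS(y, X_full).fit()

    df_num = k - 1
    df_den = n - 2 * k
    if df_den <= 0:
        raise ValueError("not enough points to test slope heterogeneity")
    sse_f = float(res_full.ssr)
    sse_r = float(res_common.ssr)
    F = ((sse_r - sse_f) / df_num) / (sse_f / df_den)
    p = float(stats.f.sf(F, df_num, df_den))

    intercepts = {
        g: (float(res_common.params[1 + j]), float(res_common.bse[1 + j]))
        for j, g in enumerate(names)
    }
    cov = np.asarray(res_common.cov_params())[1:, 1:]
    return SlopeComparison(
        groups=names,
        interaction_F=float(F),
        df_num=df_num,
        df_den=df_den,
        p_interaction=p,
        common_slope=float(res_common.params[0]),
        common_slope_se=float(res_common.bse[0]),
        intercepts=intercepts,
        n_points=n,
        df_resid_common=int(res_common.df_resid),
        _cov_intercepts=cov,
    )


def y_to_nb(y: np.ndarray) -> np.ndarray:
    """Inverse of the log2 transform (helper for the one-group reduction)."""
    return np.power(2.0, y)


def pairwise_intercepts(comparison: SlopeComparison) -> pd.DataFrame:
    """All-pairs comparison of common-slope intercepts, Tukey-adjusted.

    The familywise adjustment uses the studentized-range distribution with
    k groups and the common-slope model's residual df; with two groups the
    adjusted p equals the ordinary two-sided t-test p.
    """
    if comparison._cov_intercepts is None:
        raise ValueError("pairwise comparison requires a fitted multi-group model")
    names = comparison.groups
    k = len(names)
    dfres = comparison.df_resid_common
    cov = comparison._cov_intercepts
    est = np.array([comparison.intercepts[g][0] for g in names])
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = est[i] - est[j]
            se = float(np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j]))
            t = diff / se
            p_adj = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, dfres))
            rows.append(
                {
                    "group_i": names[i],
                    "group_j": names[j],
                    "difference": float(diff),
                    "se": se,
                    "t": float(t),
                    "p_adj": min(1.0, p_adj),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CorrelationResult:
    rho_total_dm: float
    p_total_dm: float
    rho_mean_nb: float
    p_mean_nb: float
    n_stations: int
    class_range: tuple[int, int] | None


def intercept_biomass_correlation(
    station_spectra: Sequence[SizeSpectrum],
    class_range: tuple[int, int] | None = None,
) -> CorrelationResult:
    """Spearman correlation of station NBSS intercepts with standing stock.

    Intercepts are refitted per station with free slopes.  When
    ``class_range`` is given, each station's spectrum is truncated to the
    common range before BOTH the intercept refit and the total/mean-NB
    recomputation — the intercept is only comparable across stations when
    the class support is.
    """
    if len(station_spectra) < 5:
        raise ValueError("need at least 5 stations for a rank correlation")
    intercepts, totals, mean_nb = [], [], []
    for spec in station_spectra:
        if class_range is not None:
            spec = spec.truncate(*class_range)
        norm = normalize(spec)
        fit = fit_nbss(norm)
        intercepts.append(fit.intercept)
        totals.append(spec.total_biomass_ug)
        mean_nb.append(float(np.mean(list(norm.classes.values()))))
    for name, v in (("intercepts", intercepts), ("totals", totals)):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} are constant; rank correlation undefined")
    rho_t, p_t = stats.spearmanr(intercepts, totals)
    rho_m, p_m = stats.spearmanr(intercepts, mean_nb)
    return CorrelationResult(
        rho_total_dm=float(rho_t),
        p_total_dm=float(p_t),
        rho_mean_nb=float(rho_m),
        p_mean_nb=float(p_m),
        n_stations=len(station_spectra),
        class_range=class_range,
    )
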