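"""Distance-based multivariate statistics for cross-site comparison.

Implements the resemblance-matrix toolkit used alongside the size
spectra: Euclidean and Bray-Curtis resemblance matrices, one-way
PERMANOVA (McArdle-Anderson partitioning of squared distances), a
Mantel-type matrix rank correlation (RELATE), distance-based linear
models (DistLM) with marginal tests and forward selection on adjusted
R^2, and a gamma/log-link GLM of individual body mass on temperature.

All permutation procedures take an explicit seed and are exactly
reproducible; when the permutation space is small enough the full
enumeration replaces random sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ResemblanceMatrix",
    "PermutationResult",
    "DistLMResult",
    "GLMResult",
    "euclidean_distance",
    "bray_curtis",
    "permanova_oneway",
    "relate_mantel",
    "distlm",
    "taxon_temp_glm",
]

#: Permutation spaces at or below this size are enumerated exhaustively.
EXHAUSTIVE_LIMIT = 100_000


@dataclass
class ResemblanceMatrix:
    """Symmetric station-by-station resemblance matrix.

    Distances are stored as given; Bray-Curtis is stored as dissimilarity
    in [0, 1] with :meth:`similarity_percent` giving the source-convention
    0-100 similarity scale.
    """

    labels: list[str]
    values: np.ndarray
    kind: str  # "euclidean_distance" | "bray_curtis"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("resemblance matrix must be square")
        if v.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix size")
        if not np.allclose(v, v.T):
            raise ValueError("resemblance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def similarity_percent(self) -> np.ndarray:
        if self.kind != "bray_curtis":
            raise ValueError("similarity scale only defined for Bray-Curtis")
        return 100.0 * (1.0 - self.values)

    def reorder(self, labels: Sequence[str]) -> "ResemblanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return ResemblanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)


def euclidean_distance(table: pd.DataFrame) -> ResemblanceMatrix:
    """Euclidean distances among rows (stations) of a variable table."""
    if len(table) < 2:
        raise ValueError("need at least 2 rows")
    d = squareform(pdist(table.to_numpy(float), metric="euclidean"))
    return ResemblanceMatrix([str(i) for i in table.index], d, "euclidean_distance")


def bray_curtis(table: pd.DataFrame, transform: str | None = "sqrt") -> ResemblanceMatrix:
    """Bray-Curtis dissimilarities among rows after an optional transform.

    ``D_ij = sum|x_i - x_j| / sum(x_i + x_j)`` on square-root transformed
    values by default (the standard variance-stabilising choice for
    biomass tables).  Rows must be non-negative and non-empty.
    """
    x = table.to_numpy(float)
    if len(table) < 2:
        raise ValueError("need at least 2 rows")
    if np.any(x < 0):
        raise ValueError("Bray-Curtis requires a non-negative table")
    zero_rows = np.where(x.sum(axis=1) == 0)[0]
    if zero_rows.size:
        raise ValueError(
            f"all-zero row(s) {list(table.index[zero_rows])}: similarity undefined"
        )
    if transform == "sqrt":
        x = np.sqrt(x)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    d = squareform(pdist(x, metric="braycurtis"))
    return ResemblanceMatrix([str(i) for i in table.index], d, "bray_curtis")


@dataclass
class PermutationResult:
    statistic: float
    p_perm: float
    n_permutations: int
    seed: int | None
    exhaustive: bool = False
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _multiset_permutations(items: list):
    """All distinct orderings of a label multiset (recursive)."""
    if not items:
        yield []
        return
    seen = set()
    for i, it in enumerate(items):
        if it in seen:
            continue
        seen.add(it)
        rest = items[:i] + items[i + 1 :]
        for tail in _multiset_permutations(rest):
            yield [it] + tail


def _n_distinct_arrangements(groups: Sequence) -> int:
    from math import factorial

    counts = pd.Series(list(groups)).value_counts()
    total = factorial(len(groups))
    for c in counts:
        total //= factorial(int(c))
    return total


def _permanova_f(d2: np.ndarray, codes: np.ndarray, k: int) -> float:
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(k):
        idx = np.where(codes == g)[0]
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    ss_among = ss_total - ss_within
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def permanova_oneway(
    dist: ResemblanceMatrix,
    groups: Sequence[str],
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermutationResult:
    """One-way PERMANOVA on a distance matrix.

    The pseudo-F partitions the total sum of squared distances into
    among- and within-group components (SS_total = sum d^2 / N,
    SS_within summed per group).  The p-value comes from random label
    permutations, or from the complete enumeration of distinct label
    arrangements when there are at most ``EXHAUSTIVE_LIMIT`` of them.
    """
    groups = list(groups)
    if len(groups) != dist.n:
        raise ValueError("one group label per station required")
    names = sorted(set(groups))
    k = len(names)
    if k < 2:
        raise ValueError("need at least 2 groups")
    counts = pd.Series(groups).value_counts()
    if counts.min() < 2:
        raise ValueError(f"every group needs >= 2 members, got {counts.to_dict()}")

    codes = np.array([names.index(g) for g in groups])
    d2 = dist.values**2
    f_obs = _permanova_f(d2, codes, k)

    n_distinct = _n_distinct_arrangements(groups)
    if n_distinct <= min(EXHAUSTIVE_LIMIT, n_perm + 1):
        f_all = np.array(
            [
                _permanova_f(d2, np.array(perm), k)
                for perm in _multiset_permutations(list(codes))
            ]
        )
        p = float(np.mean(f_all >= f_obs - 1e-12))
        return PermutationResult(float(f_obs), p, len(f_all), seed, exhaustive=True)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _permanova_f(d2, perm, k) >= f_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermutationResult(float(f_obs), float(p), n_perm, seed)


# ---------------------------------------------------------------------------
# RELATE (Mantel-type rank correlation)
# ---------------------------------------------------------------------------

def relate_mantel(
    m1: ResemblanceMatrix,
    m2: ResemblanceMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermutationResult:
    """Spearman rank correlation between two resemblance matrices.

    rho is computed over the off-diagonal (condensed) elements; the null
    distribution permutes the station labels of the second matrix.  Both
    matrices must be indexed by the same stations in the same order.
    """
    if m1.labels != m2.labels:
        raise ValueError("matrices must share identical, identically ordered labels")
    n = m1.n
    r1 = stats.rankdata(m1.condensed())
    r1 = r1 - r1.mean()

    # ranks of m2's entries arranged back into square form: permuting
    # station labels permutes the condensed entries, so their ranks travel
    # with them and only need computing once.
    rank2_sq = squareform(stats.rankdata(m2.condensed()))

    def rho_for(order: np.ndarray) -> float:
        r2 = squareform(rank2_sq[np.ix_(order, order)], checks=False)
        r2 = r2 - r2.mean()
        return float(r1 @ r2 / np.sqrt((r1 @ r1) * (r2 @ r2)))

    identity = np.arange(n)
    rho_obs = rho_for(identity)

    from math import factorial

    if factorial(n) <= min(EXHAUSTIVE_LIMIT, n_perm + 1):
        from itertools import permutations

        rhos = np.array([rho_for(np.array(p)) for p in permutations(range(n))])
        p = float(np.mean(rhos >= rho_obs - 1e-12))
        return PermutationResult(rho_obs, p, len(rhos), seed, exhaustive=True)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if rho_for(rng.permutation(n)) >= rho_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermutationResult(rho_obs, float(p), n_perm, seed)


# ---------------------------------------------------------------------------
# DistLM
# ---------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return q @ q.T


def _pseudo_f_trace(g: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """(pseudo-F, R^2) for Gower-centered G regressed on centered predictors x."""
    n = g.shape[0]
    m = x.shape[1]
    h = _hat(x)
    ss_total = np.trace(g)
    ss_expl = np.trace(h @ g @ h)
    ss_res = ss_total - ss_expl
    if ss_res <= 1e-12 * abs(ss_total):  # predictors explain everything
        return float("inf"), float(ss_expl / ss_total)
    f = (ss_expl / m) / (ss_res / (n - m - 1))
    return float(f), float(ss_expl / ss_total)


@dataclass
class DistLMResult:
    marginal: pd.DataFrame  # predictor, pseudo_F, p, pct_var
    selected: list[str]
    sequential: pd.DataFrame  # step, predictor, adj_r2, cum_pct_var
    r2_selected: float
    adj_r2_selected: float
    n_permutations: int
    seed: int | None


def distlm(
    dist: ResemblanceMatrix,
    predictors: pd.DataFrame,
    mode: str = "forward_adjR2",
    n_perm: int = 9999,
    seed: int | None = None,
    standardize: bool = True,
) -> DistLMResult:
    """Distance-based linear model with marginal tests and forward selection.

    Each predictor is tested marginally (pseudo-F with p by permutation of
    the Gower-centered matrix rows/columns, i.e. of the raw observations);
    ``forward_adjR2`` then adds predictors greedily while the adjusted R^2
    of the selected set improves.  Predictors are z-scored by default; an
    exactly collinear later predictor is dropped with a warning.
    """
    if mode not in ("marginal", "forward_adjR2"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(predictors) != dist.n:
        raise ValueError("one predictor row per station required")
    x_df = predictors.astype(float).copy()
    n = dist.n

    # drop exactly collinear later columns
    cols = list(x_df.columns)
    keep: list[str] = []
    for c in cols:
        drop = False
        for kcol in keep:
            r = np.corrcoef(x_df[c], x_df[kcol])[0, 1]
            if np.isclose(abs(r), 1.0):
                warnings.warn(
                    f"predictor {c!r} is collinear with {kcol!r} (|r| = 1); dropped",
                    stacklevel=2,
                )
                drop = True
                break
        if not drop:
            keep.append(c)
    x_df = x_df[keep]

    x = x_df.to_numpy()
    x = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [keep[i] for i in np.where(sd == 0)[0]]
            raise ValueError(f"constant predictor(s): {bad}")
        x = x / sd

    g = _gower_center(dist.values)
    rng = np.random.default_rng(seed)

    def perm_p(xcol: np.ndarray) -> tuple[float, float, float]:
        f_obs, r2 = _pseudo_f_trace(g, xcol)
        count = 0
        for _ in range(n_perm):
            order = rng.permutation(n)
            gp = g[np.ix_(order, order)]
            if _pseudo_f_trace(gp, xcol)[0] >= f_obs - 1e-12:
                count += 1
        return f_obs, (count + 1) / (n_perm + 1), r2

    rows = []
    for j, name in enumerate(x_df.columns):
        f_obs, p, r2 = perm_p(x[:, [j]])
        rows.append(
            {"predictor": name, "pseudo_F": f_obs, "p": p, "pct_var": 100.0 * r2}
        )
    marginal = pd.DataFrame(rows)

    selected: list[str] = []
    seq_rows = []
    r2_sel = 0.0
    adj_sel = 0.0
    if mode == "forward_adjR2":
        remaining = list(x_df.columns)
        current_adj = -np.inf
        while remaining:
            best = None
            for name in remaining:
                trial = selected + [name]
                idx = [list(x_df.columns).index(t) for t in trial]
                m = len(trial)
                if n - m - 1 <= 0:
                    continue
                _, r2 = _pseudo_f_trace(g, x[:, idx])
                adj = 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)
                if best is None or adj > best[1]:
                    best = (name, adj, r2)
            if best is None or best[1] <= current_adj:
                break
            name, adj, r2 = best
            selected.append(name)
            remaining.remove(name)
            current_adj = adj
            r2_sel, adj_sel = r2, adj
            seq_rows.append(
                {
                    "step": len(selected),
                    "predictor": name,
                    "adj_r2": adj,
                    "cum_pct_var": 100.0 * r2,
                }
            )
    sequential = pd.DataFrame(seq_rows)
    return DistLMResult(
        marginal=marginal,
        selected=selected,
        sequential=sequential,
        r2_selected=r2_sel,
        adj_r2_selected=adj_sel,
        n_permutations=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# gamma GLM of body mass on temperature
# ---------------------------------------------------------------------------

@dataclass
class GLMResult:
    coefficient: float
    se: float
    p: float
    direction: str  # "positive" | "negative" | "none" | "nonestimable"
    n: int


def taxon_temp_glm(
    dm_ug: Sequence[float],
    temperature_C: Sequence[float],
    alpha: float = 0.05,
) -> GLMResult:
    """Gamma GLM (log link) of individual dry mass on temperature.

    Returns the temperature coefficient on the log scale with its SE and
    Wald p, plus the direction called at ``alpha``.  Requires positive
    masses, at least 10 individuals and at least 2 temperature levels.
    """
    dm = np.asarray(dm_ug, dtype=float)
    temp = np.asarray(temperature_C, dtype=float)
    if np.any(~(dm > 0)):
        raise ValueError("gamma GLM requires strictly positive dry masses")
    if dm.size < 10:
        raise ValueError(f"need >= 10 individuals, got {dm.size}")
    if np.unique(temp).size < 2:
        raise ValueError("need >= 2 distinct temperature levels")
    exog = sm.add_constant(temp)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(dm, exog, family=sm.families.Gamma(sm.families.links.Log())).fit()
        coef = float(res.params[1])
        se = float(res.bse[1])
        p = float(res.pvalues[1])
        if not np.isfinite(coef) or not np.isfinite(se):
            raise ValueError("non-finite estimate")
    except Exception:
        return GLMResult(float("nan"), float("nan"), float("nan"), "nonestimable", dm.size)
    if p < alpha:
        direction = "positive" if coef > 0 else "negative"
    else:
        direction = "none"
    return GLMResult(coef, se, p, direction, dm.size)
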