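"""Per-SNP association scores and top-SNP list assembly on the training split.

Three scorers are computed per SNP against the ordinal grade target, which is
treated as continuous:

* a univariate regression F test (Pearson r converted to an F statistic with
  (1, n-2) degrees of freedom and a p-value),
* a k-nearest-neighbor mutual-information estimate (nats), using the mixed
  discrete/continuous estimator for genotype-like features and the
  Kraskov-Grassberger estimator for continuous pairs,
* Lasso coefficients over a fixed penalty grid
  (0.7, 0.5, 0.2, 0.1, 0.05, 0.01, 0.005, 0.001, 0.0005),
  fitted by warm-started cyclic coordinate descent on the raw 0/1/2 genotype
  scale.  Features are deliberately NOT standardized: the downstream scoring
  rules threshold absolute coefficients (0.1 / 0.05), which are meaningful
  only on the raw allele-count scale.

Top lists are the union of the top-k SNPs by F (after a p < 0.01 gate), the
top-k by MI, and the non-zero Lasso sets at configured alphas, with
provenance flags per SNP.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import digamma
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import f_regression
from sklearn.linear_model import Lasso, LinearRegression

logger = logging.getLogger(__name__)

#: Lasso penalty grid, largest (sparsest) first.
ALPHA_GRID = (0.7, 0.5, 0.2, 0.1, 0.05, 0.01, 0.005, 0.001, 0.0005)
#: Alphas whose non-zero coefficient sets enter the top-SNP lists.
TOP_LIST_ALPHAS = (0.5, 0.2, 0.1, 0.01, 0.005)
#: Coefficients with absolute value above this count as non-zero.
NONZERO_TOL = 1e-8
#: Default p-value gate applied before ranking SNPs by F score.
P_THRESHOLD = 0.01
#: Default size of the per-scorer top lists.
TOP_K = 30
#: Default neighbor count for the kNN MI estimator.
K_NEIGHBORS = 3
#: Features with at most this many distinct values use the discrete MI path.
DISCRETE_MAX_UNIQUE = 32

LASSO_TOL = 1e-6
LASSO_MAX_ITER = 10_000


# ---------------------------------------------------------------------------
# Univariate F test
# ---------------------------------------------------------------------------

def univariate_f_scores(
    X: np.ndarray, y: np.ndarray, snp_ids: list[str]
) -> pd.DataFrame:
    """Pearson r, F statistic and p-value of each SNP against the grades.

    r is the centered cross-product over the product of standard deviations;
    F = r^2 / (1 - r^2) * (n - 2) with an upper-tail p-value from the
    F(1, n-2) distribution.  Constant SNPs have undefined correlation: they
    get NaN scores, are logged, and are excluded from all rankings.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for the univariate F test")
    if np.ptp(y) == 0:
        raise ValueError("target is constant; F scores undefined")

    variable = X.std(axis=0) > 0
    r = np.full(X.shape[1], np.nan)
    f = np.full(X.shape[1], np.nan)
    p = np.full(X.shape[1], np.nan)
    if variable.any():
        xc = X[:, variable] - X[:, variable].mean(axis=0)
        yc = y - y.mean()
        r_v = (xc * yc[:, None]).sum(axis=0) / (
            np.sqrt((xc**2).sum(axis=0)) * np.sqrt((yc**2).sum())
        )
        r[variable] = r_v
        f[variable], p[variable] = f_regression(X[:, variable], y)
    n_const = int((~variable).sum())
    if n_const:
        logger.info("excluded %d constant SNPs from the F test", n_const)
    return pd.DataFrame(
        {"pearson_r": r, "f_score": f, "p_value": p}, index=pd.Index(snp_ids, name="snp_id")
    )


def select_by_f(
    table: pd.DataFrame, p_threshold: float = P_THRESHOLD
) -> list[str]:
    """SNPs passing the p-value gate, ranked by descending F.

    Ties in F are broken by lexicographic snp_id so the ranking is
    deterministic.
    """
    passed = table[table["p_value"] < p_threshold].reset_index()
    order = passed.sort_values(["f_score", "snp_id"], ascending=[False, True])
    return list(order["snp_id"])


# ---------------------------------------------------------------------------
# kNN mutual information
# ---------------------------------------------------------------------------

def _knn_distance_sorted(s: np.ndarray, k: int) -> np.ndarray:
    """Distance to the k-th nearest neighbor for each point of a sorted 1-D
    array, computed by scanning the k+1 candidate windows around each point."""
    m = s.size
    dist = np.full(m, np.inf)
    idx = np.arange(m)
    for t in range(k + 1):
        left = idx - k + t
        right = idx + t
        valid = (left >= 0) & (right <= m - 1)
        d = np.full(m, np.inf)
        lv = np.where(valid, left, 0)
        rv = np.where(valid, right, m - 1)
        d[valid] = np.maximum(s - s[lv], s[rv] - s)[valid]
        dist = np.minimum(dist, d)
    return dist


def _count_within(sorted_vals: np.ndarray, centers: np.ndarray,
                  dists: np.ndarray) -> np.ndarray:
    """Count sorted values strictly within ``dists`` of each center.

    Interval endpoints ``center +/- dist`` are corrected for floating-point
    rounding so the count is exactly ``#{v : |v - center| < dist}``.
    """
    n = sorted_vals.size
    hi = np.searchsorted(sorted_vals, centers + dists, side="right")
    lo = np.searchsorted(sorted_vals, centers - dists, side="left")
    # rounding of center +/- dist can land the boundary one element off
    for _ in range(n):
        over = (hi > lo) & (sorted_vals[np.minimum(hi - 1, n - 1)] - centers >= dists)
        if not over.any():
            break
        hi[over] -= 1
    for _ in range(n):
        under = (hi < n) & (sorted_vals[np.minimum(hi, n - 1)] - centers < dists)
        if not under.any():
            break
        hi[under] += 1
    for _ in range(n):
        over = (lo < hi) & (centers - sorted_vals[np.minimum(lo, n - 1)] >= dists)
        if not over.any():
            break
        lo[over] += 1
    for _ in range(n):
        under = (lo > 0) & (centers - sorted_vals[np.maximum(lo - 1, 0)] < dists)
        if not under.any():
            break
        lo[under] -= 1
    return hi - lo


def _mi_discrete_continuous(x: np.ndarray, y: np.ndarray, k: int) -> float:
    """Mixed-type MI estimator (nearest-neighbor entropy, Ross variant) for a
    discrete feature ``x`` against a continuous target ``y``.

    For each point, the distance to its k-th nearest target value *within its
    own feature level* defines a radius; counting how many targets overall
    fall strictly inside that radius yields the estimate
    psi(n) + <psi(k)> - <psi(level count)> - <psi(radius count)>.
    Levels with a single sample are ignored.  Negative estimates clip to 0.
    """
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    # contiguous runs of equal feature values
    boundaries = np.flatnonzero(np.diff(xs) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [xs.size]))

    radius = np.empty(xs.size)
    counts = np.empty(xs.size)
    k_all = np.empty(xs.size)
    valid = np.zeros(xs.size, dtype=bool)
    for a, b in zip(starts, ends):
        cnt = b - a
        if cnt <= 1:
            continue
        kk = min(k, cnt - 1)
        grp = np.sort(ys[a:b])
        d = _knn_distance_sorted(grp, kk)
        # map distances back to the unsorted group order
        grp_order = np.argsort(ys[a:b], kind="stable")
        dd = np.empty(cnt)
        dd[grp_order] = d
        sl = slice(a, b)
        radius[sl] = dd
        counts[sl] = cnt
        k_all[sl] = kk
        valid[sl] = True

    if not valid.any():
        return 0.0
    yv = ys[valid]
    rv = radius[valid]
    y_sorted = np.sort(yv)
    # strictly inside the k-th neighbor distance, self included
    m_all = _count_within(y_sorted, yv, rv)
    n_eff = int(valid.sum())
    mi = (
        digamma(n_eff)
        + np.mean(digamma(k_all[valid]))
        - np.mean(digamma(counts[valid]))
        - np.mean(digamma(m_all))
    )
    return max(0.0, float(mi))


def _mi_continuous_continuous(x: np.ndarray, y: np.ndarray, k: int) -> float:
    """Kraskov-Grassberger kNN MI estimator for two continuous variables."""
    n = x.size
    xy = np.column_stack((x, y))
    tree = cKDTree(xy)
    # k+1 because the query point itself is its own nearest neighbor
    dist, _ = tree.query(xy, k=k + 1, p=np.inf)
    radius = dist[:, -1]
    xs = np.sort(x)
    ys = np.sort(y)
    # marginal neighbor counts strictly inside the radius, self excluded
    nx = _count_within(xs, x, radius) - 1
    ny = _count_within(ys, y, radius) - 1
    mi = (
        digamma(n) + digamma(k)
        - np.mean(digamma(nx + 1))
        - np.mean(digamma(ny + 1))
    )
    return max(0.0, float(mi))


def mutual_info_scores(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = K_NEIGHBORS,
    seed: int = 0,
) -> np.ndarray:
    """Non-negative kNN mutual-information estimate per feature (nats).

    The continuous target is variance-scaled and perturbed by tiny seeded
    noise to break grade ties, mirroring common practice for nearest-neighbor
    entropy estimators.  Features with few distinct values (genotype codes,
    possibly mean-imputed) use the mixed discrete/continuous estimator;
    others are scaled, noise-perturbed and sent through the continuous
    estimator.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be below n={n}")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    rng = np.random.default_rng(seed)

    y_std = y.std()
    yc = y / y_std if y_std > 0 else y.copy()
    yc = yc + 1e-10 * max(1.0, np.mean(np.abs(yc))) * rng.standard_normal(n)

    mi = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        x = X[:, j]
        if np.unique(x).size <= DISCRETE_MAX_UNIQUE:
            mi[j] = _mi_discrete_continuous(x, yc, k_neighbors)
        else:
            x_std = x.std()
            xc = x / x_std if x_std > 0 else x.copy()
            xc = xc + 1e-10 * max(1.0, np.mean(np.abs(xc))) * rng.standard_normal(n)
            mi[j] = _mi_continuous_continuous(xc, yc, k_neighbors)
    return mi


# ---------------------------------------------------------------------------
# Lasso
# ---------------------------------------------------------------------------

@dataclass
class LassoSpec:
    """A fitted L1-penalized linear model at one penalty value.

    The objective is ``(1 / (2 n)) * ||X w - y||^2 + alpha * ||w||_1`` with an
    unpenalized intercept.
    """

    alpha: float
    coef: np.ndarray
    intercept: float
    n_samples: int
    objective: float
    n_iter: int
    converged: bool

    def nonzero(self, tol: float = NONZERO_TOL) -> np.ndarray:
        return np.abs(self.coef) > tol


def lasso_objective(
    X: np.ndarray, y: np.ndarray, coef: np.ndarray, intercept: float, alpha: float
) -> float:
    resid = y - X @ coef - intercept
    n = X.shape[0]
    return float(resid @ resid / (2 * n) + alpha * np.abs(coef).sum())


def lasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    tol: float = LASSO_TOL,
    max_iter: int = LASSO_MAX_ITER,
) -> LassoSpec:
    """Fit the Lasso at one alpha by cyclic coordinate descent.

    ``alpha = 0`` falls back to ordinary least squares.  Non-convergence at
    ``max_iter`` is flagged on the result and logged, not raised.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("X must be finite (impute missing genotypes first)")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if alpha == 0.0:
        ols = LinearRegression().fit(X, y)
        coef, intercept = ols.coef_, float(ols.intercept_)
        return LassoSpec(
            alpha=0.0, coef=coef, intercept=intercept, n_samples=X.shape[0],
            objective=lasso_objective(X, y, coef, intercept, 0.0),
            n_iter=0, converged=True,
        )
    model = Lasso(alpha=alpha, fit_intercept=True, tol=tol,
                  max_iter=max_iter, selection="cyclic")
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(X, y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            logger.warning("Lasso did not converge at alpha=%g within %d iters",
                           alpha, max_iter)
    return LassoSpec(
        alpha=alpha,
        coef=model.coef_.copy(),
        intercept=float(model.intercept_),
        n_samples=X.shape[0],
        objective=lasso_objective(X, y, model.coef_, float(model.intercept_), alpha),
        n_iter=int(model.n_iter_),
        converged=converged,
    )


@dataclass
class LassoPath:
    """Coefficients, non-zero counts and train r^2 over an alpha grid."""

    alphas: tuple[float, ...]
    coefs: pd.DataFrame            # snp_id x alpha
    intercepts: dict[float, float]
    nonzero_counts: dict[float, int]
    train_r2: dict[float, float]
    converged: dict[float, bool]

    def coef(self, alpha: float) -> pd.Series:
        return self.coefs[alpha]

    def nonzero_ids(self, alpha: float, tol: float = NONZERO_TOL) -> list[str]:
        c = self.coefs[alpha]
        return list(c.index[np.abs(c.values) > tol])


def lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    snp_ids: list[str],
    alphas: tuple[float, ...] = ALPHA_GRID,
    tol: float = LASSO_TOL,
    max_iter: int = LASSO_MAX_ITER,
) -> LassoPath:
    """Fit the Lasso over the alpha grid, warm-starting from larger alphas.

    The non-zero count is non-increasing in alpha (sparser models at larger
    penalties); the path reports per-alpha non-zero counts and train r^2.
    """
    if len(alphas) == 0:
        raise ValueError("alpha grid must be non-empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    order = sorted(set(alphas), reverse=True)
    coefs: dict[float, np.ndarray] = {}
    intercepts: dict[float, float] = {}
    r2: dict[float, float] = {}
    converged: dict[float, bool] = {}
    model = Lasso(alpha=order[0], fit_intercept=True, tol=tol,
                  max_iter=max_iter, selection="cyclic", warm_start=True)
    y_var = float(((y - y.mean()) ** 2).sum())
    for a in order:
        if a == 0.0:
            spec = lasso_fit(X, y, 0.0)
            coefs[a], intercepts[a] = spec.coef, spec.intercept
            converged[a] = True
        else:
            model.set_params(alpha=a)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", ConvergenceWarning)
                model.fit(X, y)
                converged[a] = not any(
                    issubclass(w.category, ConvergenceWarning) for w in caught
                )
            coefs[a] = model.coef_.copy()
            intercepts[a] = float(model.intercept_)
        resid = y - X @ coefs[a] - intercepts[a]
        r2[a] = 1.0 - float(resid @ resid) / y_var if y_var > 0 else np.nan
    frame = pd.DataFrame(
        {a: coefs[a] for a in alphas}, index=pd.Index(snp_ids, name="snp_id")
    )
    return LassoPath(
        alphas=tuple(alphas),
        coefs=frame,
        intercepts={a: intercepts[a] for a in alphas},
        nonzero_counts={a: int((np.abs(coefs[a]) > NONZERO_TOL).sum()) for a in alphas},
        train_r2={a: r2[a] for a in alphas},
        converged={a: converged[a] for a in alphas},
    )


# ---------------------------------------------------------------------------
# Score table and top lists
# ---------------------------------------------------------------------------

@dataclass
class FeatureScoreTable:
    """All per-SNP scores for one dataset: r, F, p, MI and Lasso path.

    ``rank_f`` is the 1-based rank by descending F *among SNPs passing the
    p-value gate* (NaN otherwise); ``rank_mi`` ranks all SNPs by descending
    MI.  Ties break lexicographically by snp_id.
    """

    table: pd.DataFrame
    path: LassoPath
    n_samples: int
    p_threshold: float = P_THRESHOLD

    @property
    def snp_ids(self) -> list[str]:
        return list(self.table.index)

    def top_ids(self, metric: str, k: int) -> list[str]:
        col = f"rank_{metric}"
        ranks = self.table[col]
        return list(ranks.index[ranks <= k])

    def nonzero_ids(self, alpha: float) -> list[str]:
        return self.path.nonzero_ids(alpha)

    def abs_coef_ids(self, alpha: float, threshold: float, strict: bool = False) -> list[str]:
        c = self.path.coef(alpha).abs()
        keep = c > threshold if strict else c >= threshold
        return list(c.index[keep])

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        for a in self.path.alphas:
            out[f"coef_a{a:g}"] = self.path.coef(a)
        return out


def _dense_rank(values: pd.Series, gate: pd.Series | None = None) -> pd.Series:
    """1-based rank by descending value, ties broken by index label."""
    v = values.copy()
    if gate is not None:
        v = v.where(gate)
    order = sorted(
        [i for i in v.index if pd.notna(v[i])],
        key=lambda i: (-v[i], i),
    )
    ranks = pd.Series(np.nan, index=values.index)
    for pos, i in enumerate(order, start=1):
        ranks[i] = pos
    return ranks


def compute_feature_scores(
    X: np.ndarray,
    y: np.ndarray,
    snp_ids: list[str],
    alphas: tuple[float, ...] = ALPHA_GRID,
    k_neighbors: int = K_NEIGHBORS,
    p_threshold: float = P_THRESHOLD,
    seed: int = 0,
) -> FeatureScoreTable:
    """Run all three scorers on one training dataset."""
    table = univariate_f_scores(X, y, snp_ids)
    table["mi"] = mutual_info_scores(X, y, k_neighbors=k_neighbors, seed=seed)
    path = lasso_path(X, y, snp_ids, alphas=alphas)
    gate = table["p_value"] < p_threshold
    table["rank_f"] = _dense_rank(table["f_score"], gate=gate)
    table["rank_mi"] = _dense_rank(table["mi"])
    return FeatureScoreTable(
        table=table, path=path, n_samples=X.shape[0], p_threshold=p_threshold
    )


@dataclass
class TopSnpList:
    """Union of the per-scorer top SNPs for one dataset, with provenance.

    ``flags`` is a boolean frame indexed by snp_id whose columns mark which
    selection route(s) each SNP satisfied (``top_f``, ``top_mi``,
    ``nonzero_a<alpha>``).
    """

    dataset: str
    flags: pd.DataFrame

    @property
    def snp_ids(self) -> list[str]:
        return list(self.flags.index)

    def __len__(self) -> int:
        return len(self.flags)


def build_top_snp_list(
    scores: FeatureScoreTable,
    dataset: str,
    top_k: int = TOP_K,
    lasso_alphas: tuple[float, ...] = TOP_LIST_ALPHAS,
) -> TopSnpList:
    """Union of top-k F (p-gated), top-k MI and non-zero Lasso sets.

    Each SNP carries every provenance flag it satisfies; duplicates collapse.
    """
    routes: dict[str, set[str]] = {
        "top_f": set(scores.top_ids("f", top_k)),
        "top_mi": set(scores.top_ids("mi", top_k)),
    }
    for a in lasso_alphas:
        routes[f"nonzero_a{a:g}"] = set(scores.nonzero_ids(a))
    members = sorted(set().union(*routes.values()))
    flags = pd.DataFrame(
        {name: [s in ids for s in members] for name, ids in routes.items()},
        index=pd.Index(members, name="snp_id"),
    )
    return TopSnpList(dataset=dataset, flags=flags)
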