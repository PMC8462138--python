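"""Population-level statistics on flattened color vectors.

Directions of evolution and their correlations
----------------------------------------------
With known ancestor–descendant population pairs (high-predation ancestor,
low-predation descendant), the difference between population mean color
vectors measures the direction of color evolution within a river.
Similarity of two rivers' directions is the vector correlation r, which is
Pearson's correlation coefficient between the two p-vectors.  Uncertainty
comes from bootstrapping whole specimens (whole rows, preserving the
within-fish channel/point associations) and pairing replicate b of one
river with replicate b of the other; the null reference is the correlation
of paired i.i.d. standard-normal vectors of the same dimension.

Variance comparisons
--------------------
Total phenotypic variance of a population is the trace of its covariance
matrix (sum of per-variable sample variances, n-1 denominator), compared
between predation regimes by a label-permutation test.  Per-point variance
is split into among- and within-population components by REML for the
one-way random-effects model with fixed year effects, via the profile
restricted likelihood over the variance ratio.

Classification
--------------
DAPC (discriminant analysis of principal components): PCA reduction of the
color vectors followed by linear discriminant analysis on the scores, with
stratified cross-validation over a grid of retained-PC counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedShuffleSplit

from .errors import ParameterError, StatError, StructuralError
from .types import PopulationSample

__all__ = [
    "vector_correlation",
    "bootstrap_directions",
    "CorrelationDistribution",
    "pairwise_direction_correlation",
    "random_vector_null",
    "trace_of_covariance",
    "permutation_variance_test",
    "variance_components",
    "variance_components_map",
    "VarCompResult",
    "DAPC",
    "dapc_fit",
    "dapc_xval",
]


# ---------------------------------------------------------------------------
# Vector correlations
# ---------------------------------------------------------------------------

def vector_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation between two p-vectors (p >= 2, non-constant)."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape or u.size < 2:
        raise ParameterError("vectors must share length >= 2")
    uc = u - u.mean()
    vc = v - v.mean()
    nu = np.linalg.norm(uc)
    nv = np.linalg.norm(vc)
    if nu == 0 or nv == 0:
        raise StatError("correlation undefined for a constant vector")
    return float(np.clip(uc @ vc / (nu * nv), -1.0, 1.0))


def _rowwise_correlation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation of paired rows of two (B, p) matrices."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", Ac, Bc)
    den = np.linalg.norm(Ac, axis=1) * np.linalg.norm(Bc, axis=1)
    if np.any(den == 0):
        raise StatError("correlation undefined for a constant vector")
    return np.clip(num / den, -1.0, 1.0)


def bootstrap_directions(
    hp: PopulationSample, lp: PopulationSample, B: int, seed=None
) -> np.ndarray:
    """B bootstrap replicates of the direction of evolution (lp - hp means).

    Whole specimens (rows) are resampled with replacement within each
    population, preserving the associations of channel values within and
    among sampling points; each replicate's direction is the difference of
    resampled population means.
    """
    if B < 1:
        raise ParameterError("B must be >= 1")
    if hp.n == 0 or lp.n == 0:
        raise StructuralError("empty population")
    if hp.p != lp.p:
        raise StructuralError("populations disagree on vector length")
    rng = np.random.default_rng(seed)
    hp_idx = rng.integers(0, hp.n, size=(B, hp.n))
    lp_idx = rng.integers(0, lp.n, size=(B, lp.n))
    hp_means = hp.X[hp_idx].mean(axis=1)
    lp_means = lp.X[lp_idx].mean(axis=1)
    return lp_means - hp_means


@dataclass
class CorrelationDistribution:
    """Observed vector correlation with its bootstrap distribution."""

    observed: float
    draws: np.ndarray
    ci: tuple[float, float]
    B: int


def pairwise_direction_correlation(
    riverA: tuple[PopulationSample, PopulationSample],
    riverB: tuple[PopulationSample, PopulationSample],
    B: int = 1000,
    ci_level: float = 0.95,
    seed=None,
) -> CorrelationDistribution:
    """Correlation between two rivers' directions of evolution.

    The observed r correlates the two observed direction vectors; replicate
    b pairs the b-th bootstrap direction of river A with the b-th of river
    B, and the CI is the percentile interval of the replicate correlations.
    """
    (hpA, lpA), (hpB, lpB) = riverA, riverB
    if hpA.p != hpB.p:
        raise StructuralError("rivers disagree on vector length")
    dA = lpA.X.mean(axis=0) - hpA.X.mean(axis=0)
    dB = lpB.X.mean(axis=0) - hpB.X.mean(axis=0)
    observed = vector_correlation(dA, dB)
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    sA, sB = ss.spawn(2)
    bootA = bootstrap_directions(hpA, lpA, B, seed=sA)
    bootB = bootstrap_directions(hpB, lpB, B, seed=sB)
    draws = _rowwise_correlation(bootA, bootB)
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.percentile(draws, [100 * alpha, 100 * (1 - alpha)])
    return CorrelationDistribution(observed=observed, draws=draws, ci=(float(lo), float(hi)), B=B)


def random_vector_null(B: int, p: int, seed=None) -> tuple[float, np.ndarray]:
    """Null distribution of the correlation between paired random vectors.

    Draws two B x p matrices of i.i.d. standard normals (zero mean,
    identity covariance) and correlates paired rows.  Returns the mean
    correlation and the full distribution; the asymptotic null SD of each r
    is 1/sqrt(p - 1).
    """
    if B < 1 or p < 2:
        raise ParameterError("need B >= 1 and p >= 2")
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((B, p))
    Bm = rng.standard_normal((B, p))
    r = _rowwise_correlation(A, Bm)
    return float(r.mean()), r


# ---------------------------------------------------------------------------
# Variance comparisons
# ---------------------------------------------------------------------------

def trace_of_covariance(pop: PopulationSample) -> float:
    """Sum of per-variable sample variances (n-1 denominator).

    Equals the trace of the p x p covariance matrix without forming it.
    """
    if pop.n < 2:
        raise StatError("trace of covariance needs n >= 2")
    return float(pop.X.var(axis=0, ddof=1).sum())


def permutation_variance_test(
    hp: PopulationSample,
    lp: PopulationSample,
    n_perm: int = 1000,
    seed=None,
    sign: str = "lp_minus_hp",
) -> tuple[float, np.ndarray, float]:
    """Permutation test for a difference in total phenotypic variance.

    The statistic is trace(lp) - trace(hp) by default (``sign`` may be
    "hp_minus_lp" to flip it; the two-sided p-value is unaffected).  Each
    permutation reshuffles the predation labels over the pooled specimens
    preserving group sizes; whole rows move together, so no specimen's
    internal values are ever altered.  p = (1 + #{|perm| >= |obs|}) /
    (n_perm + 1).
    """
    if hp.n < 2 or lp.n < 2:
        raise StructuralError("both groups need n >= 2")
    if sign not in ("lp_minus_hp", "hp_minus_lp"):
        raise ParameterError("sign must be 'lp_minus_hp' or 'hp_minus_lp'")
    flip = 1.0 if sign == "lp_minus_hp" else -1.0
    observed = flip * (trace_of_covariance(lp) - trace_of_covariance(hp))
    pooled = np.vstack([hp.X, lp.X])
    n_hp = hp.n
    n_tot = pooled.shape[0]
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.permutation(n_tot)
        g_hp = pooled[idx[:n_hp]]
        g_lp = pooled[idx[n_hp:]]
        null[b] = flip * (
            g_lp.var(axis=0, ddof=1).sum() - g_hp.var(axis=0, ddof=1).sum()
        )
    p_value = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (n_perm + 1.0)
    return observed, null, float(p_value)


# ---------------------------------------------------------------------------
# REML variance components
# ---------------------------------------------------------------------------

@dataclass
class VarCompResult:
    """Variance decomposition at one (point, channel)."""

    sigma2_pop: float
    sigma2_resid: float

    @property
    def prop_within(self) -> float:
        tot = self.sigma2_pop + self.sigma2_resid
        if tot == 0:
            return 1.0
        return self.sigma2_resid / tot


def _reduce_to_full_rank(X: np.ndarray) -> np.ndarray:
    """Drop linearly dependent columns (QR with pivoting)."""
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    keep = np.sort(piv[:rank])
    return X[:, keep]


def variance_components(
    values: np.ndarray, pop_labels: np.ndarray, year_labels: np.ndarray | None = None
) -> VarCompResult:
    """REML variance components for a one-way random-effects model.

    Model: value = year (fixed) + population (random intercept) + residual.
    The restricted likelihood is profiled over the variance ratio
    lam = sigma2_pop / sigma2_resid and maximized by bounded scalar
    optimization; estimates are truncated at zero.  In a balanced design
    with no fixed effects this reproduces the classical ANOVA estimator.
    """
    y = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        raise StatError("non-finite values")
    pops, codes = np.unique(np.asarray(pop_labels), return_inverse=True)
    if pops.size < 2:
        raise StructuralError("need at least 2 populations")
    n = y.size
    if year_labels is not None:
        years = np.asarray(year_labels)
        uy = np.unique(years)
        X = np.column_stack(
            [np.ones(n)] + [(years == lvl).astype(float) for lvl in uy[1:]]
        )
    else:
        X = np.ones((n, 1))
    X = _reduce_to_full_rank(X)
    r = X.shape[1]

    group_sizes = np.bincount(codes, minlength=pops.size).astype(float)

    def _profile(lam: float) -> tuple[float, float]:
        """(-2 restricted loglik up to a constant, profiled sigma2_resid)."""
        w = lam / (1.0 + lam * group_sizes)  # per-group shrinkage
        # V^-1 x = x - w_g * J x within each group
        gsum_y = np.bincount(codes, weights=y, minlength=pops.size)
        Viy = y - w[codes] * gsum_y[codes]
        ViX = np.empty_like(X)
        for j in range(r):
            gsx = np.bincount(codes, weights=X[:, j], minlength=pops.size)
            ViX[:, j] = X[:, j] - w[codes] * gsx[codes]
        XtViX = X.T @ ViX
        XtViy = X.T @ Viy
        try:
            beta = np.linalg.solve(XtViX, XtViy)
            sign_det, logdet_xvx = np.linalg.slogdet(XtViX)
        except np.linalg.LinAlgError:
            return np.inf, 0.0
        if sign_det <= 0:
            return np.inf, 0.0
        ypy = float(y @ Viy - XtViy @ beta)
        ypy = max(ypy, 0.0)
        logdet_v = float(np.sum(np.log1p(lam * group_sizes)))
        if ypy == 0.0:
            return -np.inf, 0.0  # perfect fit: variance zero
        crit = logdet_v + logdet_xvx + (n - r) * np.log(ypy)
        return crit, ypy / (n - r)

    def objective(log_lam: float) -> float:
        return _profile(float(np.exp(log_lam)))[0]

    res = minimize_scalar(objective, bounds=(-18.0, 18.0), method="bounded")
    candidates = [0.0, float(np.exp(res.x))]
    best_lam, best_crit, best_s2 = 0.0, np.inf, 0.0
    for lam in candidates:
        crit, s2 = _profile(lam)
        if crit < best_crit:
            best_lam, best_crit, best_s2 = lam, crit, s2
    sigma2_resid = max(best_s2, 0.0)
    sigma2_pop = max(best_lam * sigma2_resid, 0.0)
    return VarCompResult(sigma2_pop=sigma2_pop, sigma2_resid=sigma2_resid)


def variance_components_map(
    values: np.ndarray,
    pop_labels: np.ndarray,
    year_labels: np.ndarray | None,
    points: np.ndarray,
) -> pd.DataFrame:
    """Per-(point, channel) variance decomposition over a color matrix.

    ``values`` is (n_specimens, n_points, 3).  Returns a long DataFrame with
    columns point_index, x, y, channel, sigma2_pop, sigma2_resid,
    prop_within, plus the channel-mean surface rows (channel = "mean") used
    for whole-body heat maps.
    """
    values = np.asarray(values, dtype=float)
    n, m, _ = values.shape
    rows = []
    channels = "RGB"
    prop = np.empty((m, 3))
    for j in range(m):
        for c in range(3):
            vc = variance_components(values[:, j, c], pop_labels, year_labels)
            prop[j, c] = vc.prop_within
            rows.append(
                {
                    "point_index": j,
                    "x": points[j, 0],
                    "y": points[j, 1],
                    "channel": channels[c],
                    "sigma2_pop": vc.sigma2_pop,
                    "sigma2_resid": vc.sigma2_resid,
                    "prop_within": vc.prop_within,
                }
            )
    for j in range(m):
        rows.append(
            {
                "point_index": j,
                "x": points[j, 0],
                "y": points[j, 1],
                "channel": "mean",
                "sigma2_pop": np.nan,
                "sigma2_resid": np.nan,
                "prop_within": prop[j].mean(),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------

class DAPC(ClassifierMixin, BaseEstimator):
    """Discriminant analysis of principal components.

    Centers the data, projects onto the first ``n_pcs`` principal
    components (SVD, no per-variable scaling: channels share the [0, 1]
    scale), then runs linear discriminant analysis on the scores.  At most
    (groups - 1) discriminant axes exist; ``explained_variance_ratio_``
    gives each axis's share of the discriminant eigenvalue total.
    """

    def __init__(self, n_pcs: int = 50):
        self.n_pcs = n_pcs

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DAPC":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n, p = X.shape
        if self.n_pcs > min(n - 1, p):
            raise ParameterError(
                f"n_pcs={self.n_pcs} exceeds min(n - 1, p) = {min(n - 1, p)}; retain fewer PCs"
            )
        self.classes_, yi = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise StructuralError("DAPC needs at least 2 groups")
        self.pca_ = PCA(n_components=self.n_pcs, svd_solver="full").fit(X)
        scores = self.pca_.transform(X)
        k = self.classes_.size
        means = np.stack([scores[yi == c].mean(axis=0) for c in range(k)])
        within = float(((scores - means[yi]) ** 2).sum())
        total = float(((scores - scores.mean(axis=0)) ** 2).sum())
        if within <= 1e-12 * max(total, 1.0):
            # point-mass groups: the discriminant subspace is spanned by the
            # (weighted, centered) class means; assignment is nearest mean
            counts = np.bincount(yi, minlength=k).astype(float)
            xbar = (counts[:, None] * means).sum(axis=0) / counts.sum()
            M = np.sqrt(counts)[:, None] * (means - xbar)
            _, S, Vt = np.linalg.svd(M, full_matrices=False)
            naxes = min(k - 1, int(np.sum(S > 1e-12 * max(S[0], 1.0))))
            self._axes = Vt[:naxes]
            self._xbar = xbar
            self._means = means
            self.lda_ = None
            self.explained_variance_ratio_ = (S[:naxes] ** 2) / (S**2).sum()
            self.scores_ = (scores - xbar) @ self._axes.T
        else:
            self.lda_ = LinearDiscriminantAnalysis(solver="svd").fit(scores, y)
            self.explained_variance_ratio_ = self.lda_.explained_variance_ratio_
            self.scores_ = self.lda_.transform(scores)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        scores = self.pca_.transform(np.asarray(X, dtype=float))
        if self.lda_ is None:
            return (scores - self._xbar) @ self._axes.T
        return self.lda_.transform(scores)

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.pca_.transform(np.asarray(X, dtype=float))
        if self.lda_ is None:
            d = np.linalg.norm(scores[:, None, :] - self._means[None, :, :], axis=-1)
            return self.classes_[np.argmin(d, axis=1)]
        return self.lda_.predict(scores)

    @property
    def n_axes_(self) -> int:
        return self.scores_.shape[1]


def dapc_fit(X: np.ndarray, labels: np.ndarray, n_pc: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Functional wrapper over :class:`DAPC`.

    Returns ``(scores, predicted_labels, percent_variance_per_axis)`` for
    the training data, with percentages on a 0-100 scale.
    """
    model = DAPC(n_pcs=n_pc).fit(X, labels)
    return model.scores_, model.predict(X), 100.0 * model.explained_variance_ratio_


def dapc_xval(
    X: np.ndarray,
    labels: np.ndarray,
    pc_grid,
    n_rep: int = 100,
    train_frac: float = 0.8,
    seed=None,
) -> pd.DataFrame:
    """Stratified cross-validation of DAPC over a grid of retained PCs.

    For each grid value, ``n_rep`` stratified train/validation splits
    (train_frac of each group for training) are scored by the proportion of
    validation specimens assigned to their true group; RMSE is the root
    mean square of (1 - success) over replicates.  The same splits are used
    at every grid value, so grid values differ only in the retention level.
    Grid values exceeding the feasible rank are skipped with a warning.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n, p = X.shape
    rng_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1))
    splitter = StratifiedShuffleSplit(
        n_splits=n_rep, train_size=train_frac, random_state=rng_seed
    )
    splits = list(splitter.split(X, labels))
    n_train = len(splits[0][0])
    rows = []
    for n_pc in pc_grid:
        if n_pc > min(n_train - 1, p):
            warnings.warn(
                f"skipping n_pc={n_pc}: exceeds feasible rank {min(n_train - 1, p)}",
                stacklevel=2,
            )
            continue
        successes = np.empty(len(splits))
        for i, (tr, va) in enumerate(splits):
            model = DAPC(n_pcs=int(n_pc)).fit(X[tr], labels[tr])
            pred = model.predict(X[va])
            successes[i] = float(np.mean(pred == labels[va]))
        rows.append(
            {
                "n_pc": int(n_pc),
                "mean_success": float(successes.mean()),
                "rmse": float(np.sqrt(np.mean((1.0 - successes) ** 2))),
            }
        )
    return pd.DataFrame(rows)
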