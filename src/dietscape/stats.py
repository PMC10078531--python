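"""Statistical engine: dissimilarity, permutation tests, ordination, model
ranking, and the multivariate condition index.

All permutation procedures use the plus-one rule ``p = (b + 1) / (n_perm + 1)``
where ``b`` counts permuted statistics at least as extreme as the observed
one, so p-values are never exactly zero.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import isotonic_regression

from ._rng import stream

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "PermanovaTerm",
    "MantelResult",
    "NmdsResult",
    "OlsResult",
    "ModelRank",
    "WelchResult",
    "bray_curtis",
    "permanova",
    "pairwise_permanova",
    "holm_adjust",
    "mantel",
    "nmds",
    "ols_fit",
    "aicc_rank",
    "welch_t",
    "condition_index",
]


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric, hollow, nonnegative pairwise distance matrix with labels."""

    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise ValueError("distance matrix has negative entries")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries as a flat vector (row-major)."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def subset(self, keep: np.ndarray) -> "DistanceMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        labels = [self.labels[i] for i in keep]
        return DistanceMatrix(labels, self.values[np.ix_(keep, keep)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def bray_curtis(table) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between rows of an abundance table.

    ``d(a, b) = sum|a_i - b_i| / sum(a_i + b_i)``.

    Parameters
    ----------
    table : pandas.DataFrame or array-like
        Rows are samples, columns are taxa; entries nonnegative. If a
        DataFrame, its index provides the output labels.

    Returns
    -------
    DistanceMatrix
        Entries lie in [0, 1].
    """
    if isinstance(table, pd.DataFrame):
        labels = list(table.index)
        X = table.to_numpy(dtype=float)
    else:
        X = np.asarray(table, dtype=float)
        labels = list(range(X.shape[0]))
    if (X < 0).any():
        raise ValueError("abundance table has negative entries")
    row_sums = X.sum(axis=1)
    zero = np.flatnonzero(row_sums == 0)
    if zero.size:
        raise ValueError(f"all-zero rows: {[labels[i] for i in zero]}")
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(X[i] - X[i + 1 :]).sum(axis=1)
        tot = row_sums[i] + row_sums[i + 1 :]
        D[i, i + 1 :] = diff / tot
    D = D + D.T
    return DistanceMatrix(labels, D)


# ---------------------------------------------------------------------------
# perMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaTerm:
    name: str
    df: int
    ss: float
    pseudo_f: float | None
    r2: float
    p_perm: float | None


@dataclass
class PermanovaResult:
    terms: list[PermanovaTerm]
    residual_df: int
    residual_ss: float
    total_ss: float
    n_perm: int
    blocks: np.ndarray | None
    seed: int | None

    def term(self, name: str) -> PermanovaTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    n = A.shape[0]
    row = A.mean(axis=0)
    grand = A.mean()
    return A - row[None, :] - row[:, None] + grand


def _dummies(labels: np.ndarray) -> np.ndarray:
    """Treatment-coded dummy columns (first level dropped)."""
    levels = np.unique(labels)
    return (labels[:, None] == levels[None, 1:]).astype(float)


def _hat_trace(X: np.ndarray, G: np.ndarray) -> float:
    """trace(H G) for the hat matrix of X, via thin QR."""
    Q, R = np.linalg.qr(X)
    # guard against rank deficiency: drop dependent columns
    keep = np.abs(np.diag(R)) > 1e-10 * max(X.shape)
    if not keep.all():
        Q = Q[:, keep]
    return float(np.einsum("ij,ij->", Q, G @ Q))


def _oneway_f(
    W: np.ndarray,
    codes: np.ndarray,
    n_levels: int,
    sizes: np.ndarray,
    ss_total: float,
    df_f: int,
    df_res: int,
) -> float:
    ss_w = 0.0
    for lev in range(n_levels):
        idx = np.flatnonzero(codes == lev)
        ss_w += W[np.ix_(idx, idx)].sum() / (2 * sizes[lev])
    ss_b = ss_total - ss_w
    return (ss_b / df_f) / (ss_w / df_res)


def _strata_permutation(rng, block: np.ndarray | None, n: int) -> np.ndarray:
    if block is None:
        return rng.permutation(n)
    perm = np.arange(n)
    for lev in np.unique(block):
        idx = np.flatnonzero(block == lev)
        perm[idx] = idx[rng.permutation(idx.size)]
    return perm


def permanova(
    D: DistanceMatrix,
    factor,
    block=None,
    n_perm: int = 9999,
    seed: int = 0,
) -> PermanovaResult:
    """Sequential (Type-I) permutational MANOVA on a distance matrix.

    Sums of squares are partitioned on the Gower-centered matrix
    ``G = -1/2 C D^2 C`` via hat-matrix traces, with the optional ``block``
    term fitted before ``factor``. Significance of the factor term is
    assessed by permuting sample labels; when a block is supplied the
    permutations are restricted within block strata and the block term is
    also fitted first in the sequential model (both halves of that
    convention together reproduce the standard blocked-design df pattern).

    Parameters
    ----------
    D : DistanceMatrix
    factor : sequence
        Main predictor, one label per sample; must have at least two levels.
    block : sequence, optional
        Blocking factor (e.g. sampling year).
    n_perm : int
        Number of label permutations.
    seed : int
        Seed for the permutation stream.

    Returns
    -------
    PermanovaResult
        Terms in fitting order (block first if present), with residual and
        total sums of squares satisfying additivity.
    """
    factor = np.asarray(factor)
    n = D.n
    if factor.shape != (n,):
        raise ValueError("factor length does not match distance matrix")
    levels, counts = np.unique(factor, return_counts=True)
    if levels.size < 2:
        raise ValueError("factor needs >= 2 levels")
    if (counts < 2).any() and levels.size == counts.size == 2:
        # a singleton group makes within-group variance undefined for that side
        if (counts < 2).all():
            raise ValueError("degenerate design: all groups are singletons")
    if block is not None:
        block = np.asarray(block)
        if block.shape != (n,):
            raise ValueError("block length does not match distance matrix")

    G = _gower_center(D.values)
    ss_total = float(np.trace(G))
    if ss_total <= 0:
        raise ValueError("degenerate distance matrix: no variance")

    ones = np.ones((n, 1))
    Xb = ones if block is None else np.hstack([ones, _dummies(block)])
    rank_b = np.linalg.matrix_rank(Xb)
    tr_b = _hat_trace(Xb, G)

    Xf_obs = _dummies(factor)
    Xfull = np.hstack([Xb, Xf_obs])
    rank_full = np.linalg.matrix_rank(Xfull)
    tr_full = _hat_trace(Xfull, G)

    df_block = rank_b - 1
    df_factor = rank_full - rank_b
    df_res = n - rank_full
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    ss_block = tr_b  # trace under intercept-only is 0 on the centered G
    ss_factor = tr_full - tr_b
    ss_res = ss_total - tr_full

    f_obs = (ss_factor / df_factor) / (ss_res / df_res)

    rng = stream(seed, "permanova")
    hits = 0
    if block is None:
        # one-way design: residual SS has a closed form in squared distances
        # (sum of within-group pairwise d^2 over group size), which vectorizes
        # over permutations. Identical to the hat-trace partition.
        W = D.values**2
        codes = np.searchsorted(levels, factor)
        sizes = counts.astype(float)
        f_ref = _oneway_f(W, codes, levels.size, sizes, ss_total, df_factor, df_res)
        chunk = max(1, min(n_perm, 2_000_000 // max(n * n, 1)))
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            P = np.stack([rng.permutation(n) for _ in range(m)])
            lab = codes[P]
            ss_w = np.zeros(m)
            for lev in range(levels.size):
                B = (lab == lev).astype(float)
                ss_w += np.einsum("ri,ij,rj->r", B, W, B) / (2 * sizes[lev])
            ss_b = ss_total - ss_w
            f_p = (ss_b / df_factor) / (ss_w / df_res)
            hits += int((f_p >= f_ref - 1e-12).sum())
            done += m
    else:
        for _ in range(n_perm):
            perm = _strata_permutation(rng, block, n)
            Xp = np.hstack([Xb, Xf_obs[perm]])
            tr_p = _hat_trace(Xp, G)
            ss_f_p = tr_p - tr_b
            ss_r_p = ss_total - tr_p
            f_p = (ss_f_p / df_factor) / (ss_r_p / df_res)
            if f_p >= f_obs - 1e-12:
                hits += 1
    p = (hits + 1) / (n_perm + 1)

    terms = []
    if block is not None:
        terms.append(
            PermanovaTerm("block", df_block, ss_block, None, ss_block / ss_total, None)
        )
    terms.append(
        PermanovaTerm("factor", df_factor, ss_factor, f_obs, ss_factor / ss_total, p)
    )
    return PermanovaResult(
        terms=terms,
        residual_df=df_res,
        residual_ss=ss_res,
        total_ss=ss_total,
        n_perm=n_perm,
        blocks=block,
        seed=seed,
    )


@dataclass
class PairwiseContrast:
    level_a: object
    level_b: object
    pseudo_f: float
    r2: float
    df: tuple[int, int]
    p_raw: float
    p_adjusted: float | None = None


def pairwise_permanova(
    D: DistanceMatrix,
    factor,
    block=None,
    n_perm: int = 999,
    seed: int = 0,
) -> list[PairwiseContrast]:
    """Post-hoc pairwise contrasts with Holm-adjusted p-values.

    Runs one two-group permanova per unordered pair of factor levels on the
    corresponding sub-matrix and applies the Holm step-down adjustment over
    the whole family of contrasts. Pairs where either side has fewer than two
    samples are skipped with a warning. The block term is dropped for a pair
    whose samples all share one block level.
    """
    factor = np.asarray(factor)
    block_arr = None if block is None else np.asarray(block)
    levels = np.unique(factor)
    if levels.size < 2:
        raise ValueError("factor needs >= 2 levels")
    contrasts: list[PairwiseContrast] = []
    for k, (a, b) in enumerate(itertools.combinations(levels, 2)):
        mask = (factor == a) | (factor == b)
        na = int((factor == a).sum())
        nb = int((factor == b).sum())
        if na < 2 or nb < 2:
            warnings.warn(f"skipping contrast {a} vs {b}: fewer than 2 per side")
            continue
        sub_block = None
        if block_arr is not None:
            sb = block_arr[mask]
            if np.unique(sb).size > 1:
                sub_block = sb
        res = permanova(
            D.subset(mask), factor[mask], block=sub_block, n_perm=n_perm, seed=seed + k
        )
        t = res.term("factor")
        contrasts.append(
            PairwiseContrast(a, b, t.pseudo_f, t.r2, (t.df, res.residual_df), t.p_perm)
        )
    adj = holm_adjust([c.p_raw for c in contrasts])
    for c, pa in zip(contrasts, adj):
        c.p_adjusted = pa
    return contrasts


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjustment, returned in the input order.

    ``adj_(i) = max_{j<=i} min(1, (m - j + 1) * p_(j))`` over the ascending
    order statistics.
    """
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------


@dataclass
class MantelResult:
    r: float
    p_perm: float
    n_perm: int
    seed: int


def mantel(
    D1: DistanceMatrix, D2: DistanceMatrix, n_perm: int = 9999, seed: int = 0
) -> MantelResult:
    """Mantel test: Pearson correlation of two distance matrices.

    ``r`` is the plain Pearson correlation of the strictly-lower-triangle
    vectors. The null distribution is built by jointly permuting the row and
    column order of ``D2``; the p-value is one-sided (greater), with the
    plus-one rule.
    """
    if D1.labels != D2.labels:
        raise ValueError("distance matrices must share labels in the same order")
    v1 = D1.condensed()
    n = D1.n
    if np.ptp(v1) == 0 or np.ptp(D2.condensed()) == 0:
        raise ValueError("zero variance in a distance matrix: r undefined")
    z1 = (v1 - v1.mean()) / v1.std()
    i, j = np.tril_indices(n, k=-1)

    def _corr(M2: np.ndarray) -> float:
        v2 = M2[i, j]
        s = v2.std()
        if s == 0:
            return 0.0
        return float(np.mean(z1 * (v2 - v2.mean()) / s))

    r_obs = _corr(D2.values)
    rng = stream(seed, "mantel")
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _corr(D2.values[np.ix_(perm, perm)]) >= r_obs - 1e-12:
            hits += 1
    return MantelResult(r_obs, (hits + 1) / (n_perm + 1), n_perm, seed)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


@dataclass
class NmdsResult:
    configuration: np.ndarray
    stress: float
    stress_history: list[float]
    converged: bool


def _config_distances(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def nmds(
    D: DistanceMatrix,
    k: int = 2,
    max_iter: int = 300,
    seed: int = 0,
    tol: float = 1e-7,
) -> NmdsResult:
    """Nonmetric multidimensional scaling (visualization-grade).

    Minimizes Kruskal stress-1 by alternating monotone (isotonic) regression
    of configuration distances on dissimilarity ranks with Guttman-transform
    configuration updates, starting from classical scaling. The recorded
    stress sequence is nonincreasing: the loop stops (and reverts) at the
    first non-improving step.
    """
    n = D.n
    if k >= n:
        raise ValueError("embedding dimension must be smaller than n")
    G = _gower_center(D.values)
    evals, evecs = np.linalg.eigh(G)
    idx = np.argsort(evals)[::-1][:k]
    lam = np.clip(evals[idx], 0.0, None)
    X = evecs[:, idx] * np.sqrt(lam)[None, :]
    if not np.any(lam > 0):  # fully degenerate start: tiny random jitter
        X = stream(seed, "nmds-init").normal(scale=1e-3, size=(n, k))

    ii, jj = np.tril_indices(n, k=-1)
    diss = D.values[ii, jj]
    order = np.argsort(diss, kind="stable")

    def _stress(X: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        d = _config_distances(X)[ii, jj]
        fit = isotonic_regression(d[order])
        dhat = np.empty_like(d)
        dhat[order] = fit.x
        denom = float((d**2).sum())
        if denom == 0:
            return np.inf, d, dhat
        return float(np.sqrt(((d - dhat) ** 2).sum() / denom)), d, dhat

    stress, d, dhat = _stress(X)
    history = [stress]
    converged = False
    for _ in range(max_iter):
        # Guttman transform toward the monotone targets
        W = np.zeros((n, n))
        ratio = np.divide(dhat, d, out=np.zeros_like(dhat), where=d > 0)
        W[ii, jj] = ratio
        W = W + W.T
        B = -W
        np.fill_diagonal(B, W.sum(axis=1))
        X_new = (B @ X) / n
        s_new, d_new, dhat_new = _stress(X_new)
        if s_new >= stress - tol:
            if s_new < stress:  # accept a final negligible improvement
                X, stress = X_new, s_new
                history.append(s_new)
            converged = True
            break
        X, stress, d, dhat = X_new, s_new, d_new, dhat_new
        history.append(stress)
    return NmdsResult(X, stress, history, converged)


# ---------------------------------------------------------------------------
# OLS + AICc ranking
# ---------------------------------------------------------------------------


@dataclass
class OlsResult:
    params: np.ndarray  # intercept first
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    r2: float
    adj_r2: float
    rss: float
    n: int
    n_coef: int  # including the intercept
    term_names: list[str] = field(default_factory=list)

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def slopes(self) -> np.ndarray:
        return self.params[1:]

    def slope(self, name: str) -> float:
        return float(self.params[self.term_names.index(name)])


def ols_fit(y, X, term_names: list[str] | None = None) -> OlsResult:
    """Ordinary least squares with an intercept prepended.

    Parameters
    ----------
    y : array-like, shape (n,)
    X : array-like, shape (n,) or (n, p)
        Predictor column(s), without an intercept.
    term_names : list of str, optional
        Names for the p predictor columns.

    Returns
    -------
    OlsResult
        Coefficients (intercept first), standard errors, two-sided t-test
        p-values, R-squared and adjusted R-squared.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y and X have incompatible shapes")
    A = np.hstack([np.ones((n, 1)), X])
    ncoef = p + 1
    if n <= ncoef - 1:
        raise ValueError("need n > number of predictors")
    if np.linalg.matrix_rank(A) < ncoef:
        raise ValueError("design matrix is rank-deficient")
    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    df_res = n - ncoef
    sigma2 = rss / df_res if df_res > 0 else np.nan
    XtX_inv = np.linalg.inv(A.T @ A)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * sps.t.sf(np.abs(tvals), df_res)
    r2 = 1 - rss / tss if tss > 0 else np.nan
    adj = 1 - (1 - r2) * (n - 1) / df_res if df_res > 0 else np.nan
    names = ["intercept"] + (
        term_names if term_names is not None else [f"x{i}" for i in range(p)]
    )
    return OlsResult(beta, se, tvals, pvals, r2, adj, rss, n, ncoef, names)


@dataclass
class RankedModel:
    label: str
    k: int  # parameter count including residual variance
    aicc: float
    delta_aicc: float
    weight: float
    adj_r2: float


@dataclass
class ModelRank:
    models: list[RankedModel]

    def best(self) -> RankedModel:
        return self.models[0]


def aicc_rank(models: list[tuple[str, OlsResult]], n: int) -> ModelRank:
    """Rank OLS models by small-sample AIC and Akaike weights.

    ``AIC = n ln(RSS/n) + 2k`` with ``k`` counting the regression
    coefficients plus one for the residual variance;
    ``AICc = AIC + 2k(k+1)/(n-k-1)``. Models are returned sorted by AICc
    (best first) with ``delta_aicc`` relative to the best and weights
    ``w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)``.
    """
    if not models:
        raise ValueError("no models to rank")
    rows = []
    for label, fit in models:
        if fit.n != n:
            raise ValueError(f"model {label!r} fit to n={fit.n}, expected {n}")
        k = fit.n_coef + 1
        if n - k - 1 <= 0:
            raise ValueError(f"model {label!r}: n - k - 1 <= 0")
        aic = n * np.log(fit.rss / n) + 2 * k
        aicc = aic + 2 * k * (k + 1) / (n - k - 1)
        rows.append((label, k, aicc, fit.adj_r2))
    best = min(r[2] for r in rows)
    deltas = np.array([r[2] - best for r in rows])
    w = np.exp(-deltas / 2)
    w /= w.sum()
    ranked = sorted(
        (
            RankedModel(lab, k, aicc, aicc - best, wi, adj)
            for (lab, k, aicc, adj), wi in zip(rows, w)
        ),
        key=lambda m: m.aicc,
    )
    return ModelRank(ranked)


# ---------------------------------------------------------------------------
# Welch's t
# ---------------------------------------------------------------------------


@dataclass
class WelchResult:
    t: float
    df: float
    p: float


def welch_t(x1, x2) -> WelchResult:
    """Welch's two-sample t-test (unequal variances), two-sided p."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = x1.size, x2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    v1 = x1.var(ddof=1)
    v2 = x2.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise ValueError("both groups have zero variance")
    a, b = v1 / n1, v2 / n2
    t = (x1.mean() - x2.mean()) / np.sqrt(a + b)
    df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


# ---------------------------------------------------------------------------
# Condition index (PCA)
# ---------------------------------------------------------------------------


@dataclass
class ConditionIndex:
    scores: pd.Series
    loadings: pd.Series
    explained_variance_ratio: float


def condition_index(measurements: pd.DataFrame, anchor: str | None = None) -> ConditionIndex:
    """First-principal-component condition score from body measurements.

    Columns are z-scored; the PC1 score of each individual is returned with
    the sign oriented so the ``anchor`` variable (default: the first column,
    conventionally a fat-depth measure) loads positively — higher score means
    better condition. Constant columns are dropped with a warning.
    """
    if measurements.shape[0] < 2 or measurements.shape[1] < 2:
        raise ValueError("need >= 2 individuals and >= 2 variables")
    if measurements.isna().any().any():
        raise ValueError("missing values: impute or drop before scoring")
    M = measurements.copy()
    sd = M.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant columns: {constant}")
        M = M.drop(columns=constant)
        if M.shape[1] < 2:
            raise ValueError("fewer than 2 non-constant variables remain")
        sd = sd.drop(constant)
    Z = (M - M.mean()) / sd
    U, s, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    load = Vt[0]
    scores = U[:, 0] * s[0]
    anchor_col = anchor if anchor is not None else M.columns[0]
    if anchor_col not in M.columns:
        raise KeyError(f"anchor variable {anchor_col!r} not in measurements")
    if load[M.columns.get_loc(anchor_col)] < 0:
        load = -load
        scores = -scores
    evr = float(s[0] ** 2 / (s**2).sum())
    return ConditionIndex(
        pd.Series(scores, index=M.index, name="condition"),
        pd.Series(load, index=M.columns, name="pc1_loading"),
        evr,
    )
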