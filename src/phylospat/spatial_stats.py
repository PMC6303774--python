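"""Spatially aware correlation and regression on gridded data.

Contains the statistical core of the analysis chain: lattice contiguity
weights, Moran's I with permutation inference, Dutilleul's modified t-test
for spatially autocorrelated correlations, OLS and maximum-likelihood
simultaneous autoregressive (SAR) error models, and AICc / Akaike-weight
multimodel inference over all predictor subsets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import optimize, stats

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "ModifiedTTestResult",
    "OLSFit",
    "SARFit",
    "ModelSelectionTable",
    "build_weights",
    "morans_i",
    "pearson_dutilleul",
    "fit_ols",
    "fit_sar_error",
    "aicc",
    "akaike_weights",
    "variable_importance",
    "all_subsets",
    "significance_stars",
]


# --------------------------------------------------------------------------
# spatial weights


@dataclass
class SpatialWeights:
    """Sparse non-negative spatial weights on a set of cells.

    ``matrix`` has a zero diagonal; if ``row_standardized`` each nonzero row
    sums to one. The binary neighbor structure is symmetric even when the
    row-standardized weights are not. Eigenvalues (of the similar symmetric
    matrix for row-standardized weights) are computed lazily and cached for
    the SAR log-determinant.
    """

    matrix: sp.csr_matrix
    ids: List[str]
    scheme: str = "queen"
    row_standardized: bool = True
    islands: List[str] = field(default_factory=list)
    _eigvals: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def s0(self) -> float:
        return float(self.matrix.sum())

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues of W (via the similar symmetric matrix if W = D^-1 C)."""
        if self._eigvals is None:
            if self.row_standardized:
                # W = D^-1 C is similar to D^-1/2 C D^-1/2 (symmetric)
                deg = self._degrees()
                c = (self.matrix.multiply(deg[:, None])).toarray()
                dinv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
                m = c * dinv_sqrt[:, None] * dinv_sqrt[None, :]
                self._eigvals = np.linalg.eigvalsh(m)
            else:
                self._eigvals = np.linalg.eigvalsh(self.matrix.toarray())
        return self._eigvals

    def _degrees(self) -> np.ndarray:
        if self.row_standardized:
            # recover binary degree: row-standardized entries are 1/deg
            with np.errstate(divide="ignore"):
                first = self.matrix.max(axis=1).toarray().ravel()
            deg = np.where(first > 0, np.round(1.0 / np.maximum(first, 1e-300)), 0.0)
            return deg
        return np.asarray(self.matrix.sum(axis=1)).ravel()


def build_weights(
    cells: pd.DataFrame,
    scheme: str = "queen",
    row_standardize: bool = True,
    cell_size: Optional[float] = None,
) -> SpatialWeights:
    """Contiguity weights for cells on a regular lattice.

    ``cells`` needs columns x, y (cell centers); lattice indices are inferred
    by dividing by ``cell_size`` (the smallest positive coordinate gap when
    not given). Rook neighbors share an edge, queen neighbors an edge or a
    corner. Cells without neighbors are reported as islands; if every cell is
    isolated the weights are unusable and an error is raised.
    """
    if scheme not in ("queen", "rook"):
        raise ValueError("scheme must be 'queen' or 'rook'")
    if len(cells) < 2:
        raise ValueError("need at least 2 cells")
    xy = cells[["x", "y"]].to_numpy(float)
    if cell_size is None:
        gaps = []
        for k in (0, 1):
            u = np.unique(xy[:, k])
            if len(u) > 1:
                gaps.append(np.diff(u).min())
        if not gaps:
            raise ValueError("all cells at one coordinate; cannot infer cell size")
        cell_size = float(min(gaps))
    ij = np.column_stack(
        [
            np.round((xy[:, 0] - xy[:, 0].min()) / cell_size).astype(int),
            np.round((xy[:, 1] - xy[:, 1].min()) / cell_size).astype(int),
        ]
    )
    index = {tuple(p): i for i, p in enumerate(ij)}
    if len(index) != len(ij):
        raise ValueError("duplicate cell coordinates")
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if scheme == "queen":
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    rows, cols = [], []
    for i, (a, b) in enumerate(map(tuple, ij)):
        for da, db in offsets:
            j = index.get((a + da, b + db))
            if j is not None:
                rows.append(i)
                cols.append(j)
    n = len(ij)
    w = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    deg = np.asarray(w.sum(axis=1)).ravel()
    ids = [str(c) for c in cells.index]
    islands = [ids[i] for i in np.flatnonzero(deg == 0)]
    if len(islands) == n:
        raise ValueError("every cell is isolated under this neighbor scheme")
    if row_standardize:
        inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1e-300), 0.0)
        w = sp.diags(inv) @ w
    return SpatialWeights(
        matrix=w.tocsr(),
        ids=ids,
        scheme=scheme,
        row_standardized=row_standardize,
        islands=islands,
    )


# --------------------------------------------------------------------------
# Moran's I


@dataclass
class MoranResult:
    statistic: float
    expected: float
    p_value: float
    n_perm: int


def _moran_stat(z: np.ndarray, w: sp.csr_matrix, s0: float) -> float:
    return float(len(z) / s0 * (z @ (w @ z)) / (z @ z))


def morans_i(
    values: Sequence[float],
    w: SpatialWeights,
    n_perm: int = 999,
    seed: int = 0,
) -> MoranResult:
    """Global Moran's I with a two-sided permutation p-value.

    I = (n/S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z the centered values;
    the permutation null shuffles cell labels. Expectation under the null is
    -1/(n-1).
    """
    z = np.asarray(values, float)
    if not np.isfinite(z).all():
        raise ValueError("values must be finite")
    if np.ptp(z) == 0:
        raise ValueError("Moran's I is undefined for constant input")
    z = z - z.mean()
    s0 = w.s0
    obs = _moran_stat(z, w.matrix, s0)
    expected = -1.0 / (w.n - 1)
    if n_perm < 1:
        return MoranResult(obs, expected, np.nan, 0)
    rng = np.random.default_rng(seed)
    perms = np.empty(n_perm)
    for b in range(n_perm):
        perms[b] = _moran_stat(rng.permutation(z), w.matrix, s0)
    # two-sided: fold the permutation distribution around its expectation
    dev = abs(obs - expected)
    p = (1.0 + np.sum(np.abs(perms - expected) >= dev - 1e-15)) / (n_perm + 1.0)
    return MoranResult(obs, expected, float(min(p, 1.0)), n_perm)


# --------------------------------------------------------------------------
# Dutilleul's modified t-test


@dataclass
class ModifiedTTestResult:
    r: float
    effective_sample_size: float
    t: float
    p_value: float
    n: int
    n_classes: int
    powerless: bool = False


def pearson_dutilleul(
    x: Sequence[float],
    y: Sequence[float],
    coords: np.ndarray,
    n_distance_classes: int = 12,
) -> ModifiedTTestResult:
    """Pearson correlation with Dutilleul's spatially corrected t-test.

    The Pearson r is the usual one; its significance is referred to a
    Student-t with M-hat - 2 degrees of freedom, where the effective sample
    size M-hat is estimated from the spatial autocovariances of x and y:

        M-hat = 1 + tr(B Sx) tr(B Sy) / tr(B Sx B Sy)

    with B the centering projector and Sx, Sy block-constant covariance
    estimates over equal-width distance classes (class 0 = the diagonal).
    Under iid data the correction vanishes (M-hat -> n); under strong
    autocorrelation M-hat shrinks and the test loses the classical test's
    anticonservative bias. If M-hat <= 2 the test is powerless and p = 1 is
    reported with a flag.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    coords = np.asarray(coords, float)
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all() and np.isfinite(coords).all()):
        raise ValueError("inputs must be finite")
    r = float(np.corrcoef(x, y)[0, 1])

    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    dmax = d.max()
    # class 0 is the diagonal (distance 0); off-diagonal distances get
    # n_distance_classes equal-width bins over (0, dmax]
    edges = np.linspace(0.0, dmax, n_distance_classes + 1)
    off = ~np.eye(n, dtype=bool)
    klass = np.zeros((n, n), dtype=int)
    klass[off] = np.clip(np.searchsorted(edges[1:], d[off], side="left") + 1, 1, n_distance_classes)

    wx = x - x.mean()
    wy = y - y.mean()
    sx = np.zeros((n, n))
    sy = np.zeros((n, n))
    px = np.outer(wx, wx)
    py = np.outer(wy, wy)
    for h in range(n_distance_classes + 1):
        mask = klass == h
        cnt = mask.sum()
        if cnt == 0:
            continue
        sx[mask] = px[mask].mean()
        sy[mask] = py[mask].mean()

    def center(m: np.ndarray) -> np.ndarray:
        m = m - m.mean(axis=0, keepdims=True)
        return m - m.mean(axis=1, keepdims=True)

    bsx = center(sx)
    bsy = center(sy)
    tr_x = np.trace(bsx)
    tr_y = np.trace(bsy)
    tr_xy = float((bsx * bsy.T).sum())  # tr(B Sx B Sy)
    powerless = False
    if tr_xy <= 0 or tr_x <= 0 or tr_y <= 0:
        m_hat = float(n)
    else:
        m_hat = 1.0 + tr_x * tr_y / tr_xy
        m_hat = min(m_hat, float(n))
    if m_hat <= 2.0:
        return ModifiedTTestResult(r, m_hat, np.nan, 1.0, n, n_distance_classes, True)
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt((m_hat - 2.0) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=m_hat - 2.0))
    return ModifiedTTestResult(r, m_hat, float(t), p, n, n_distance_classes, powerless)


# --------------------------------------------------------------------------
# regression fits


@dataclass
class OLSFit:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    loglik: float
    aicc: float
    r2: float
    residuals: np.ndarray
    fitted: np.ndarray
    n: int
    k: int
    terms: Tuple[str, ...]
    kind: str = "ols"


@dataclass
class SARFit:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    lam: float
    loglik: float
    aicc: float
    pseudo_r2: float
    r2_fitted_obs: float
    residual_moran: Optional[MoranResult]
    residuals: np.ndarray
    fitted: np.ndarray
    n: int
    k: int
    terms: Tuple[str, ...]
    lambda_at_boundary: bool = False
    kind: str = "sar_error"


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion.

    AICc = -2 logL + 2k + 2k(k+1)/(n - k - 1); requires n > k + 1.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def _design(X: pd.DataFrame) -> Tuple[np.ndarray, List[str]]:
    names = ["intercept"] + list(X.columns)
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify offending columns via QR diagonal
        _, rdiag = np.linalg.qr(mat)
        bad = [names[i] for i in np.flatnonzero(np.abs(np.diag(rdiag)) < 1e-10)]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    return mat, names


def _gaussian_loglik(resid: np.ndarray) -> float:
    n = len(resid)
    s2 = float(resid @ resid) / n  # MLE variance
    return -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)


def fit_ols(response: Sequence[float], design: pd.DataFrame) -> OLSFit:
    """Ordinary least squares with Gaussian likelihood at the MLE variance.

    The fit itself is delegated to statsmodels; AICc counts the coefficients
    plus the error variance.
    """
    import statsmodels.api as sm

    y = np.asarray(response, float)
    mat, names = _design(design)
    res = sm.OLS(y, mat).fit()
    k = mat.shape[1] + 1  # + sigma^2
    fit_aicc = aicc(float(res.llf), k, len(y))
    params = pd.Series(res.params, index=names)
    return OLSFit(
        params=params,
        bse=pd.Series(res.bse, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        loglik=float(res.llf),
        aicc=fit_aicc,
        r2=float(res.rsquared) if mat.shape[1] > 1 else 0.0,
        residuals=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
        n=len(y),
        k=k,
        terms=tuple(design.columns),
    )


def fit_sar_error(
    response: Sequence[float],
    design: pd.DataFrame,
    w: SpatialWeights,
    lam: Optional[float] = None,
    moran_n_perm: int = 999,
    moran_seed: int = 0,
) -> SARFit:
    """Maximum-likelihood simultaneous autoregressive error model.

    Model: y = X beta + u, u = lambda W u + eps, eps ~ iid N(0, sigma^2).
    lambda is estimated by profiling the concentrated log-likelihood

        LL(lambda) = log|I - lambda W| - (n/2) (log(2 pi sigma^2(lambda)) + 1)

    over (1/e_min, 1/e_max) using the eigenvalues of W for the
    log-determinant; beta and sigma^2 follow by GLS at lambda-hat. The
    reported pseudo-r^2 is Nagelkerke's 1 - exp((2/n)(LL_0 - LL)) against the
    intercept-only OLS null, and the residual Moran's I is computed on the
    spatially filtered residuals eps-hat = (I - lambda W)(y - X beta).

    Passing ``lam`` fixes lambda instead of estimating it (lam=0 reproduces
    the OLS likelihood exactly).
    """
    y = np.asarray(response, float)
    mat, names = _design(design)
    n = len(y)
    eig = w.eigenvalues()
    lo = 1.0 / eig.min() + 1e-6 if eig.min() < 0 else -0.999999
    hi = 1.0 / eig.max() - 1e-6

    wy = w.matrix @ y
    wx = w.matrix @ mat

    def concentrated(lmb: float) -> Tuple[float, np.ndarray, np.ndarray]:
        ay = y - lmb * wy
        ax = mat - lmb * wx
        beta, *_ = np.linalg.lstsq(ax, ay, rcond=None)
        resid = ay - ax @ beta
        logdet = float(np.log1p(-lmb * eig).sum())
        return logdet + _gaussian_loglik(resid), beta, resid

    if lam is None:
        res = optimize.minimize_scalar(
            lambda l: -concentrated(l)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        if not res.success:
            raise RuntimeError(f"lambda search failed: {res.message}")
        lam_hat = float(res.x)
    else:
        lam_hat = float(lam)
    at_boundary = lam is None and (lam_hat - lo < 1e-4 or hi - lam_hat < 1e-4)

    loglik, beta, eps = concentrated(lam_hat)
    ax = mat - lam_hat * wx
    s2 = float(eps @ eps) / n
    cov = s2 * np.linalg.inv(ax.T @ ax)
    bse = np.sqrt(np.diag(cov))
    zval = beta / bse
    pvals = 2.0 * stats.norm.sf(np.abs(zval))

    k = mat.shape[1] + 2  # + sigma^2 + lambda
    fit_aicc = aicc(loglik, k, n)

    ll_null = _gaussian_loglik(y - y.mean())
    pseudo = 1.0 - np.exp((2.0 / n) * (ll_null - loglik))
    fitted = mat @ beta
    u = y - fitted
    denom = np.std(fitted) * np.std(y)
    r2_fo = float(np.corrcoef(fitted, y)[0, 1] ** 2) if denom > 0 else 0.0

    moran = None
    if moran_n_perm > 0 and np.ptp(eps) > 0:
        moran = morans_i(eps, w, n_perm=moran_n_perm, seed=moran_seed)

    return SARFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        pvalues=pd.Series(pvals, index=names),
        lam=lam_hat,
        loglik=float(loglik),
        aicc=fit_aicc,
        pseudo_r2=float(np.clip(pseudo, 0.0, 1.0)),
        r2_fitted_obs=r2_fo,
        residual_moran=moran,
        residuals=u,
        fitted=fitted,
        n=n,
        k=k,
        terms=tuple(design.columns),
        lambda_at_boundary=at_boundary,
    )


# --------------------------------------------------------------------------
# multimodel inference


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """w_i = exp(-delta_i / 2) / sum_j exp(-delta_j / 2)."""
    a = np.asarray(aicc_values, float)
    if a.size == 0:
        raise ValueError("need at least one model")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class ModelSelectionTable:
    """All-subsets model comparison ranked by AICc."""

    table: pd.DataFrame  # one row per model: terms, k, loglik, aicc, delta, weight
    importance: pd.Series  # per-term summed Akaike weights
    fits: List  # fit objects aligned with table rows (AICc order)
    kind: str

    @property
    def best(self):
        return self.fits[0]


def variable_importance(table: pd.DataFrame, terms: Sequence[str]) -> pd.Series:
    """Summed Akaike weights of the models containing each term."""
    imp = {}
    for term in terms:
        imp[term] = float(
            table.loc[[term in t for t in table["terms"]], "weight"].sum()
        )
    return pd.Series(imp, name="importance")


def _candidate_subsets(
    terms: Sequence[str], marginality: Sequence[Tuple[str, str]]
) -> List[Tuple[str, ...]]:
    """All term subsets respecting marginality (quadratic implies linear)."""
    requires = dict(marginality)  # higher-order term -> required lower-order term
    out = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            cs = set(combo)
            if all(req in cs for t, req in requires.items() if t in cs):
                out.append(combo)
    return out


def all_subsets(
    response: Sequence[float],
    design: pd.DataFrame,
    marginality: Sequence[Tuple[str, str]] = (),
    model_kind: str = "ols",
    w: Optional[SpatialWeights] = None,
    moran_n_perm: int = 0,
    moran_seed: int = 0,
) -> ModelSelectionTable:
    """Fit every admissible predictor subset and rank by AICc.

    ``marginality`` pairs (quadratic_term, linear_term) restrict the subset
    lattice so a quadratic never enters without its linear term. Models are
    ranked by AICc; Akaike weights are normalized over the full candidate
    set, and per-term importance sums the weights of the models containing
    the term. Individual fit failures are recorded and skipped; only a fully
    failed set is fatal.
    """
    terms = list(design.columns)
    if len(terms) > 10:
        raise ValueError("all-subsets search limited to 10 terms")
    if model_kind == "sar" and w is None:
        raise ValueError("SAR model selection needs spatial weights")
    subsets = _candidate_subsets(terms, marginality)
    rows, fits, failures = [], [], {}
    for combo in subsets:
        sub = design[list(combo)]
        try:
            if model_kind == "sar":
                fit = fit_sar_error(
                    response, sub, w, moran_n_perm=moran_n_perm, moran_seed=moran_seed
                )
            else:
                fit = fit_ols(response, sub)
        except Exception as exc:  # recorded, not fatal
            failures[combo] = str(exc)
            continue
        rows.append({"terms": combo, "k": fit.k, "loglik": fit.loglik, "aicc": fit.aicc})
        fits.append(fit)
    if not rows:
        raise RuntimeError(f"every candidate model failed: {failures}")
    table = pd.DataFrame(rows)
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    table["weight"] = akaike_weights(table["aicc"].to_numpy())
    order = np.argsort(table["aicc"].to_numpy(), kind="stable")
    table = table.iloc[order].reset_index(drop=True)
    fits = [fits[i] for i in order]
    imp = variable_importance(table, terms)
    table.attrs["failures"] = failures
    return ModelSelectionTable(table=table, importance=imp, fits=fits, kind=model_kind)


def significance_stars(p: float) -> str:
    """Three-level star coding with 'ns' above 0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
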