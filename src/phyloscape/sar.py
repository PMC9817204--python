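"""Spatial autocorrelation diagnostics and spatial-error regression.

The regression stage follows the classic comparative-biogeography recipe:
diagnose residual spatial autocorrelation with a Moran's I correlogram at
fixed distance increments, take the first nonsignificant distance class
as the neighborhood radius, build a row-standardized distance-band
weights matrix W, and fit simultaneous autoregressive ERROR models

    y = X beta + u,      u = lambda W u + eps,   eps ~ N(0, sigma^2 I)

by maximum likelihood (concentrated over lambda, log-determinant via the
eigenvalues of W).  Model selection is exhaustive over predictor subsets,
ranked by AIC, with Nagelkerke's pseudo-R^2 against the non-spatial
intercept-only model as the goodness-of-fit summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

__all__ = [
    "morans_i",
    "correlogram",
    "neighbor_threshold",
    "SpatialWeights",
    "build_weights",
    "SarFit",
    "fit_sar_error",
    "nagelkerke_r2",
    "ModelRanking",
    "all_subsets_selection",
]


# ---------------------------------------------------------------------------
# Moran's I and the correlogram


def morans_i(values: np.ndarray, weights) -> dict:
    """Global Moran's I with expectation, normal-approximation variance
    and two-sided p-value.

    ``weights`` may be a :class:`SpatialWeights` (its row-standardized
    matrix is used) or any (n, n) array / sparse matrix with zero
    diagonal.  Constant inputs are an error: I is undefined.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 cells")
    if isinstance(weights, SpatialWeights):
        W = weights.W
    else:
        W = sparse.csr_matrix(weights) if not sparse.issparse(weights) else weights
    if W.shape != (n, n):
        raise ValueError("weights shape does not match values")
    z = x - x.mean()
    den = float(z @ z)
    if den == 0:
        raise ValueError("values are constant; Moran's I is undefined")
    S0 = float(W.sum())
    if S0 == 0:
        raise ValueError("weights are empty")
    num = float(z @ (W @ z))
    I = (n / S0) * num / den

    Wt = W.T.tocsr()
    S1 = 0.5 * float(((W + Wt).multiply(W + Wt)).sum())
    rs = np.asarray(W.sum(axis=1)).ravel()
    cs = np.asarray(W.sum(axis=0)).ravel()
    S2 = float(((rs + cs) ** 2).sum())
    EI = -1.0 / (n - 1)
    var = (n**2 * S1 - n * S2 + 3 * S0**2) / (S0**2 * (n**2 - 1)) - EI**2
    var = max(var, 0.0)
    if var > 0:
        zscore = (I - EI) / np.sqrt(var)
        p = 2 * norm.sf(abs(zscore))
    else:
        zscore, p = np.nan, np.nan
    return {"I": I, "expected": EI, "variance": var, "z": zscore, "p": p}


@dataclass
class Correlogram:
    """Moran's I in contiguous distance classes ``(lo, hi]`` from 0."""

    table: pd.DataFrame  # lower, upper, n_pairs, I, expected, variance, p, flagged
    increment: float

    def __getitem__(self, col):
        return self.table[col]


def correlogram(
    values: np.ndarray,
    coords: np.ndarray,
    increment: float = 0.52,
    max_distance: float | None = None,
) -> Correlogram:
    """Moran correlogram: binary pair weights per distance class.

    Classes are ``(k*increment, (k+1)*increment]`` covering ``[0,
    max_distance]`` (default: the maximum pairwise distance).  Classes
    with fewer than 2 pairs are flagged and carry NaN statistics rather
    than being dropped."""
    x = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = x.size
    D = squareform(pdist(coords))
    if max_distance is None:
        max_distance = float(D.max())
    n_classes = max(1, int(np.ceil(max_distance / increment - 1e-12)))
    rows = []
    for k in range(n_classes):
        lo, hi = k * increment, (k + 1) * increment
        mask = (D > lo) & (D <= hi)
        n_pairs = int(mask.sum()) // 2
        if n_pairs < 2:
            rows.append(
                {"lower": lo, "upper": hi, "n_pairs": n_pairs, "I": np.nan,
                 "expected": -1.0 / (n - 1), "variance": np.nan, "p": np.nan,
                 "flagged": True}
            )
            continue
        res = morans_i(x, mask.astype(float))
        rows.append(
            {"lower": lo, "upper": hi, "n_pairs": n_pairs, "I": res["I"],
             "expected": res["expected"], "variance": res["variance"],
             "p": res["p"], "flagged": False}
        )
    return Correlogram(pd.DataFrame(rows), increment)


def neighbor_threshold(corr: Correlogram, alpha: float = 0.05) -> float:
    """Neighborhood radius rule: the upper bound of the first distance
    class (scanning outward from zero) whose Moran's I is nonsignificant
    (p >= alpha).  Flagged classes (too few pairs) count as
    nonsignificant.  If every class is significant the maximum distance
    is returned with a warning."""
    t = corr.table
    for _, row in t.iterrows():
        if row["flagged"] or row["p"] >= alpha:
            return float(row["upper"])
    warnings.warn(
        "autocorrelation significant in every distance class; "
        "using the maximum distance as neighborhood radius",
        stacklevel=2,
    )
    return float(t["upper"].iloc[-1])


# ---------------------------------------------------------------------------
# spatial weights


@dataclass
class SpatialWeights:
    """Distance-band neighbors with row-standardized ("W") weights."""

    A: sparse.csr_matrix  # symmetric binary adjacency, zero diagonal
    W: sparse.csr_matrix  # row-standardized
    d_max: float
    ids: tuple | None = None
    _eigs: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def cardinalities(self) -> np.ndarray:
        return np.asarray(self.A.sum(axis=1)).ravel().astype(int)

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues of the row-standardized W.  W = D^-1 A with A
        symmetric, so W is similar to the symmetric D^-1/2 A D^-1/2 and the
        spectrum is real; computed densely and cached."""
        if self._eigs is None:
            from scipy.linalg import eigh

            d = self.cardinalities.astype(float)
            dinv = 1.0 / np.sqrt(d)
            B = self.A.toarray() * np.outer(dinv, dinv)
            self._eigs = eigh(B, eigvals_only=True)
        return self._eigs


def build_weights(
    coords: np.ndarray, d_max: float, ids=None, drop_islands: bool = False
) -> SpatialWeights:
    """Neighbors = all cells within Euclidean distance ``d_max`` of a
    centroid (self excluded); weights row-standardized to sum to 1.

    Cells with no neighbor ("islands") are a hard error listing their
    indices/ids; pass ``drop_islands=True`` to silently restrict the
    weights (and the returned ``ids``) to connected cells — callers must
    then subset their data to ``weights.ids``."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    tree = cKDTree(coords)
    pairs = np.array(sorted(tree.query_pairs(r=d_max)), dtype=np.intp)
    if pairs.size:
        i = np.concatenate([pairs[:, 0], pairs[:, 1]])
        j = np.concatenate([pairs[:, 1], pairs[:, 0]])
        A = sparse.csr_matrix((np.ones(i.size), (i, j)), shape=(n, n))
    else:
        A = sparse.csr_matrix((n, n))
    deg = np.asarray(A.sum(axis=1)).ravel()
    islands = np.flatnonzero(deg == 0)
    if islands.size:
        labels = [ids[k] for k in islands] if ids is not None else islands.tolist()
        if not drop_islands:
            raise ValueError(
                f"{islands.size} cells have no neighbor within d_max={d_max}: "
                f"{labels[:20]}; raise d_max or pass drop_islands=True"
            )
        keep = np.flatnonzero(deg > 0)
        sub_ids = tuple(ids[k] for k in keep) if ids is not None else tuple(keep)
        return build_weights(coords[keep], d_max, ids=sub_ids)
    Dinv = sparse.diags(1.0 / deg)
    W = (Dinv @ A).tocsr()
    return SpatialWeights(A.tocsr(), W, d_max,
                          tuple(ids) if ids is not None else None)


# ---------------------------------------------------------------------------
# SAR-error maximum likelihood


@dataclass
class SarFit:
    """A fitted spatial-error model."""

    response: str
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    lam: float
    lam_se: float
    sigma2: float
    loglik: float
    aic: float
    n: int
    pseudo_r2: float | None = None

    @property
    def k(self) -> int:
        # beta's plus lambda and sigma^2
        return len(self.beta) + 2

    def coefficients(self) -> pd.DataFrame:
        stars = [
            "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
            for p in self.pvalues
        ]
        return pd.DataFrame(
            {"estimate": self.beta, "se": self.se, "z": self.zvalues,
             "p": self.pvalues, "sig": stars},
            index=self.names,
        )


def _sar_profile_loglik(lam, y, X, Wy, WX, eigs, n):
    ys = y - lam * Wy
    Xs = X - lam * WX
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    e = ys - Xs @ beta
    sigma2 = float(e @ e) / n
    if sigma2 <= 0 or not np.isfinite(sigma2):
        return -np.inf, beta, sigma2
    logdet = float(np.log(1.0 - lam * eigs).sum())
    ll = logdet - 0.5 * n * np.log(2 * np.pi * sigma2) - 0.5 * n
    return ll, beta, sigma2


def fit_sar_error(
    y: np.ndarray,
    X: np.ndarray,
    weights: SpatialWeights,
    names: list[str] | None = None,
    response: str = "y",
    fixed_lam: float | None = None,
) -> SarFit:
    """Maximum-likelihood spatial-error fit.

    The likelihood is concentrated: for trial lambda the data are
    spatially filtered ((I - lambda W) applied to y and X), beta and
    sigma^2 follow by least squares, and

        logL = ln|I - lambda W| - (n/2) ln(2 pi sigma^2) - n/2

    with the log-determinant from the (real) eigenvalues of W.  lambda is
    optimized by bounded scalar search inside the interval defined by the
    reciprocal extreme eigenvalues.  Coefficient standard errors are the
    GLS errors at the optimum; the lambda standard error comes from the
    numerical curvature of the profile likelihood.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = y.size
    if X.ndim != 2 or X.shape[0] != n:
        raise ValueError("X must be (n, k)")
    if weights.n != n:
        raise ValueError("weights do not match data size")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix X'X")
    names = names or [f"x{j}" for j in range(X.shape[1])]

    eigs = weights.eigenvalues()
    lo = 1.0 / eigs.min() if eigs.min() < 0 else -0.999
    hi = 1.0 / eigs.max() if eigs.max() > 0 else 0.999
    eps = 1e-6 * (hi - lo)
    Wy = weights.W @ y
    WX = weights.W @ X

    def neg_ll(lam):
        ll, *_ = _sar_profile_loglik(lam, y, X, Wy, WX, eigs, n)
        return -ll

    if fixed_lam is not None:
        lam = float(fixed_lam)  # e.g. 0.0 reduces the fit to OLS exactly
    else:
        res = minimize_scalar(neg_ll, bounds=(lo + eps, hi - eps),
                              method="bounded", options={"xatol": 1e-8})
        lam = float(res.x)
    ll, beta, sigma2 = _sar_profile_loglik(lam, y, X, Wy, WX, eigs, n)
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite SAR likelihood at the optimum")

    Xs = X - lam * WX
    XtX = Xs.T @ Xs
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    zvals = beta / se
    pvals = 2 * norm.sf(np.abs(zvals))

    h = max(1e-5, 1e-4 * (hi - lo))
    h = min(h, (lam - lo) / 2 if lam > lo else h, (hi - lam) / 2 if lam < hi else h)
    d2 = (neg_ll(lam + h) - 2 * neg_ll(lam) + neg_ll(lam - h)) / h**2
    lam_se = float(1.0 / np.sqrt(d2)) if d2 > 0 else np.nan

    k = X.shape[1] + 2
    aic = -2 * ll + 2 * k
    return SarFit(response, list(names), beta, se, zvals, pvals, lam, lam_se,
                  sigma2, ll, aic, n)


def _ols_loglik(y: np.ndarray, X: np.ndarray | None = None) -> float:
    """Gaussian ML log-likelihood of an OLS fit (intercept-only when X is
    None); sigma^2 is the ML (1/n) estimate."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if X is None:
        resid = y - y.mean()
    else:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
    sigma2 = float(resid @ resid) / n
    return -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)


def nagelkerke_r2(loglik_model: float, loglik_null: float, n: int) -> float:
    """Nagelkerke pseudo-R^2: the Cox-Snell likelihood-ratio R^2
    normalized by its maximum attainable value so the range is [0, 1]."""
    r2_cs = 1.0 - np.exp(-2.0 / n * (loglik_model - loglik_null))
    r2_max = 1.0 - np.exp(2.0 / n * loglik_null)
    if r2_max <= 0:
        return float(np.clip(r2_cs, 0.0, 1.0))
    return float(np.clip(r2_cs / r2_max, 0.0, 1.0))


# ---------------------------------------------------------------------------
# all-subsets model selection


@dataclass
class ModelRanking:
    """AIC-ordered spatial-error fits over predictor subsets."""

    table: pd.DataFrame  # subset, k, aic, delta_aic, loglik, pseudo_r2, lambda
    fits: list[SarFit]

    @property
    def best(self) -> SarFit:
        return self.fits[0]


def all_subsets_selection(
    y: np.ndarray,
    candidates: pd.DataFrame,
    weights: SpatialWeights,
    extra_fixed: pd.Series | None = None,
    response: str = "y",
) -> ModelRanking:
    """Fit a spatial-error model for EVERY subset of the candidate
    predictors (including the empty subset) and rank by AIC.

    ``extra_fixed`` (e.g. the null-model expected diversity) is included
    in every model when supplied.  Every design contains an intercept.
    Pseudo-R^2 is computed against the non-spatial intercept-only fit.
    A hard ceiling of 15 candidates (2^15 fits) applies.
    """
    cols = list(candidates.columns)
    if len(cols) > 15:
        raise ValueError("more than 15 candidate predictors (2^15 fit ceiling)")
    y = np.asarray(y, dtype=float)
    n = y.size
    ll_null = _ols_loglik(y)
    fixed_mat = []
    fixed_names = []
    if extra_fixed is not None:
        fixed_mat.append(np.asarray(extra_fixed, dtype=float))
        fixed_names.append(getattr(extra_fixed, "name", None) or "fixed")

    fits = []
    rows = []
    for mask in range(2 ** len(cols)):
        subset = [cols[j] for j in range(len(cols)) if mask >> j & 1]
        X = np.column_stack(
            [np.ones(n)] + fixed_mat + [candidates[c].to_numpy(float) for c in subset]
        )
        names = ["(intercept)"] + fixed_names + subset
        fit = fit_sar_error(y, X, weights, names=names, response=response)
        fit.pseudo_r2 = nagelkerke_r2(fit.loglik, ll_null, n)
        fits.append(fit)
        rows.append(
            {"subset": "+".join(subset) if subset else "(intercept)",
             "k": fit.k, "aic": fit.aic, "loglik": fit.loglik,
             "pseudo_r2": fit.pseudo_r2, "lambda": fit.lam}
        )
    order = np.argsort([r["aic"] for r in rows], kind="stable")
    table = pd.DataFrame([rows[i] for i in order]).reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return ModelRanking(table, [fits[i] for i in order])
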