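"""Linear mixed-model baselines: ridge-regression BLUP and GRM-based BLUP.

Both fit the additive model

    y = 1 mu + g + e,    e ~ N(0, sigma2_e I)

where the genetic values are either ``g = Z u`` with i.i.d. marker effects
``u ~ N(0, sigma2_u I)`` (rrBLUP) or ``g ~ N(0, sigma2_g K)`` with a genomic
relationship matrix K (gBLUP). The two are the same model when
``K = Z Z' / c`` with matched scaling, which the tests exploit as a
cross-implementation oracle.

Variance components are estimated by REML on the spectral decomposition of
the covariance kernel: with ``K = U diag(lambda) U'`` the restricted
log-likelihood is a cheap 1D function of the noise-to-genetic variance ratio
``delta = sigma2_e / sigma2_u``, profiled over the intercept and the genetic
variance, and maximised by a log-grid scan refined with bounded Brent.

The genomic relationship matrix follows VanRaden's first method:
``K = W W' / (2 sum_j p_j (1 - p_j))`` with ``W`` the dosage matrix centred
by twice the allele frequencies.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .io import Coding, RawGenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "DosageMatrix",
    "MixedModelFit",
    "ModelKind",
    "to_dosage",
    "rrblup_fit",
    "grm",
    "gblup_fit",
    "RRBLUPRegressor",
    "GBLUPRegressor",
]


class ModelKind(str, enum.Enum):
    RRBLUP = "RRBLUP"
    GBLUP = "GBLUP"


@dataclass
class DosageMatrix:
    """Accessions x markers alternate-allele dosages in [0, 2], fully imputed."""

    Z: np.ndarray
    accessions: list[str]
    marker_ids: list[str]
    n_imputed: int = 0

    def __post_init__(self) -> None:
        if np.isnan(self.Z).any():
            raise ValueError("dosage matrix contains missing values after imputation")
        if self.Z.size and (self.Z.min() < 0 or self.Z.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")


def _dosage_from_call(call) -> float:
    from .encoding import _parse_diploid  # shared GT-string parser

    alleles = _parse_diploid(call)
    if alleles is None:
        return np.nan
    a, b = alleles
    if a > 1 or b > 1:  # no slot for extra alternate alleles
        return np.nan
    return float(a + b)


def to_dosage(table: RawGenotypeTable) -> DosageMatrix:
    """Convert any genotype table to alternate-allele dosages.

    Phased/unphased calls: hom-ref 0, het 1, hom-alt 2. Integer codes map
    relative to the ``1 = reference (1/1)`` convention: 1 -> 0, 0 -> 1,
    -1 -> 2. Missing cells are imputed with the per-marker mean (columns
    with no observed call fall back to 0); monomorphic markers are retained.
    """
    raw = table.calls.to_numpy()
    if table.coding is Coding.INTEGER_CODED:
        codes = raw.astype(float)
        Z = np.where(np.isnan(codes), np.nan, 1.0 - codes)  # 1->0, 0->1, -1->2
    else:
        flat = raw.astype(str).ravel()
        uniq, inv = np.unique(flat, return_inverse=True)
        lut = np.asarray([_dosage_from_call(c) for c in uniq], dtype=float)
        Z = lut[inv].reshape(raw.shape)
    n_imputed = int(np.isnan(Z).sum())
    if n_imputed:
        col_mean = np.nanmean(
            np.where(np.isnan(Z), np.nan, Z), axis=0,
        )
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        nan_r, nan_c = np.where(np.isnan(Z))
        Z[nan_r, nan_c] = col_mean[nan_c]
        logger.info("to_dosage: mean-imputed %d missing cell(s)", n_imputed)
    return DosageMatrix(
        Z=Z,
        accessions=list(table.accessions),
        marker_ids=list(table.marker_ids),
        n_imputed=n_imputed,
    )


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

def _reml_delta(K: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """REML estimates (delta, sigma2_u, mu) for y = 1 mu + g + e, g ~ N(0, s2u K).

    delta = sigma2_e / sigma2_u is found by maximising the restricted
    likelihood on the eigenbasis of K: a log10 grid scan over
    [1e-6, 1e6] x trace(K)/n followed by bounded Brent refinement around the
    grid optimum. Scaling the search range by trace(K)/n makes the estimate
    exactly invariant to a rescaling K -> K/c (with delta -> delta/c), so
    rrBLUP on ZZ' and gBLUP on ZZ'/c give identical predictions.
    """
    n = len(y)
    lam, U = np.linalg.eigh((K + K.T) / 2.0)
    lam = np.maximum(lam, 0.0)
    yt = U.T @ y
    xt = U.T @ np.ones(n)
    scale = float(lam.sum()) / n  # trace(K)/n
    if scale <= 0:
        raise ValueError("K has zero trace; no genetic variance is representable")

    def neg_restricted_ll(log10_ratio: float) -> float:
        delta = scale * 10.0**log10_ratio
        w = lam + delta
        xtw = xt / w
        xwx = float(xtw @ xt)
        beta = float(xtw @ yt) / xwx
        r = yt - xt * beta
        rss = float((r * r / w).sum())
        s2 = rss / (n - 1)
        return 0.5 * (
            (n - 1) * np.log(s2) + np.log(w).sum() + np.log(xwx) + (n - 1)
        )

    grid = np.linspace(-6.0, 6.0, 121)
    vals = [neg_restricted_ll(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        neg_restricted_ll, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    delta = float(scale * 10.0**res.x)
    w = lam + delta
    xtw = xt / w
    beta = float(xtw @ yt) / float(xtw @ xt)
    r = yt - xt * beta
    sigma2_u = float((r * r / w).sum()) / (n - 1)
    return delta, sigma2_u, beta


@dataclass
class MixedModelFit:
    """A fitted rrBLUP or gBLUP model, ready to predict new individuals."""

    model_kind: ModelKind
    mu: float
    sigma2_u: float
    sigma2_e: float
    lam: float  # sigma2_e / sigma2_u
    effects: np.ndarray  # marker effects (rrBLUP) or GEBVs (gBLUP)
    h2: float  # genetic fraction of phenotypic variance on the kernel scale
    _alpha: np.ndarray | None = None  # (K_train + lam I)^-1 (y - mu)
    _Z_train: np.ndarray | None = None

    def predict(self, Z_or_Kcross: np.ndarray) -> np.ndarray:
        """Predict phenotypes: rrBLUP takes new dosages, gBLUP a K cross-block."""
        M = np.asarray(Z_or_Kcross, dtype=float)
        if self.model_kind is ModelKind.RRBLUP:
            return self.mu + M @ self.effects
        return self.mu + M @ self._alpha


def rrblup_fit(
    Z: DosageMatrix | np.ndarray, y: np.ndarray, lam: float | None = None
) -> MixedModelFit:
    """Fit the ridge mixed model y = 1 mu + Z u + e with u ~ N(0, sigma2_u I).

    Variance components come from REML on the spectrum of ZZ' unless ``lam``
    (the ridge parameter sigma2_e/sigma2_u) is supplied directly. Marker
    effects solve the ridge system ``u = Z'(ZZ' + lam I)^-1 (y - mu)``.
    """
    Zm = Z.Z if isinstance(Z, DosageMatrix) else np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = Zm.shape
    if len(y) != n:
        raise ValueError(f"len(y)={len(y)} does not match {n} accessions")
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant; no genetic variance to estimate")
    K = Zm @ Zm.T
    if lam is None:
        delta, sigma2_u, mu = _reml_delta(K, y)
    else:
        delta = float(lam)
        ones = np.ones(n)
        V = K + delta * np.eye(n)
        Vinv_y = np.linalg.solve(V, y)
        Vinv_1 = np.linalg.solve(V, ones)
        mu = float(ones @ Vinv_y) / float(ones @ Vinv_1)
        sigma2_u = float("nan")
    alpha = np.linalg.solve(K + delta * np.eye(n), y - mu)
    u = Zm.T @ alpha
    # genetic variance in this sample: sigma2_u times the sum of marker variances
    genic = float(Zm.var(axis=0).sum())
    sigma2_e = delta * sigma2_u if np.isfinite(sigma2_u) else float("nan")
    h2 = (
        sigma2_u * genic / (sigma2_u * genic + sigma2_e)
        if np.isfinite(sigma2_u)
        else float("nan")
    )
    return MixedModelFit(
        model_kind=ModelKind.RRBLUP,
        mu=mu,
        sigma2_u=sigma2_u,
        sigma2_e=sigma2_e,
        lam=delta,
        effects=u,
        h2=h2,
    )


def grm(Z: DosageMatrix | np.ndarray) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    Columns are centred by twice the allele frequency ``p_j`` (half the
    column dosage mean) and the cross-product is scaled by
    ``2 sum_j p_j (1 - p_j)``.
    """
    Zm = Z.Z if isinstance(Z, DosageMatrix) else np.asarray(Z, dtype=float)
    if Zm.shape[0] < 2:
        raise ValueError("GRM needs at least 2 accessions")
    p = Zm.mean(axis=0) / 2.0
    denom = 2.0 * float((p * (1.0 - p)).sum())
    if denom == 0.0:
        raise ValueError("all markers are monomorphic; GRM denominator is zero")
    W = Zm - 2.0 * p
    K = (W @ W.T) / denom
    return (K + K.T) / 2.0


def gblup_fit(
    K: np.ndarray, y: np.ndarray, lam: float | None = None
) -> MixedModelFit:
    """Fit y = 1 mu + g + e with g ~ N(0, sigma2_g K) on the training kernel.

    ``K`` is the training-block relationship matrix. GEBVs are the BLUP
    ``g_hat = K (K + lam I)^-1 (y - mu)``; predictions for unobserved
    accessions use the same coefficients through a K cross-block
    (``fit.predict(K_cross)``).
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if K.shape != (n, n):
        raise ValueError(f"K has shape {K.shape}, expected ({n}, {n})")
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant; no genetic variance to estimate")
    Kw = (K + K.T) / 2.0
    lam_min = float(np.linalg.eigvalsh(Kw).min())
    if lam_min < -1e-8:
        raise ValueError("K is not positive semi-definite")
    if lam_min < 1e-6:  # numerical PSD guard
        Kw = Kw + 1e-6 * np.eye(n)
    if lam is None:
        delta, sigma2_g, mu = _reml_delta(Kw, y)
    else:
        delta = float(lam)
        ones = np.ones(n)
        V = Kw + delta * np.eye(n)
        mu = float(ones @ np.linalg.solve(V, y)) / float(
            ones @ np.linalg.solve(V, ones)
        )
        sigma2_g = float("nan")
    alpha = np.linalg.solve(Kw + delta * np.eye(n), y - mu)
    gebv = Kw @ alpha
    sigma2_e = delta * sigma2_g if np.isfinite(sigma2_g) else float("nan")
    # genetic variance in this sample: sigma2_g times mean diagonal of the
    # double-centred kernel (insensitive to a constant shift of K)
    Kc = Kw - Kw.mean(axis=0) - Kw.mean(axis=1)[:, None] + Kw.mean()
    mean_diag = float(np.mean(np.diag(Kc)))
    h2 = (
        sigma2_g * mean_diag / (sigma2_g * mean_diag + sigma2_e)
        if np.isfinite(sigma2_g)
        else float("nan")
    )
    return MixedModelFit(
        model_kind=ModelKind.GBLUP,
        mu=mu,
        sigma2_u=sigma2_g,
        sigma2_e=sigma2_e,
        lam=delta,
        effects=gebv,
        h2=h2,
        _alpha=alpha,
    )


class RRBLUPRegressor(BaseEstimator, RegressorMixin):
    """scikit-learn estimator for ridge-regression BLUP on dosage matrices.

    Fitted attributes: ``mu_``, ``coef_`` (marker effects), ``sigma2_u_``,
    ``sigma2_e_``, ``lambda_`` and ``h2_``.
    """

    def __init__(self, lam: float | None = None):
        self.lam = lam

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        fit = rrblup_fit(X, np.asarray(y, dtype=float), lam=self.lam)
        self.fit_ = fit
        self.mu_ = fit.mu
        self.coef_ = fit.effects
        self.sigma2_u_ = fit.sigma2_u
        self.sigma2_e_ = fit.sigma2_e
        self.lambda_ = fit.lam
        self.h2_ = fit.h2
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        return self.fit_.predict(np.asarray(X, dtype=float))


class GBLUPRegressor(BaseEstimator, RegressorMixin):
    """scikit-learn estimator for GRM-based BLUP.

    ``fit`` builds a VanRaden GRM from the training dosages (allele
    frequencies are estimated on the training set and reused, with the same
    denominator, for the prediction cross-block).
    """

    def __init__(self, lam: float | None = None):
        self.lam = lam

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self._p = X.mean(axis=0) / 2.0
        self._denom = 2.0 * float((self._p * (1.0 - self._p)).sum())
        if self._denom == 0.0:
            raise ValueError("all markers are monomorphic; GRM denominator is zero")
        self._W_train = X - 2.0 * self._p
        K = (self._W_train @ self._W_train.T) / self._denom
        fit = gblup_fit((K + K.T) / 2.0, np.asarray(y, dtype=float), lam=self.lam)
        self.fit_ = fit
        self.mu_ = fit.mu
        self.gebv_ = fit.effects
        self.sigma2_g_ = fit.sigma2_u
        self.sigma2_e_ = fit.sigma2_e
        self.lambda_ = fit.lam
        self.h2_ = fit.h2
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        W_new = np.asarray(X, dtype=float) - 2.0 * self._p
        K_cross = (W_new @ self._W_train.T) / self._denom
        return self.fit_.predict(K_cross)
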