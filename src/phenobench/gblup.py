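"""Genomic BLUP: kinship construction, REML variance components, prediction.

The model is the standard animal-model mixed model

    y = 1μ + g + e,   g ~ N(0, σg² K),   e ~ N(0, σe² I),

where K is a genomic similarity matrix built from the standardized marker
matrix (K = ZZᵀ/p, the VanRaden-style cross-product over p polymorphic
markers). Variance components are estimated by REML: after one
eigendecomposition K = U S Uᵀ the restricted log-likelihood is a cheap
function of the single variance ratio λ = σe²/σg², which is maximized by 1-D
bounded search over log λ. The eigendecomposition is computed once per K and
reused across traits.

Prediction for unseen individuals uses the conditional-mean (BLUP) equation
ŷ_test = μ + K_cross (K_train + λI)⁻¹ (y_train − μ), with the degenerate
σg² = 0 case documented to return μ everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .dataio import GenotypeMatrix

#: search bounds for the variance ratio λ = σe²/σg²
LAMBDA_BOUNDS = (1e-6, 1e6)


@dataclass
class GSM:
    """Genomic similarity matrix with its sample ids and construction tag."""

    K: np.ndarray
    sample_ids: list[str]
    scheme: str = "standardized-crossproduct"
    _eig: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float)
        if K.shape[0] != K.shape[1]:
            raise ValueError("K must be square")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("K must be symmetric within 1e-10")
        self.K = K

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition (ascending eigenvalues)."""
        if self._eig is None:
            s, U = np.linalg.eigh(self.K)
            smax = max(s.max(), 1.0)
            if s.min() < -1e-8 * smax:
                raise ValueError("K is not positive semi-definite within tolerance")
            self._eig = (np.clip(s, 0.0, None), U)
        return self._eig

    def submatrix(self, idx: np.ndarray) -> "GSM":
        return GSM(
            K=self.K[np.ix_(idx, idx)],
            sample_ids=[self.sample_ids[i] for i in idx],
            scheme=self.scheme,
        )


@dataclass
class GBLUPModel:
    sigma_g2: float
    sigma_e2: float
    mu: float
    h2: float
    loglik: float
    sample_ids: list[str]
    y_train: np.ndarray

    @property
    def lam(self) -> float:
        """Variance ratio λ = σe²/σg² (inf when σg² = 0)."""
        return np.inf if self.sigma_g2 == 0 else self.sigma_e2 / self.sigma_g2


def standardize_markers(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardized marker matrix over polymorphic markers.

    Returns (Z, kept_index). Constant markers carry no similarity information
    and are dropped. Standardization uses the population (n) variance so that
    the mean diagonal of ZZᵀ/p is exactly 1.
    """
    vals = G.values
    if np.isnan(vals).any():
        raise ValueError("impute missing genotypes before computing the GSM")
    sd = vals.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all markers constant; GSM undefined")
    Z = (vals[:, keep] - vals[:, keep].mean(axis=0)) / sd[keep]
    return Z, np.flatnonzero(keep)


def compute_gsm(G: GenotypeMatrix) -> GSM:
    """K = ZZᵀ/p over the p polymorphic, column-standardized markers."""
    if G.n_samples < 2:
        raise ValueError("GSM needs at least two samples")
    Z, kept = standardize_markers(G)
    K = Z @ Z.T / Z.shape[1]
    return GSM(K=K, sample_ids=list(G.sample_ids))


def compute_gsm_cross(G_test: GenotypeMatrix, G_train: GenotypeMatrix) -> np.ndarray:
    """Test × train similarity block on the training standardization/markers."""
    Z_train, kept = standardize_markers(G_train)
    vals = G_train.values[:, kept]
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0)
    Z_test = (G_test.values[:, kept] - mean) / sd
    return Z_test @ Z_train.T / Z_train.shape[1]


def _reml_neg_loglik(log_lam: float, s: np.ndarray, Uty: np.ndarray, UtX: np.ndarray):
    """Negative restricted log-likelihood profiled over σg² and μ at fixed λ."""
    lam = np.exp(log_lam)
    w = s + lam
    XtWX = (UtX * UtX / w[:, None]).sum(axis=0)  # X is the 1-column intercept
    XtWy = (UtX[:, 0] * Uty / w).sum()
    beta = XtWy / XtWX[0]
    r = Uty - UtX[:, 0] * beta
    n = len(s)
    q = (r * r / w).sum()
    sigma_g2 = q / (n - 1)
    ll = -0.5 * (
        (n - 1) * np.log(2 * np.pi * sigma_g2)
        + np.log(w).sum()
        + np.log(XtWX[0])
        + (n - 1)
    )
    # constant term ln|XᵀX| omitted from the optimization (fixed in n)
    return -ll, beta, sigma_g2


def fit_gblup(K: GSM, y: np.ndarray) -> GBLUPModel:
    """REML fit of the variance components via eigendecomposition + 1-D search."""
    y = np.asarray(y, dtype=float)
    n = len(K.sample_ids)
    if len(y) != n:
        raise ValueError("y length does not match K")
    if np.isnan(y).any():
        raise ValueError("drop samples with missing phenotypes before fitting")
    if n < 3:
        raise ValueError("need at least 3 samples to fit variance components")
    s, U = K.eig()
    Uty = U.T @ y
    UtX = U.T @ np.ones((n, 1))
    lo, hi = np.log(LAMBDA_BOUNDS[0]), np.log(LAMBDA_BOUNDS[1])
    res = minimize_scalar(
        lambda ll: _reml_neg_loglik(ll, s, Uty, UtX)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    nll, mu, sigma_g2 = _reml_neg_loglik(res.x, s, Uty, UtX)
    lam = np.exp(res.x)
    sigma_e2 = lam * sigma_g2
    h2 = sigma_g2 / (sigma_g2 + sigma_e2)
    return GBLUPModel(
        sigma_g2=float(sigma_g2),
        sigma_e2=float(sigma_e2),
        mu=float(mu),
        h2=float(h2),
        loglik=float(-nll),
        sample_ids=list(K.sample_ids),
        y_train=y,
    )


def reml_loglik(K: GSM, y: np.ndarray, lam: float) -> float:
    """Restricted log-likelihood at an arbitrary variance ratio (for checks)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    s, U = K.eig()
    nll, _, _ = _reml_neg_loglik(np.log(lam), s, U.T @ y, U.T @ np.ones((n, 1)))
    return -nll


def predict_gblup(model: GBLUPModel, K_cross: np.ndarray, K_train: GSM) -> np.ndarray:
    """BLUP predictions μ + K_cross (K_train + λI)⁻¹ (y − μ) for test samples."""
    K_cross = np.atleast_2d(np.asarray(K_cross, dtype=float))
    if model.sigma_g2 == 0 or not np.isfinite(model.lam):
        return np.full(K_cross.shape[0], model.mu)
    n = len(model.sample_ids)
    A = K_train.K + model.lam * np.eye(n)
    alpha = np.linalg.solve(A, model.y_train - model.mu)
    return model.mu + K_cross @ alpha
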