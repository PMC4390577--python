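"""Single-kinship linear mixed model: REML variance components, the
equivalent GBLUP/RRBLUP solver, and prediction metrics.

The model is y = Xb + Zu + e with u ~ N(0, sigma_u^2 K) and
e ~ N(0, sigma_e^2 I). Fitting goes through the phenotyped-record
covariance V = Z K Z' + lambda I:

    b_hat = (X' V^-1 X)^-1 X' V^-1 y
    s_hat = V^-1 (y - X b_hat)
    u_hat = K Z' s_hat                      (all individuals, candidates too)
    g_hat = M' Z' s_hat / c                 (ridge-regression marker effects)

which reproduces the direct mixed-model-equation solutions while never
forming K^-1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .errors import NonIdentifiableError, ValidationError
from .kinship import CenteredGenotypes, RelationshipMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceComponents",
    "SolverResult",
    "design_matrices",
    "estimate_variance_components",
    "gls_fixed_effects",
    "solve_shat",
    "gebv_from_shat",
    "marker_effects_rrblup",
    "solve_blup",
    "accuracy",
    "unbiasedness",
    "regression_slopes",
]


@dataclass
class VarianceComponents:
    """REML estimates for the single-kinship model.

    ``h2`` is the model-scale ratio sigma_u^2 / (sigma_u^2 + sigma_e^2)
    (the optimized parameter). ``h2_realized`` rescales sigma_u^2 by the
    mean eigenvalue of the X-projected kinship, giving the realized
    phenotypic-variance share, which is invariant to how K is scaled.
    """

    sigma_u2: float
    sigma_e2: float
    lam: float
    log_restricted_likelihood: float
    h2: float
    h2_realized: float


@dataclass
class SolverResult:
    b_hat: np.ndarray
    s_hat: np.ndarray
    gebv: np.ndarray
    kinship_label: str
    lam: float
    marker_effects: np.ndarray | None = None


def design_matrices(individual_ids, phenotyped_ids) -> tuple[np.ndarray, np.ndarray]:
    """Intercept-only X and a record->individual incidence matrix Z."""
    lookup = {v: i for i, v in enumerate(individual_ids)}
    records = list(phenotyped_ids)
    Z = np.zeros((len(records), len(lookup)))
    for r, pid in enumerate(records):
        if pid not in lookup:
            raise ValidationError(f"phenotyped individual {pid!r} not in kinship order")
        Z[r, lookup[pid]] = 1.0
    X = np.ones((len(records), 1))
    return X, Z


def _kinship_values(K) -> np.ndarray:
    return K.values if isinstance(K, RelationshipMatrix) else np.asarray(K, dtype=float)


def _spd_solve(V: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Cholesky solve with one jitter retry for borderline-indefinite V."""
    try:
        c = linalg.cho_factor(V, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * float(np.mean(np.diag(V))) or 1e-8
        logger.info("Cholesky failed; retrying with diagonal jitter %g", jitter)
        c = linalg.cho_factor(V + jitter * np.eye(V.shape[0]), lower=True, check_finite=False)
    return linalg.cho_solve(c, B, check_finite=False)


def _projected_spectrum(y, X, Z, K):
    """Eigen-decompose the kinship of phenotyped records after projecting out X."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    Kv = _kinship_values(K)
    n_rec, p = X.shape
    if n_rec - p < 2:
        raise ValidationError("need at least p + 2 phenotyped records for REML")
    if np.linalg.matrix_rank(X) < p:
        raise ValidationError("X is rank deficient")
    Koo = Z @ Kv @ Z.T
    Koo = 0.5 * (Koo + Koo.T)
    Q, _ = np.linalg.qr(X, mode="complete")
    A = Q[:, p:]  # orthonormal basis of the error-contrast space
    Kp = A.T @ Koo @ A
    Kp = 0.5 * (Kp + Kp.T)
    xi, V = np.linalg.eigh(Kp)
    top = max(xi[-1], 1.0)
    if xi[0] < -1e-6 * top:
        raise ValidationError(
            f"kinship is not PSD on the phenotyped subset (min eigenvalue {xi[0]:g})"
        )
    xi = np.clip(xi, 0.0, None)
    if xi[-1] - xi[0] <= 1e-10 * top:
        raise NonIdentifiableError(
            "projected kinship has (numerically) equal eigenvalues; "
            "additive and residual variances are not separable"
        )
    eta = V.T @ (A.T @ y)
    return xi, eta, n_rec - p


def estimate_variance_components(y, X, Z, K, h2_tol: float = 1e-8) -> VarianceComponents:
    """REML by eigendecomposition of the projected Z K Z' and a bracketed
    1-D search of the restricted likelihood over h2 in (0, 1)."""
    xi, eta, df = _projected_spectrum(y, X, Z, K)
    eta2 = eta**2

    def negll(h2: float) -> float:
        delta = (1.0 - h2) / h2
        v = xi + delta
        return 0.5 * (df * math.log(eta2 @ (1.0 / v)) + np.log(v).sum())

    lo, hi = 1e-6, 1.0 - 1e-6
    grid = np.linspace(lo, hi, 201)
    values = np.array([negll(h) for h in grid])
    i = int(values.argmin())
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        negll, bounds=(a, b), method="bounded", options={"xatol": h2_tol * 1e-2}
    )
    h2 = float(res.x if res.fun <= values[i] else grid[i])
    delta = (1.0 - h2) / h2
    v = xi + delta
    quad = float(eta2 @ (1.0 / v))
    sigma_u2 = quad / df
    sigma_e2 = delta * sigma_u2
    ll = 0.5 * (
        df * math.log(df / (2.0 * math.pi)) - df - df * math.log(quad) - np.log(v).sum()
    )
    s_bar = float(xi.mean())
    h2_realized = sigma_u2 * s_bar / (sigma_u2 * s_bar + sigma_e2)
    return VarianceComponents(
        sigma_u2=sigma_u2,
        sigma_e2=sigma_e2,
        lam=delta,
        log_restricted_likelihood=float(ll),
        h2=h2,
        h2_realized=float(h2_realized),
    )


def _record_covariance(Z, K, lam) -> np.ndarray:
    Kv = _kinship_values(K)
    V = Z @ Kv @ Z.T + lam * np.eye(Z.shape[0])
    return 0.5 * (V + V.T)


def gls_fixed_effects(y, X, Z, K, lam) -> np.ndarray:
    """Generalized least squares for the fixed effects under V = ZKZ' + lam I."""
    y = np.asarray(y, dtype=float).ravel()
    V = _record_covariance(Z, K, lam)
    ViX = _spd_solve(V, np.asarray(X, dtype=float))
    Viy = _spd_solve(V, y)
    XtViX = X.T @ ViX
    try:
        return np.linalg.solve(XtViX, X.T @ Viy)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(f"singular GLS normal equations: {exc}") from exc


def solve_shat(y, X, Z, K, lam, b_hat) -> np.ndarray:
    """s_hat = V^-1 (y - X b_hat) on the phenotyped records."""
    y = np.asarray(y, dtype=float).ravel()
    V = _record_covariance(Z, K, lam)
    return _spd_solve(V, y - np.asarray(X, dtype=float) @ np.asarray(b_hat, dtype=float))


def gebv_from_shat(K, Z, s_hat) -> np.ndarray:
    """u_hat = K Z' s_hat; candidates get predictions through their K rows."""
    Kv = _kinship_values(K)
    return Kv @ (np.asarray(Z, dtype=float).T @ np.asarray(s_hat, dtype=float))


def marker_effects_rrblup(M: CenteredGenotypes, Z, s_hat, scale_constant=None) -> np.ndarray:
    """Ridge-regression marker effects g_hat = M' Z' s_hat / c.

    The scale constant must be the one of the kinship used to obtain
    s_hat so that M g_hat reproduces u_hat exactly.
    """
    c = M.scale_constant if scale_constant is None else float(scale_constant)
    if abs(c - M.scale_constant) > 1e-9:
        raise ValidationError(
            f"scale constant {c} does not match the centered genotypes ({M.scale_constant})"
        )
    return (M.values.T @ (np.asarray(Z, dtype=float).T @ np.asarray(s_hat, dtype=float))) / c


def solve_blup(y, X, Z, K, lam, label: str = "G") -> SolverResult:
    """Run the equivalent algorithm end to end for a given kinship and lambda."""
    b_hat = gls_fixed_effects(y, X, Z, K, lam)
    s_hat = solve_shat(y, X, Z, K, lam, b_hat)
    gebv = gebv_from_shat(K, Z, s_hat)
    return SolverResult(b_hat=b_hat, s_hat=s_hat, gebv=gebv, kinship_label=label, lam=lam)


def _paired(gebv, reference_values):
    a = np.asarray(gebv, dtype=float).ravel()
    b = np.asarray(reference_values, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValidationError("gebv and reference values differ in length")
    if a.size < 3:
        raise ValidationError("need at least 3 paired values")
    return a, b


def accuracy(gebv, reference_values) -> float:
    """Pearson correlation between predictions and reference values."""
    a, b = _paired(gebv, reference_values)
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValidationError("zero variance; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def regression_slopes(gebv, reference_values) -> tuple[float, float]:
    """(slope of reference on gebv, slope of gebv on reference)."""
    a, b = _paired(gebv, reference_values)
    va = np.var(a, ddof=1)
    vb = np.var(b, ddof=1)
    if np.all(a == a[0]) or va == 0:
        raise ValidationError("zero GEBV variance; regression undefined")
    cov = np.cov(a, b, ddof=1)[0, 1]
    reverse = cov / vb if vb > 0 else math.nan
    return float(cov / va), float(reverse)


def unbiasedness(gebv, reference_values) -> float:
    """OLS slope of the reference values on the GEBVs (1 = unbiased dispersion)."""
    return regression_slopes(gebv, reference_values)[0]
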