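"""Relationship matrices: G, the weighted-subset matrix S, the blend T,
and the T-G distance statistic sigma.

All matrices use the fixed-frequency convention p = 0.5 for every
marker, so centering is simply dosage - 1 and the normalizing constant
for m markers is 2 * sum(p_i (1 - p_i)) = m / 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import GenotypeMatrix
from .errors import AlignmentError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "RelationshipMatrix",
    "CenteredGenotypes",
    "WeightDiagonal",
    "center_genotypes",
    "build_G",
    "build_D",
    "build_S",
    "build_T",
    "matrix_distance_sigma",
    "psd_jitter",
]

SYMMETRY_TOL = 1e-10
PSD_REL_TOL = 1e-8


@dataclass
class RelationshipMatrix:
    """Symmetric n x n covariance structure over a fixed individual order."""

    individual_ids: np.ndarray
    values: np.ndarray
    label: str = "G"

    def __post_init__(self):
        self.individual_ids = np.asarray(list(self.individual_ids), dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} individuals"
            )
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > SYMMETRY_TOL:
            raise ValidationError(f"matrix is not symmetric (max asymmetry {asym:g})")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    def min_max_eigenvalues(self) -> tuple[float, float]:
        w = np.linalg.eigvalsh(self.values)
        return float(w[0]), float(w[-1])

    def is_psd(self, rel_tol: float = PSD_REL_TOL) -> bool:
        lo, hi = self.min_max_eigenvalues()
        return lo >= -rel_tol * max(hi, 1e-300)


@dataclass
class CenteredGenotypes:
    """Dosages centered at the fixed frequency 0.5 (i.e. dosage - 1)."""

    marker_ids: np.ndarray
    values: np.ndarray
    scale_constant: float  # 2 * sum p(1-p) = m/2 under p = 0.5


@dataclass
class WeightDiagonal:
    """Per-selected-marker weights rescaled so the diagonal mean is 1."""

    selected_marker_ids: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.selected_marker_ids = np.asarray(list(self.selected_marker_ids), dtype=object)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.selected_marker_ids):
            raise ValidationError("weights and marker ids differ in length")
        if (self.weights < 0).any():
            raise ValidationError("weights must be non-negative")
        if abs(self.weights.mean() - 1.0) > 1e-12:
            raise ValidationError("weight diagonal mean must be 1")


def center_genotypes(genotypes: GenotypeMatrix, marker_subset=None) -> CenteredGenotypes:
    """Center dosages to dosage - 1 over ``marker_subset`` (default: all markers)."""
    if marker_subset is None:
        marker_ids = genotypes.marker_ids
        idx = np.arange(genotypes.n_markers)
    else:
        marker_ids = np.asarray(list(marker_subset), dtype=object)
        if len(marker_ids) == 0:
            raise ValidationError("marker subset is empty")
        idx = genotypes.marker_index(marker_ids)
    values = genotypes.dosages[:, idx] - 1.0
    return CenteredGenotypes(
        marker_ids=marker_ids, values=values, scale_constant=len(marker_ids) / 2.0
    )


def build_G(genotypes: GenotypeMatrix) -> RelationshipMatrix:
    """Realized relationship matrix G = M M' / (2 sum p(1-p)) with p = 0.5."""
    if genotypes.n_individuals < 2:
        raise ValidationError("need at least 2 individuals to build G")
    if genotypes.n_markers < 1:
        raise ValidationError("need at least 1 marker to build G")
    cg = center_genotypes(genotypes)
    values = (cg.values @ cg.values.T) / cg.scale_constant
    return RelationshipMatrix(genotypes.individual_ids, values, label="G")


def build_D(selected_marker_ids, selected_effects, transform: str = "abs") -> WeightDiagonal:
    """Weight diagonal from estimated effects, rescaled to mean exactly 1.

    ``transform`` maps signed effects to non-negative weights: ``abs``
    (default) or ``square``.
    """
    effects = np.asarray(selected_effects, dtype=float)
    if effects.size == 0:
        raise ValidationError("no selected effects")
    if transform == "abs":
        w = np.abs(effects)
    elif transform == "square":
        w = effects**2
    else:
        raise ValidationError(f"unknown transform {transform!r}; use 'abs' or 'square'")
    total = w.sum()
    if total == 0:
        raise ValidationError("all selected effects are zero; cannot rescale D")
    w = w * (len(w) / total)
    return WeightDiagonal(selected_marker_ids=selected_marker_ids, weights=w)


def build_S(genotypes: GenotypeMatrix, weight_diag: WeightDiagonal) -> RelationshipMatrix:
    """Architecture matrix S = M1 D M1' / (m1 / 2) over the selected markers."""
    if len(weight_diag.selected_marker_ids) == 0:
        raise ValidationError("selected marker set is empty")
    cg = center_genotypes(genotypes, weight_diag.selected_marker_ids)
    weighted = cg.values * weight_diag.weights  # column scaling by diag(D)
    values = (weighted @ cg.values.T) / cg.scale_constant
    values = 0.5 * (values + values.T)  # exact symmetry despite fp order effects
    return RelationshipMatrix(genotypes.individual_ids, values, label="S")


def build_T(S: RelationshipMatrix, G: RelationshipMatrix, omega: float) -> RelationshipMatrix:
    """Blended matrix T = omega * S + (1 - omega) * G."""
    if not 0.0 <= omega <= 1.0:
        raise ValidationError(f"omega must be in [0, 1], got {omega}")
    if not np.array_equal(S.individual_ids, G.individual_ids):
        raise AlignmentError("S and G individual orderings differ")
    if omega == 0.0:
        values = G.values.copy()
    elif omega == 1.0:
        values = S.values.copy()
    else:
        values = omega * S.values + (1.0 - omega) * G.values
    return RelationshipMatrix(G.individual_ids, values, label="T")


def matrix_distance_sigma(T: RelationshipMatrix, G: RelationshipMatrix) -> float:
    """Sample standard deviation of T_ij - G_ij over the upper triangle
    (diagonal included)."""
    if not np.array_equal(T.individual_ids, G.individual_ids):
        raise AlignmentError("matrices have different individual orderings")
    n = T.n
    if n < 2:
        raise ValidationError("sigma needs at least 2 individuals")
    iu = np.triu_indices(n)
    diff = T.values[iu] - G.values[iu]
    return float(np.std(diff, ddof=1))


def psd_jitter(values: np.ndarray, rel_tol: float = PSD_REL_TOL) -> np.ndarray:
    """Add diagonal jitter when round-off pushed the matrix slightly indefinite."""
    w = np.linalg.eigvalsh(values)
    if w[0] >= -rel_tol * max(w[-1], 1e-300):
        if w[0] >= 0:
            return values
    jitter = 1e-8 * float(np.mean(np.diag(values)))
    if jitter <= 0:
        jitter = 1e-8
    logger.info("applying PSD jitter %g to matrix diagonal", jitter)
    return values + jitter * np.eye(values.shape[0])
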