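"""Model-choice diagnostics: cumulative variance curves, effect
rescaling, the zero-intercept delta-on-sigma regression, and
heat-map-ready matrix ordering."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix
from .errors import AlignmentError, ValidationError
from .kinship import RelationshipMatrix

__all__ = [
    "VarianceCurve",
    "DeltaSigmaFit",
    "variance_explained_curve",
    "rescale_effects_mean_abs_one",
    "delta_sigma_regression",
    "order_by_top_genotype",
]


@dataclass
class VarianceCurve:
    """Markers sorted by |effect| descending with the cumulative fraction
    of genetic variance (2 p (1-p) effect^2) they explain."""

    sorted_marker_ids: np.ndarray
    cumulative_fraction: np.ndarray

    def fraction_at_top(self, fraction_of_markers: float) -> float:
        """Cumulative variance fraction at the top given fraction of markers."""
        m = len(self.sorted_marker_ids)
        k = max(1, int(round(fraction_of_markers * m)))
        return float(self.cumulative_fraction[min(k, m) - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.sorted_marker_ids) + 1),
                "marker_id": self.sorted_marker_ids,
                "cumulative_fraction": self.cumulative_fraction,
            }
        )


@dataclass
class DeltaSigmaFit:
    slope: float
    se: float
    t_statistic: float
    p_value: float
    n: int


def variance_explained_curve(marker_ids, marker_effects, allele_freqs) -> VarianceCurve:
    """Per-marker variance v = 2 p (1-p) a^2 with observed frequencies,
    cumulated over markers sorted by |a| descending (ties keep map order)."""
    effects = np.asarray(marker_effects, dtype=float)
    p = np.asarray(allele_freqs, dtype=float)
    ids = np.asarray(list(marker_ids), dtype=object)
    if not (len(ids) == effects.size == p.size):
        raise ValidationError("marker ids, effects and frequencies differ in length")
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("allele frequencies must lie in [0, 1]")
    v = 2.0 * p * (1.0 - p) * effects**2
    total = v.sum()
    if total == 0:
        raise ValidationError("total explained variance is zero")
    order = np.argsort(-np.abs(effects), kind="stable")
    cumulative = np.cumsum(v[order]) / total
    cumulative[-1] = 1.0  # kill last-bin round-off
    return VarianceCurve(sorted_marker_ids=ids[order], cumulative_fraction=cumulative)


def rescale_effects_mean_abs_one(marker_effects) -> np.ndarray:
    """Divide effects by mean(|effects|), preserving signs."""
    effects = np.asarray(marker_effects, dtype=float)
    scale = np.abs(effects).mean() if effects.size else 0.0
    if scale == 0:
        raise ValidationError("cannot rescale an all-zero effect vector")
    return effects / scale


def delta_sigma_regression(sigma, delta) -> DeltaSigmaFit:
    """Zero-intercept least squares of accuracy gain on the T-G distance.

    slope = sum(sigma * delta) / sum(sigma^2); the t test for slope != 0
    uses n - 1 residual degrees of freedom (no intercept fitted).
    """
    s = np.asarray(sigma, dtype=float).ravel()
    d = np.asarray(delta, dtype=float).ravel()
    if s.size != d.size:
        raise ValidationError("sigma and delta differ in length")
    if s.size < 2:
        raise ValidationError("need at least 2 points")
    if (s < 0).any():
        raise ValidationError("sigma values must be non-negative")
    ss = float(np.sum(s * s))
    if ss == 0:
        raise ValidationError("all sigma values are zero")
    slope = float(np.sum(s * d) / ss)
    resid = d - slope * s
    df = s.size - 1
    se = float(np.sqrt(np.sum(resid**2) / df / ss))
    if se == 0:
        t = np.inf if slope != 0 else 0.0
        p = 0.0 if slope != 0 else 1.0
    else:
        t = slope / se
        p = float(2.0 * stats.t.sf(abs(t), df))
    return DeltaSigmaFit(slope=slope, se=se, t_statistic=float(t), p_value=p, n=s.size)


def order_by_top_genotype(
    matrix: RelationshipMatrix, genotypes: GenotypeMatrix, top_marker_id
) -> tuple[RelationshipMatrix, np.ndarray]:
    """Permute rows/columns so individuals are grouped by dosage (0, 1, 2)
    at the named marker; ties keep the original order."""
    if not np.array_equal(matrix.individual_ids, genotypes.individual_ids):
        raise AlignmentError("matrix and genotype individual orderings differ")
    j = genotypes.marker_index([top_marker_id])[0]
    dosage = genotypes.dosages[:, j]
    perm = np.argsort(dosage, kind="stable")
    ordered = RelationshipMatrix(
        individual_ids=matrix.individual_ids[perm],
        values=matrix.values[np.ix_(perm, perm)],
        label=matrix.label,
    )
    return ordered, perm
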