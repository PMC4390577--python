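"""Top-effect SNP selection, flank expansion, and the hyperparameter grid."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .core import MarkerMap
from .errors import ValidationError

__all__ = ["ArchitectureParams", "SelectedSet", "select_top_snps", "expand_flanks", "default_grid"]

MAX_NFLANK = 10

DEFAULT_OMEGAS = (0.0, 0.02, 0.04, 0.1, 0.2, 0.3, 0.45, 0.6, 0.8)
DEFAULT_TOP_PCTS = (0.0001, 0.0005, 0.001, 0.005, 0.01, 0.05)
DEFAULT_NFLANKS = (0, 3, 5)


@dataclass(frozen=True, order=True)
class ArchitectureParams:
    """The hyperparameter triple (top fraction, flanks per side, blend weight)."""

    omega: float
    top_pct: float
    nflank: int

    def __post_init__(self):
        if not 0.0 < self.top_pct <= 1.0:
            raise ValidationError(f"top_pct must be in (0, 1], got {self.top_pct}")
        if not 0.0 <= self.omega <= 1.0:
            raise ValidationError(f"omega must be in [0, 1], got {self.omega}")
        if not 0 <= self.nflank <= MAX_NFLANK:
            raise ValidationError(f"nflank must be in [0, {MAX_NFLANK}], got {self.nflank}")


@dataclass
class SelectedSet:
    """Deduplicated, map-ordered selection of top markers plus flanks."""

    marker_ids: np.ndarray
    is_top: np.ndarray
    effects: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.marker_ids = np.asarray(list(self.marker_ids), dtype=object)
        self.is_top = np.asarray(self.is_top, dtype=bool)
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValidationError("selected set contains duplicates")


def top_count(top_pct: float, n_markers: int) -> int:
    """k = max(1, round-half-up(top_pct * m))."""
    return max(1, math.floor(top_pct * n_markers + 0.5))


def select_top_snps(marker_ids, marker_effects, top_pct: float) -> list:
    """IDs of the k markers with the largest |effect|.

    Ties break toward the earlier marker in the supplied (map) order, so
    selection is deterministic.
    """
    effects = np.asarray(marker_effects, dtype=float)
    if effects.size == 0:
        raise ValidationError("empty effects vector")
    if not 0.0 < top_pct <= 1.0:
        raise ValidationError(f"top_pct must be in (0, 1], got {top_pct}")
    ids = np.asarray(list(marker_ids), dtype=object)
    if len(ids) != effects.size:
        raise ValidationError("marker ids and effects differ in length")
    k = top_count(top_pct, effects.size)
    order = np.argsort(-np.abs(effects), kind="stable")  # stable => earlier wins ties
    chosen = np.sort(order[:k])  # back to map order
    return list(ids[chosen])


def expand_flanks(top_ids, marker_map: MarkerMap, nflank: int, effects=None) -> SelectedSet:
    """Union of top markers and up to ``nflank`` same-chromosome map
    neighbors per side, deduplicated and ordered by map."""
    if nflank < 0:
        raise ValidationError("nflank must be >= 0")
    top_set = set(top_ids)
    for mid in top_ids:
        marker_map.row_index(mid)  # raises AlignmentError when absent
    selected: set = set()
    for mid in top_ids:
        selected.update(marker_map.neighbors(mid, nflank))
    ordered = [mid for mid in marker_map.frame["marker_id"] if mid in selected]
    ids = np.asarray(ordered, dtype=object)
    is_top = np.array([mid in top_set for mid in ordered], dtype=bool)
    eff = None
    if effects is not None:
        eff = np.array([effects[mid] for mid in ordered], dtype=float)
    return SelectedSet(marker_ids=ids, is_top=is_top, effects=eff)


def default_grid(omegas=None, top_pcts=None, nflanks=None) -> list:
    """Cartesian hyperparameter grid.

    omega = 0 makes every (top_pct, nflank) combination collapse to the
    same plain-GBLUP model, so it contributes exactly one cell.
    """
    omegas = DEFAULT_OMEGAS if omegas is None else tuple(omegas)
    top_pcts = DEFAULT_TOP_PCTS if top_pcts is None else tuple(top_pcts)
    nflanks = DEFAULT_NFLANKS if nflanks is None else tuple(nflanks)
    cells = []
    if any(w == 0.0 for w in omegas):
        cells.append(ArchitectureParams(omega=0.0, top_pct=min(top_pcts), nflank=min(nflanks)))
    for w, t, f in itertools.product(sorted(omegas), sorted(top_pcts), sorted(nflanks)):
        if w == 0.0:
            continue
        cells.append(ArchitectureParams(omega=w, top_pct=t, nflank=f))
    return cells
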