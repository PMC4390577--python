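"""Two-stage validation workflow: cross-validated hyperparameter grid
search within the reference population, then one-shot prediction of
never-used candidates with the selected parameters.

Per fold the expensive steps (REML, s_hat, marker effects) are computed
once and shared by every grid cell; only the selected-marker matrix S
and the final solve differ between cells.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mixed_model as mm
from .core import Dataset, GenotypeMatrix
from .errors import ValidationError
from .kinship import (
    RelationshipMatrix,
    build_D,
    build_G,
    build_S,
    build_T,
    center_genotypes,
)
from .selection import ArchitectureParams, default_grid, expand_flanks, select_top_snps

logger = logging.getLogger(__name__)

__all__ = [
    "FoldPlan",
    "FoldMetrics",
    "CellResult",
    "GridSearchResult",
    "StageReport",
    "make_folds",
    "run_fold",
    "grid_search",
    "apply_stage",
    "train",
]


@dataclass
class FoldPlan:
    n_folds: int
    replicate_seeds: list
    assignments: list  # assignments[replicate] -> list of n_folds id arrays


@dataclass
class FoldMetrics:
    accuracy: float
    bias: float
    ok: bool = True


@dataclass
class CellResult:
    params: ArchitectureParams
    mean_accuracy: float  # mean of per-replicate means (canonical aggregation)
    pooled_accuracy: float  # plain mean over all folds x replicates
    se_accuracy: float
    mean_bias: float
    replicate_means: list = field(default_factory=list)


@dataclass
class GridSearchResult:
    cells: list
    best_params: ArchitectureParams
    n_folds: int
    n_replicates: int

    def cell(self, params: ArchitectureParams) -> CellResult:
        for c in self.cells:
            if c.params == params:
                return c
        raise KeyError(params)

    def gblup_cell(self) -> CellResult:
        for c in self.cells:
            if c.params.omega == 0.0:
                return c
        raise KeyError("no omega=0 cell in grid")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "omega": c.params.omega,
                "top_pct": c.params.top_pct,
                "nflank": c.params.nflank,
                "mean_accuracy": c.mean_accuracy,
                "pooled_accuracy": c.pooled_accuracy,
                "se_accuracy": c.se_accuracy,
                "mean_bias": c.mean_bias,
            }
            for c in self.cells
        ]
        return pd.DataFrame(rows)


@dataclass
class StageReport:
    stage: str
    accuracy_gblup: float
    accuracy_model: float
    bias_gblup: float
    bias_model: float
    params: ArchitectureParams
    variance_components: mm.VarianceComponents
    gebv: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "accuracy_gblup": self.accuracy_gblup,
            "accuracy_model": self.accuracy_model,
            "bias_gblup": self.bias_gblup,
            "bias_model": self.bias_model,
            "params": {
                "omega": self.params.omega,
                "top_pct": self.params.top_pct,
                "nflank": self.params.nflank,
            },
            "variance_components": {
                "sigma_u2": self.variance_components.sigma_u2,
                "sigma_e2": self.variance_components.sigma_e2,
                "lambda": self.variance_components.lam,
                "h2": self.variance_components.h2,
                "h2_realized": self.variance_components.h2_realized,
            },
        }


def make_folds(individual_ids, n_folds: int, n_replicates: int = 1, seed: int = 0) -> FoldPlan:
    """Seeded random partitions into folds whose sizes differ by at most 1."""
    ids = np.asarray(list(individual_ids), dtype=object)
    n = len(ids)
    if n_folds < 2:
        raise ValidationError("n_folds must be >= 2")
    if n_folds > n:
        raise ValidationError(f"n_folds ({n_folds}) exceeds number of individuals ({n})")
    replicate_seeds = [int(s) for s in np.random.SeedSequence(seed).generate_state(n_replicates)]
    assignments = []
    for rep_seed in replicate_seeds:
        rng = np.random.default_rng(rep_seed)
        perm = rng.permutation(n)
        folds = [ids[chunk] for chunk in np.array_split(perm, n_folds)]
        assignments.append(folds)
    return FoldPlan(n_folds=n_folds, replicate_seeds=replicate_seeds, assignments=assignments)


@dataclass
class _FoldContext:
    """Cached per-fold quantities reused across grid cells."""

    train_ids: np.ndarray
    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    varcomps: mm.VarianceComponents
    lam: float
    g_hat: np.ndarray  # RRBLUP effects, aligned to genotype marker order
    effects_by_id: dict


def _prepare_fold(data: Dataset, G: RelationshipMatrix, centered, train_ids) -> _FoldContext:
    """Steps 1-3 on the training records: REML, s_hat, RRBLUP marker effects."""
    train_ids = np.asarray(list(train_ids), dtype=object)
    y = data.phenotypes.loc[train_ids].to_numpy(dtype=float)
    X, Z = mm.design_matrices(data.genotypes.individual_ids, train_ids)
    vc = mm.estimate_variance_components(y, X, Z, G)
    fit = mm.solve_blup(y, X, Z, G, vc.lam, label="G")
    g_hat = mm.marker_effects_rrblup(centered, Z, fit.s_hat)
    return _FoldContext(
        train_ids=train_ids,
        y=y,
        X=X,
        Z=Z,
        varcomps=vc,
        lam=vc.lam,
        g_hat=g_hat,
        effects_by_id=dict(zip(data.genotypes.marker_ids, g_hat)),
    )


def _selected_S(data: Dataset, ctx: _FoldContext, params: ArchitectureParams, d_transform: str):
    top = select_top_snps(data.genotypes.marker_ids, ctx.g_hat, params.top_pct)
    sel = expand_flanks(top, data.marker_map, params.nflank, effects=ctx.effects_by_id)
    D = build_D(sel.marker_ids, sel.effects, transform=d_transform)
    return build_S(data.genotypes, D)


def _evaluate_cell(
    data: Dataset,
    G: RelationshipMatrix,
    ctx: _FoldContext,
    params: ArchitectureParams,
    test_ids,
    variance_policy: str,
    d_transform: str,
    S: RelationshipMatrix | None = None,
) -> FoldMetrics:
    if params.omega == 0.0:
        K, lam = G, ctx.lam
    else:
        if S is None:
            S = _selected_S(data, ctx, params, d_transform)
        K = build_T(S, G, params.omega)
        if variance_policy == "reestimate":
            lam = mm.estimate_variance_components(ctx.y, ctx.X, ctx.Z, K).lam
        else:
            lam = ctx.lam
    fit = mm.solve_blup(ctx.y, ctx.X, ctx.Z, K, lam, label=K.label)
    test_idx = data.genotypes.individual_index(test_ids)
    gebv_test = fit.gebv[test_idx]
    ref = data.evaluation_values().loc[list(test_ids)].to_numpy(dtype=float)
    try:
        acc = mm.accuracy(gebv_test, ref)
        bias = mm.unbiasedness(gebv_test, ref)
    except ValidationError as exc:
        warnings.warn(f"degenerate fold (cell {params}): {exc}", stacklevel=2)
        return FoldMetrics(accuracy=math.nan, bias=math.nan, ok=False)
    return FoldMetrics(accuracy=acc, bias=bias, ok=True)


def _check_policy(variance_policy: str) -> None:
    if variance_policy not in ("reuse_lambda", "reestimate"):
        raise ValidationError(f"unknown variance policy {variance_policy!r}")


def run_fold(
    train_ids,
    test_ids,
    data: Dataset,
    params: ArchitectureParams,
    variance_policy: str = "reuse_lambda",
    d_transform: str = "abs",
    G: RelationshipMatrix | None = None,
) -> FoldMetrics:
    """Fit on the training individuals only and score the held-out fold."""
    _check_policy(variance_policy)
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise ValidationError(f"train/test overlap: {sorted(overlap)[:5]}")
    if G is None:
        G = build_G(data.genotypes)
    centered = center_genotypes(data.genotypes)
    ctx = _prepare_fold(data, G, centered, train_ids)
    return _evaluate_cell(data, G, ctx, params, test_ids, variance_policy, d_transform)


def grid_search(
    fold_plan: FoldPlan,
    data: Dataset,
    grid=None,
    variance_policy: str = "reuse_lambda",
    d_transform: str = "abs",
) -> GridSearchResult:
    """Evaluate every grid cell on every fold x replicate and pick the best.

    Ties on mean accuracy resolve to the smaller omega, then top_pct,
    then nflank.
    """
    _check_policy(variance_policy)
    grid = list(default_grid() if grid is None else grid)
    if not grid:
        raise ValidationError("empty grid")
    G = build_G(data.genotypes)
    centered = center_genotypes(data.genotypes)
    acc = {p: [] for p in grid}  # per cell: list over replicates of per-fold lists
    bias = {p: [] for p in grid}
    for rep, folds in enumerate(fold_plan.assignments):
        for p in grid:
            acc[p].append([])
            bias[p].append([])
        for k, test_ids in enumerate(folds):
            train_ids = np.concatenate([f for j, f in enumerate(folds) if j != k])
            ctx = _prepare_fold(data, G, centered, train_ids)
            s_cache: dict = {}
            for p in grid:
                S = None
                if p.omega > 0.0:
                    key = (p.top_pct, p.nflank)
                    if key not in s_cache:
                        s_cache[key] = _selected_S(data, ctx, p, d_transform)
                    S = s_cache[key]
                fm = _evaluate_cell(
                    data, G, ctx, p, test_ids, variance_policy, d_transform, S=S
                )
                acc[p][rep].append(fm.accuracy)
                bias[p][rep].append(fm.bias)
    cells = []
    for p in grid:
        rep_means = [np.nanmean(r) if not np.all(np.isnan(r)) else math.nan for r in acc[p]]
        rep_means = [m for m in rep_means if not math.isnan(m)]
        all_folds = np.concatenate(acc[p])
        pooled = float(np.nanmean(all_folds)) if not np.all(np.isnan(all_folds)) else math.nan
        mean_acc = float(np.mean(rep_means)) if rep_means else math.nan
        se = (
            float(np.std(rep_means, ddof=1) / math.sqrt(len(rep_means)))
            if len(rep_means) > 1
            else 0.0
        )
        all_bias = np.concatenate(bias[p])
        mean_bias = float(np.nanmean(all_bias)) if not np.all(np.isnan(all_bias)) else math.nan
        cells.append(
            CellResult(
                params=p,
                mean_accuracy=mean_acc,
                pooled_accuracy=pooled,
                se_accuracy=se,
                mean_bias=mean_bias,
                replicate_means=rep_means,
            )
        )
    scored = [c for c in cells if not math.isnan(c.mean_accuracy)]
    if not scored:
        raise ValidationError("every grid cell was degenerate; no best parameters")
    best = min(
        scored,
        key=lambda c: (-c.mean_accuracy, c.params.omega, c.params.top_pct, c.params.nflank),
    ).params
    logger.info("grid search best cell: %s", best)
    return GridSearchResult(
        cells=cells,
        best_params=best,
        n_folds=fold_plan.n_folds,
        n_replicates=len(fold_plan.assignments),
    )


def train(
    data: Dataset,
    grid=None,
    n_folds: int = 5,
    n_replicates: int = 20,
    seed: int = 0,
    variance_policy: str = "reuse_lambda",
    d_transform: str = "abs",
) -> GridSearchResult:
    """Training stage: seeded k-fold CV grid search over the reference set."""
    plan = make_folds(data.phenotyped_ids, n_folds, n_replicates, seed)
    return grid_search(plan, data, grid, variance_policy, d_transform)


def predict_candidates(
    reference_data: Dataset,
    candidate_genotypes: GenotypeMatrix,
    params: ArchitectureParams,
    variance_policy: str = "reuse_lambda",
    d_transform: str = "abs",
) -> tuple[pd.DataFrame, mm.VarianceComponents]:
    """GEBVs for unphenotyped candidates (no scoring), one combined fit."""
    _check_policy(variance_policy)
    genotypes = GenotypeMatrix.concat(reference_data.genotypes, candidate_genotypes)
    combined = Dataset(
        genotypes=genotypes,
        marker_map=reference_data.marker_map,
        phenotypes=reference_data.phenotypes,
    )
    G = build_G(genotypes)
    centered = center_genotypes(genotypes)
    ctx = _prepare_fold(combined, G, centered, reference_data.phenotyped_ids)
    if params.omega == 0.0:
        K, lam = G, ctx.lam
    else:
        S = _selected_S(combined, ctx, params, d_transform)
        K = build_T(S, G, params.omega)
        lam = (
            mm.estimate_variance_components(ctx.y, ctx.X, ctx.Z, K).lam
            if variance_policy == "reestimate"
            else ctx.lam
        )
    fit = mm.solve_blup(ctx.y, ctx.X, ctx.Z, K, lam, label=K.label)
    cand_ids = list(candidate_genotypes.individual_ids)
    cand_idx = genotypes.individual_index(cand_ids)
    table = pd.DataFrame({"individual_id": cand_ids, "gebv": fit.gebv[cand_idx]})
    return table, ctx.varcomps


def apply_stage(
    reference_data: Dataset,
    candidate_data: Dataset,
    best_params: ArchitectureParams,
    variance_policy: str = "reuse_lambda",
    d_transform: str = "abs",
) -> StageReport:
    """Application stage: fit once on reference phenotypes over the combined
    population and score the candidates for both GBLUP and the selected cell."""
    _check_policy(variance_policy)
    overlap = set(reference_data.genotypes.individual_ids) & set(
        candidate_data.genotypes.individual_ids
    )
    if overlap:
        raise ValidationError(f"candidates overlap the reference set: {sorted(overlap)[:5]}")
    genotypes = GenotypeMatrix.concat(reference_data.genotypes, candidate_data.genotypes)
    combined = Dataset(
        genotypes=genotypes,
        marker_map=reference_data.marker_map,
        phenotypes=reference_data.phenotypes,
    )
    G = build_G(genotypes)
    centered = center_genotypes(genotypes)
    ctx = _prepare_fold(combined, G, centered, reference_data.phenotyped_ids)
    cand_ids = list(candidate_data.genotypes.individual_ids)
    cand_idx = genotypes.individual_index(cand_ids)
    ref_values = candidate_data.evaluation_values().loc[cand_ids].to_numpy(dtype=float)

    def _score(params: ArchitectureParams):
        if params.omega == 0.0:
            K, lam = G, ctx.lam
        else:
            S = _selected_S(combined, ctx, params, d_transform)
            K = build_T(S, G, params.omega)
            lam = (
                mm.estimate_variance_components(ctx.y, ctx.X, ctx.Z, K).lam
                if variance_policy == "reestimate"
                else ctx.lam
            )
        fit = mm.solve_blup(ctx.y, ctx.X, ctx.Z, K, lam, label=K.label)
        gebv = fit.gebv[cand_idx]
        return gebv, mm.accuracy(gebv, ref_values), mm.unbiasedness(gebv, ref_values)

    gebv_g, acc_g, bias_g = _score(ArchitectureParams(omega=0.0, top_pct=1.0, nflank=0))
    if best_params.omega == 0.0:
        gebv_m, acc_m, bias_m = gebv_g, acc_g, bias_g
    else:
        gebv_m, acc_m, bias_m = _score(best_params)
    table = pd.DataFrame(
        {"individual_id": cand_ids, "gebv": gebv_m, "gebv_gblup": gebv_g}
    )
    return StageReport(
        stage="application",
        accuracy_gblup=acc_g,
        accuracy_model=acc_m,
        bias_gblup=bias_g,
        bias_model=bias_m,
        params=best_params,
        variance_components=ctx.varcomps,
        gebv=table,
    )
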