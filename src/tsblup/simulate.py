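"""Synthetic genotype/phenotype simulator.

Genotypes come from a per-chromosome AR(1) Gaussian copula: each gamete
is a latent first-order autoregressive normal sequence thresholded at
per-marker allele frequencies, and the dosage is the sum of two
independent gametes. This reproduces the qualitative
linkage-disequilibrium decay the flanking-SNP machinery needs without a
coalescent simulator.

True breeding values are linear in centered QTL dosages; residual
variance is set from the realized TBV variance in the reference sample
to hit the target heritability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .core import Dataset, GenotypeMatrix, MarkerMap
from .errors import ValidationError

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_genotypes",
    "simulate_qtl_effects",
    "simulate_phenotypes",
    "simulate_dataset",
    "preset",
    "PRESETS",
]


@dataclass(frozen=True)
class SimulationConfig:
    n_ref: int = 500
    n_cand: int = 0
    n_chrom: int = 5
    markers_per_chrom: int = 400
    n_qtl: int = 100
    effect_dist: str = "normal"  # or "gamma" (random-sign draws)
    gamma_shape: float = 0.4
    gamma_scale: float = 1.66
    h2: float = 0.5
    maf_min: float = 0.05
    ld_rho: float = 0.3
    seed: int = 0
    major_qtl_var: float | None = None  # fraction of genetic variance on one QTL
    mask_qtl: bool = False  # drop QTL columns from the analysis marker panel

    def __post_init__(self):
        if not 0.0 <= self.h2 <= 1.0:
            raise ValidationError(f"h2 must be in [0, 1], got {self.h2}")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValidationError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        if not 0.0 < self.maf_min < 0.5:
            raise ValidationError(f"maf_min must be in (0, 0.5), got {self.maf_min}")
        if self.n_qtl > self.n_chrom * self.markers_per_chrom:
            raise ValidationError("n_qtl exceeds the total number of markers")
        if self.effect_dist not in ("normal", "gamma"):
            raise ValidationError(f"unknown effect distribution {self.effect_dist!r}")
        if self.major_qtl_var is not None and not 0.0 < self.major_qtl_var < 1.0:
            raise ValidationError("major_qtl_var must be in (0, 1)")

    @property
    def n_markers(self) -> int:
        return self.n_chrom * self.markers_per_chrom

    @property
    def n_individuals(self) -> int:
        return self.n_ref + self.n_cand


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    marker_map: MarkerMap
    qtl_ids: np.ndarray
    qtl_effects: np.ndarray
    tbv: pd.Series  # all individuals
    phenotypes: pd.Series  # reference individuals only
    ref_ids: np.ndarray
    cand_ids: np.ndarray
    realized_h2: float
    config: SimulationConfig
    analysis_genotypes: GenotypeMatrix = field(init=False)
    analysis_map: MarkerMap = field(init=False)

    def __post_init__(self):
        if self.config.mask_qtl:
            keep = [m for m in self.genotypes.marker_ids if m not in set(self.qtl_ids)]
            self.analysis_genotypes = self.genotypes.subset_markers(keep)
            self.analysis_map = MarkerMap(
                self.marker_map.frame[
                    self.marker_map.frame["marker_id"].isin(keep)
                ].drop(columns="rank")
            )
        else:
            self.analysis_genotypes = self.genotypes
            self.analysis_map = self.marker_map

    def reference_dataset(self) -> Dataset:
        geno = self.analysis_genotypes.subset_individuals(self.ref_ids)
        return Dataset(
            genotypes=geno,
            marker_map=self.analysis_map,
            phenotypes=self.phenotypes,
            reference_values=self.tbv.loc[list(self.ref_ids)],
        )

    def candidate_dataset(self) -> Dataset:
        if len(self.cand_ids) == 0:
            raise ValidationError("no candidate individuals were simulated")
        geno = self.analysis_genotypes.subset_individuals(self.cand_ids)
        return Dataset(
            genotypes=geno,
            marker_map=self.analysis_map,
            phenotypes=pd.Series(dtype=float),
            reference_values=self.tbv.loc[list(self.cand_ids)],
        )


def _latent_rho(ld_rho: float) -> float:
    """Invert the arcsine attenuation so ld_rho approximates the adjacent
    dosage correlation (exact at allele frequency 0.5)."""
    return float(np.sin(0.5 * np.pi * ld_rho))


def _simulate_gametes(rng, n_gametes: int, thresholds: np.ndarray, rho: float) -> np.ndarray:
    """One chromosome worth of alleles for every gamete (AR(1) latent scale)."""
    m = thresholds.size
    eps = rng.standard_normal((n_gametes, m))
    z = np.empty_like(eps)
    z[:, 0] = eps[:, 0]
    if rho > 0:
        innov = np.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + innov * eps[:, j]
    else:
        z[:, 1:] = eps[:, 1:]
    return (z < thresholds).astype(np.int8)


def simulate_genotypes(config: SimulationConfig, rng=None):
    """Dosage matrix plus marker map; deterministic for a given config/seed."""
    from scipy.stats import norm

    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_individuals
    if n < 2:
        raise ValidationError("need at least 2 individuals")
    ids = [f"ref_{i + 1:05d}" for i in range(config.n_ref)] + [
        f"cand_{i + 1:05d}" for i in range(config.n_cand)
    ]
    dosages = np.empty((n, config.n_markers), dtype=float)
    marker_ids, chroms, positions = [], [], []
    col = 0
    for c in range(1, config.n_chrom + 1):
        m = config.markers_per_chrom
        freqs = rng.uniform(config.maf_min, 1.0 - config.maf_min, size=m)
        thresholds = norm.ppf(freqs)
        rho = _latent_rho(config.ld_rho)
        g1 = _simulate_gametes(rng, n, thresholds, rho)
        g2 = _simulate_gametes(rng, n, thresholds, rho)
        dosages[:, col : col + m] = g1 + g2
        marker_ids.extend(f"c{c}_m{j + 1:05d}" for j in range(m))
        chroms.extend([str(c)] * m)
        positions.extend((np.arange(m) + 1) * 1000)
        col += m
    genotypes = GenotypeMatrix(individual_ids=ids, marker_ids=marker_ids, dosages=dosages)
    marker_map = MarkerMap(
        pd.DataFrame({"marker_id": marker_ids, "chromosome": chroms, "position": positions})
    )
    return genotypes, marker_map


def simulate_qtl_effects(config: SimulationConfig, marker_ids, rng=None):
    """Sample QTL positions without replacement and additive effects.

    Gamma draws get an independent random sign with probability 0.5.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    ids = np.asarray(list(marker_ids), dtype=object)
    if config.n_qtl > ids.size:
        raise ValidationError("n_qtl exceeds the number of markers")
    qtl_ids = ids[np.sort(rng.choice(ids.size, size=config.n_qtl, replace=False))]
    if config.effect_dist == "normal":
        effects = rng.standard_normal(config.n_qtl)
    else:
        magnitudes = rng.gamma(config.gamma_shape, config.gamma_scale, size=config.n_qtl)
        signs = rng.choice([-1.0, 1.0], size=config.n_qtl)
        effects = magnitudes * signs
    return qtl_ids, effects


def simulate_phenotypes(
    genotypes: GenotypeMatrix, qtl_ids, qtl_effects, h2: float, rng, ref_ids=None
):
    """TBV for everyone, phenotype = TBV + scaled noise for the reference set.

    Residual variance is var(TBV_ref) * (1 - h2) / h2. h2 = 1 gives
    phenotype == TBV; h2 = 0 gives pure standard-normal noise (TBV still
    emitted for null testing).
    """
    if not 0.0 <= h2 <= 1.0:
        raise ValidationError(f"h2 must be in [0, 1], got {h2}")
    idx = genotypes.marker_index(qtl_ids)
    Q = genotypes.dosages[:, idx]
    Q = Q - Q.mean(axis=0)
    tbv_values = Q @ np.asarray(qtl_effects, dtype=float)
    tbv = pd.Series(tbv_values, index=genotypes.individual_ids)
    ref = list(ref_ids) if ref_ids is not None else list(genotypes.individual_ids)
    tbv_ref = tbv.loc[ref].to_numpy()
    if h2 == 0.0:
        phen = pd.Series(rng.standard_normal(len(ref)), index=ref)
        return tbv, phen
    var_tbv = float(np.var(tbv_ref, ddof=1))
    if var_tbv == 0:
        raise ValidationError("TBV variance is zero; cannot target a positive h2")
    if h2 == 1.0:
        phen = pd.Series(tbv_ref, index=ref)
    else:
        sd_e = np.sqrt(var_tbv * (1.0 - h2) / h2)
        phen = pd.Series(tbv_ref + sd_e * rng.standard_normal(len(ref)), index=ref)
    return tbv, phen


def _calibrate_major_qtl(genotypes, qtl_ids, effects, share, rng):
    """Fix one QTL's effect so it explains ``share`` of the genetic variance."""
    idx = genotypes.marker_index(qtl_ids)
    Q = genotypes.dosages[:, idx]
    Q = Q - Q.mean(axis=0)
    freqs = genotypes.dosages[:, idx].mean(axis=0) / 2.0
    major_pos = int(np.argmin(np.abs(freqs - 0.5)))  # mid-frequency locus: stable, informative
    minor = np.ones(len(qtl_ids), dtype=bool)
    minor[major_pos] = False
    tbv_minor = Q[:, minor] @ effects[minor]
    var_minor = float(np.var(tbv_minor, ddof=1))
    var_major_col = float(np.var(Q[:, major_pos], ddof=1))
    if var_minor == 0 or var_major_col == 0:
        raise ValidationError("degenerate genotypes; cannot calibrate the major QTL")
    target = share / (1.0 - share) * var_minor
    effects = effects.copy()
    effects[major_pos] = np.sqrt(target / var_major_col) * rng.choice([-1.0, 1.0])
    return effects, qtl_ids[major_pos]


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """End-to-end simulation driven by a single seed."""
    rng = np.random.default_rng(config.seed)
    genotypes, marker_map = simulate_genotypes(config, rng)
    qtl_ids, effects = simulate_qtl_effects(config, genotypes.marker_ids, rng)
    if config.major_qtl_var is not None:
        effects, _ = _calibrate_major_qtl(genotypes, qtl_ids, effects, config.major_qtl_var, rng)
    ref_ids = genotypes.individual_ids[: config.n_ref]
    cand_ids = genotypes.individual_ids[config.n_ref :]
    tbv, phen = simulate_phenotypes(genotypes, qtl_ids, effects, config.h2, rng, ref_ids)
    tbv_ref = tbv.loc[list(ref_ids)].to_numpy()
    var_p = float(np.var(phen.to_numpy(), ddof=1))
    realized_h2 = float(np.var(tbv_ref, ddof=1) / var_p) if var_p > 0 else float("nan")
    return SimulatedDataset(
        genotypes=genotypes,
        marker_map=marker_map,
        qtl_ids=qtl_ids,
        qtl_effects=effects,
        tbv=tbv,
        phenotypes=phen,
        ref_ids=ref_ids,
        cand_ids=cand_ids,
        realized_h2=realized_h2,
        config=config,
    )


PRESETS = {
    # 2000 reference + 1500 candidates, 900 gamma(0.4, 1.66) QTL, h2 = 0.25,
    # 60k-marker panel spread over 30 chromosomes.
    "gsa_gamma": SimulationConfig(
        n_ref=2000,
        n_cand=1500,
        n_chrom=30,
        markers_per_chrom=2000,
        n_qtl=900,
        effect_dist="gamma",
        gamma_shape=0.4,
        gamma_scale=1.66,
        h2=0.25,
        ld_rho=0.5,
    ),
    "gsa_normal": SimulationConfig(
        n_ref=2000,
        n_cand=1500,
        n_chrom=30,
        markers_per_chrom=2000,
        n_qtl=900,
        effect_dist="normal",
        h2=0.25,
        ld_rho=0.5,
    ),
    # 3000 training + 1000 validation, 5 chromosomes x 4000 SNPs, 50
    # gamma(0.42, 5.4) QTL.
    "qtlmas_like": SimulationConfig(
        n_ref=3000,
        n_cand=1000,
        n_chrom=5,
        markers_per_chrom=4000,
        n_qtl=50,
        effect_dist="gamma",
        gamma_shape=0.42,
        gamma_scale=5.4,
        h2=0.35,
        ld_rho=0.7,
    ),
    # One QTL pinned to 30% of genetic variance on top of 2999 small ones.
    "major_gene": SimulationConfig(
        n_ref=600,
        n_cand=300,
        n_chrom=3,
        markers_per_chrom=1000,
        n_qtl=3000,
        effect_dist="normal",
        h2=0.5,
        ld_rho=0.5,
        major_qtl_var=0.30,
    ),
    # Matched purely polygenic contrast: same genome, all-normal small effects.
    "polygenic": SimulationConfig(
        n_ref=600,
        n_cand=300,
        n_chrom=3,
        markers_per_chrom=1000,
        n_qtl=3000,
        effect_dist="normal",
        h2=0.5,
        ld_rho=0.5,
    ),
}


def preset(name: str, **overrides) -> SimulationConfig:
    """Named simulation design; keyword overrides adjust any field."""
    if name not in PRESETS:
        raise ValidationError(
            f"unknown preset {name!r}; valid presets: {', '.join(sorted(PRESETS))}"
        )
    cfg = PRESETS[name]
    return replace(cfg, **overrides) if overrides else cfg


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
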