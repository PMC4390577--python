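"""Core data containers: genotypes, marker maps, phenotypes, datasets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError

__all__ = ["GenotypeMatrix", "MarkerMap", "PhenotypeTable", "Dataset"]


def _as_str_array(values) -> np.ndarray:
    return np.asarray(list(values), dtype=object)


def _chrom_sort_key(label):
    """Natural chromosome ordering: numeric labels first, then lexicographic."""
    s = str(label)
    try:
        return (0, int(s), "")
    except ValueError:
        return (1, 0, s)


@dataclass
class GenotypeMatrix:
    """An n x m allele-dosage matrix with row (individual) and column (marker) IDs.

    Dosages count copies of the second allele, so every entry lies in
    [0, 2]; fractional values may appear after mean imputation of
    missing cells.
    """

    individual_ids: np.ndarray
    marker_ids: np.ndarray
    dosages: np.ndarray

    def __post_init__(self):
        self.individual_ids = _as_str_array(self.individual_ids)
        self.marker_ids = _as_str_array(self.marker_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.individual_ids):
            raise ValidationError(
                f"dosage rows ({n}) != number of individual ids ({len(self.individual_ids)})"
            )
        if m != len(self.marker_ids):
            raise ValidationError(
                f"dosage columns ({m}) != number of marker ids ({len(self.marker_ids)})"
            )
        if len(set(self.individual_ids)) != n:
            raise ValidationError("duplicate individual ids")
        if len(set(self.marker_ids)) != m:
            raise ValidationError("duplicate marker ids")
        if np.isnan(self.dosages).any():
            raise ValidationError("dosages contain missing values after load")
        if (self.dosages < 0).any() or (self.dosages > 2).any():
            raise ValidationError("dosages outside the closed interval [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def individual_index(self, ids) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.individual_ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise AlignmentError(f"unknown individual id {exc.args[0]!r}") from None

    def marker_index(self, ids) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.marker_ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise AlignmentError(f"unknown marker id {exc.args[0]!r}") from None

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        idx = self.individual_index(ids)
        return GenotypeMatrix(
            individual_ids=self.individual_ids[idx],
            marker_ids=self.marker_ids.copy(),
            dosages=self.dosages[idx, :].copy(),
        )

    def subset_markers(self, ids) -> "GenotypeMatrix":
        idx = self.marker_index(ids)
        return GenotypeMatrix(
            individual_ids=self.individual_ids.copy(),
            marker_ids=self.marker_ids[idx],
            dosages=self.dosages[:, idx].copy(),
        )

    def allele_frequencies(self) -> np.ndarray:
        """Observed second-allele frequency per marker (column mean / 2)."""
        return self.dosages.mean(axis=0) / 2.0

    @staticmethod
    def concat(a: "GenotypeMatrix", b: "GenotypeMatrix") -> "GenotypeMatrix":
        """Stack two genotype matrices (disjoint individuals, identical markers)."""
        if not np.array_equal(a.marker_ids, b.marker_ids):
            raise AlignmentError("marker ids/order differ between genotype matrices")
        overlap = set(a.individual_ids) & set(b.individual_ids)
        if overlap:
            raise ValidationError(f"overlapping individual ids: {sorted(overlap)[:5]}")
        return GenotypeMatrix(
            individual_ids=np.concatenate([a.individual_ids, b.individual_ids]),
            marker_ids=a.marker_ids.copy(),
            dosages=np.vstack([a.dosages, b.dosages]),
        )


@dataclass
class MarkerMap:
    """Ordered marker map: one row per marker with chromosome, position, rank.

    Rows are sorted by (chromosome, position); rank is the 0-based order
    within each chromosome. Positions must strictly increase within a
    chromosome.
    """

    frame: pd.DataFrame
    _pos: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self):
        required = {"marker_id", "chromosome", "position"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"marker map missing columns: {sorted(missing)}")
        df = self.frame.copy()
        df["chromosome"] = df["chromosome"].astype(str)
        df["position"] = df["position"].astype(np.int64)
        if (df["position"] < 0).any():
            raise ValidationError("marker positions must be non-negative")
        if df["marker_id"].duplicated().any():
            dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ValidationError(f"duplicate marker id in map: {dup!r}")
        if df.duplicated(subset=["chromosome", "position"]).any():
            row = df[df.duplicated(subset=["chromosome", "position"])].iloc[0]
            raise ValidationError(
                f"duplicate (chromosome, position): ({row['chromosome']}, {row['position']})"
            )
        df["_ckey"] = df["chromosome"].map(_chrom_sort_key)
        df = df.sort_values(["_ckey", "position"], kind="stable").drop(columns="_ckey")
        df["rank"] = df.groupby("chromosome", sort=False).cumcount()
        extra = [c for c in df.columns if c not in ("marker_id", "chromosome", "position", "rank")]
        self.frame = df.reset_index(drop=True)[
            ["marker_id", "chromosome", "position", "rank"] + extra
        ]
        self._pos = {mid: i for i, mid in enumerate(self.frame["marker_id"])}

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def marker_ids(self) -> np.ndarray:
        return _as_str_array(self.frame["marker_id"])

    def row_index(self, marker_id) -> int:
        try:
            return self._pos[marker_id]
        except KeyError:
            raise AlignmentError(f"marker {marker_id!r} not in map") from None

    def neighbors(self, marker_id, nflank: int) -> list:
        """IDs of the marker plus up to ``nflank`` adjacent markers per side,
        truncated at chromosome boundaries; ordered by map position."""
        i = self.row_index(marker_id)
        chrom = self.frame.at[i, "chromosome"]
        lo, hi = max(0, i - nflank), min(len(self.frame) - 1, i + nflank)
        rows = self.frame.iloc[lo : hi + 1]
        rows = rows[rows["chromosome"] == chrom]
        return list(rows["marker_id"])

    def check_alignment(self, genotypes: GenotypeMatrix) -> None:
        if not np.array_equal(self.marker_ids, genotypes.marker_ids):
            raise AlignmentError(
                "genotype marker order does not match the marker map order"
            )


@dataclass
class PhenotypeTable:
    """Long-format phenotype records (individual_id, trait, value)."""

    frame: pd.DataFrame

    def __post_init__(self):
        required = {"individual_id", "trait", "value"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"phenotype table missing columns: {sorted(missing)}")
        df = self.frame.copy()
        df["individual_id"] = df["individual_id"].astype(str)
        df["trait"] = df["trait"].astype(str)
        df["value"] = df["value"].astype(float)
        if df.duplicated(subset=["individual_id", "trait"]).any():
            row = df[df.duplicated(subset=["individual_id", "trait"])].iloc[0]
            raise ValidationError(
                f"more than one value for ({row['individual_id']}, {row['trait']})"
            )
        self.frame = df.reset_index(drop=True)

    @property
    def traits(self) -> list:
        return sorted(self.frame["trait"].unique())

    def values_for(self, trait: str | None = None) -> pd.Series:
        """Phenotype values for one trait as a Series indexed by individual."""
        if trait is None:
            traits = self.traits
            if len(traits) != 1:
                raise ValidationError(
                    f"trait must be named when the table holds {len(traits)} traits"
                )
            trait = traits[0]
        sub = self.frame[self.frame["trait"] == trait]
        if sub.empty:
            raise ValidationError(f"no records for trait {trait!r}")
        return pd.Series(
            sub["value"].to_numpy(), index=sub["individual_id"].to_numpy(), name=trait
        )


@dataclass
class Dataset:
    """Aligned bundle handed to the model-fitting and validation code.

    ``phenotypes`` holds the records used to train (indexed by
    individual id; individuals without a record are candidates).
    ``reference_values`` is what accuracy is computed against (EBV,
    deregressed phenotype, or simulated TBV); defaults to the phenotypes.
    """

    genotypes: GenotypeMatrix
    marker_map: MarkerMap
    phenotypes: pd.Series
    reference_values: pd.Series | None = None

    def __post_init__(self):
        self.marker_map.check_alignment(self.genotypes)
        known = set(self.genotypes.individual_ids)
        unknown = [i for i in self.phenotypes.index if i not in known]
        if unknown:
            raise AlignmentError(
                f"phenotyped individuals missing from genotypes: {unknown[:5]}"
            )
        if self.phenotypes.index.has_duplicates:
            raise ValidationError("duplicate individual in phenotype vector")

    @property
    def phenotyped_ids(self) -> np.ndarray:
        return _as_str_array(self.phenotypes.index)

    def evaluation_values(self) -> pd.Series:
        return self.reference_values if self.reference_values is not None else self.phenotypes
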