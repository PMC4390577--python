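"""Readers and writers for the delimited-text dialects used by the toolkit.

Supported inputs: dosage TSV (marker-ID header, individual IDs in the
first column), PLINK 1.x ``--recode A`` raw files, PLINK ``.map``-style
marker maps, and long/wide phenotype TSVs. Relationship matrices and
prediction tables round-trip losslessly at 17 significant digits.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, MarkerMap, PhenotypeTable
from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

_NA_TOKENS = ["NA", "na", "N/A", ".", "nan", "NaN", ""]
_DIALECTS = ("dosage-tsv", "plink-raw")

_FLOAT_FMT = "%.17g"


def _format_float(x: float) -> str:
    return _FLOAT_FMT % x


def _impute_mean(values: np.ndarray, marker_ids) -> np.ndarray:
    """Replace missing cells by the marker's mean observed dosage."""
    missing = np.isnan(values)
    n_missing = int(missing.sum())
    if n_missing == 0:
        return values
    for j in np.flatnonzero(missing.any(axis=0)):
        col = values[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise ValidationError(
                f"marker {marker_ids[j]!r} has no observed genotypes to impute from"
            )
        col[np.isnan(col)] = obs.mean()
    logger.info("imputed %d missing genotype cells to marker means", n_missing)
    return values


def _validate_dosage_tokens(values: np.ndarray, individual_ids, marker_ids) -> None:
    # integers outside {0,1,2} are genotype-coding errors; fractional values
    # inside [0,2] are accepted as previously imputed cells
    with np.errstate(invalid="ignore"):
        bad = ~np.isnan(values) & ((values < 0.0) | (values > 2.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"dosage {values[i, j]!r} for individual {individual_ids[i]!r} at marker "
            f"{marker_ids[j]!r} is not in {{0, 1, 2, missing}}"
        )


def read_genotypes(path, dialect: str = "dosage-tsv", impute: str = "mean") -> GenotypeMatrix:
    """Load a dosage matrix, imputing missing cells at load time.

    ``dialect`` is ``dosage-tsv`` (header row of marker IDs, first column
    individual IDs, tab separated) or ``plink-raw`` (PLINK ``--recode A``).
    """
    if dialect not in _DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if impute != "mean":
        raise ValidationError(f"unknown imputation rule {impute!r}")
    try:
        if dialect == "dosage-tsv":
            df = pd.read_csv(
                path, sep="\t", index_col=0, na_values=_NA_TOKENS,
                keep_default_na=False, float_precision="round_trip",
            )
            individual_ids = [str(i) for i in df.index]
            marker_ids = [str(c) for c in df.columns]
            values = df.to_numpy(dtype=float)
        else:
            df = pd.read_csv(
                path, sep=r"\s+", na_values=_NA_TOKENS, keep_default_na=False,
                float_precision="round_trip",
            )
            meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
            if list(df.columns[: len(meta)]) != meta:
                raise ParseError(
                    f"{path}: not a PLINK raw file (expected header starting {' '.join(meta)})"
                )
            individual_ids = [str(i) for i in df["IID"]]
            snp_cols = list(df.columns[len(meta) :])
            # PLINK suffixes each SNP column with the counted allele.
            marker_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
            values = df[snp_cols].to_numpy(dtype=float)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric dosage value ({exc})") from exc

    _validate_dosage_tokens(values, individual_ids, marker_ids)
    values = _impute_mean(values, marker_ids)
    return GenotypeMatrix(individual_ids=individual_ids, marker_ids=marker_ids, dosages=values)


def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    """Write a dosage TSV (integers stay integers, imputed cells keep precision)."""
    with open(path, "w") as fh:
        fh.write("individual_id\t" + "\t".join(genotypes.marker_ids) + "\n")
        for ind, row in zip(genotypes.individual_ids, genotypes.dosages):
            cells = [
                str(int(v)) if float(v).is_integer() else _format_float(v) for v in row
            ]
            fh.write(str(ind) + "\t" + "\t".join(cells) + "\n")


def read_marker_map(path) -> MarkerMap:
    """Read a 4-column PLINK ``.map``-style file (chrom, id, cM, position).

    The third column is ignored. Rows come back sorted by (chromosome,
    position) with 0-based per-chromosome ranks.
    """
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            names=["chromosome", "marker_id", "_cm", "position"],
            dtype={"chromosome": str, "marker_id": str},
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.isna().any().any():
        raise ParseError(f"{path}: marker map has missing fields")
    return MarkerMap(df.drop(columns="_cm"))


def write_marker_map(marker_map: MarkerMap, path) -> None:
    with open(path, "w") as fh:
        for _, row in marker_map.frame.iterrows():
            fh.write(f"{row['chromosome']}\t{row['marker_id']}\t0\t{row['position']}\n")


def read_phenotypes(path, trait: str | None = None) -> PhenotypeTable:
    """Read phenotypes from a TSV.

    Accepts either long format (individual_id, trait, value) or a wide
    two-column table (individual_id, <trait name>).
    """
    df = pd.read_csv(
        path, sep="\t", na_values=_NA_TOKENS, keep_default_na=False,
        float_precision="round_trip",
    )
    if {"individual_id", "trait", "value"} <= set(df.columns):
        table = df[["individual_id", "trait", "value"]]
    elif df.shape[1] == 2 and df.columns[0] == "individual_id":
        name = trait or df.columns[1]
        table = pd.DataFrame(
            {"individual_id": df["individual_id"], "trait": name, "value": df.iloc[:, 1]}
        )
    else:
        raise ParseError(
            f"{path}: expected columns (individual_id, trait, value) or a two-column table"
        )
    table = table.dropna(subset=["value"])
    return PhenotypeTable(table)


def write_phenotypes(values: pd.Series, path, trait: str = "trait") -> None:
    with open(path, "w") as fh:
        fh.write("individual_id\ttrait\tvalue\n")
        for ind, v in values.items():
            fh.write(f"{ind}\t{trait}\t{_format_float(v)}\n")


def write_predictions(table: pd.DataFrame, path) -> None:
    """Write a prediction table (individual_id, gebv[, trait...]) as TSV."""
    if "individual_id" not in table.columns or "gebv" not in table.columns:
        raise ValidationError("prediction table needs individual_id and gebv columns")
    out = table.copy()
    out["gebv"] = [_format_float(v) for v in out["gebv"].astype(float)]
    out.to_csv(path, sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "individual_id" not in df.columns or "gebv" not in df.columns:
        raise ParseError(f"{path}: not a prediction table")
    df["individual_id"] = df["individual_id"].astype(str)
    return df


def write_matrix(individual_ids, values: np.ndarray, path) -> None:
    """Export a symmetric matrix as full delimited text with an ID header
    row/column; values survive a round trip at 17 significant digits."""
    ids = [str(i) for i in individual_ids]
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(ids) + "\n")
        for ind, row in zip(ids, np.asarray(values, dtype=float)):
            fh.write(ind + "\t" + "\t".join(_format_float(v) for v in row) + "\n")


def read_matrix(path):
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    ids = np.asarray([str(i) for i in df.index], dtype=object)
    if not np.array_equal(ids, np.asarray([str(c) for c in df.columns], dtype=object)):
        raise ParseError(f"{path}: matrix row and column IDs differ")
    return ids, df.to_numpy(dtype=float)
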