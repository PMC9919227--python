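"""Reading, writing and validation of plot-level phenotype tables.

A phenotype table is a long-format :class:`pandas.DataFrame` with the key
columns ``genotype``, ``environment``, ``replicate`` followed by one column
per trait.  The same layout is used for simulated and field data, and for
genotype-mean tables (where ``environment``/``replicate`` are absent).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .reference import TRAITS

KEY_COLUMNS = ["genotype", "environment", "replicate"]

#: Traits that must be strictly positive in a valid table.
POSITIVE_TRAITS = {"SN", "SD", "IL", "SH", "SW", "Y", "SY"}

#: Percentage traits bounded in the open interval (0, 100).
PERCENT_TRAITS = {"B", "SC"}


class PhenotypeTableError(ValueError):
    """Raised when a phenotype table violates its structural invariants."""


def trait_columns(table: pd.DataFrame) -> list[str]:
    """Columns of ``table`` that hold trait values (everything non-key)."""
    return [c for c in table.columns if c not in KEY_COLUMNS]


def validate_phenotypes(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a plot-level phenotype table against its invariants.

    Checks key uniqueness, finiteness of all trait values, strict positivity
    of the size/weight/yield traits and the (0, 100) bound on percentage
    traits.  Returns the table unchanged so the call can be chained.

    Raises
    ------
    PhenotypeTableError
        If any invariant is violated; the message names the offending rows.
    """
    missing = [c for c in KEY_COLUMNS if c not in table.columns]
    if missing:
        raise PhenotypeTableError(f"missing key column(s): {missing}")
    dup = table.duplicated(subset=KEY_COLUMNS)
    if dup.any():
        keys = table.loc[dup, KEY_COLUMNS].to_records(index=False).tolist()
        raise PhenotypeTableError(f"duplicated (genotype, environment, replicate) keys: {keys[:5]}")
    for col in trait_columns(table):
        values = table[col]
        if not np.issubdtype(values.dtype, np.number):
            bad = values[pd.to_numeric(values, errors="coerce").isna()]
            raise PhenotypeTableError(
                f"non-numeric value in trait column {col!r} at row(s) {list(bad.index[:5])}"
            )
        if not np.isfinite(values.to_numpy(dtype=float)).all():
            bad = values.index[~np.isfinite(values.to_numpy(dtype=float))]
            raise PhenotypeTableError(f"non-finite value in trait column {col!r} at row(s) {list(bad[:5])}")
        if col in POSITIVE_TRAITS and (values <= 0).any():
            bad = values.index[values <= 0]
            raise PhenotypeTableError(f"trait {col!r} must be strictly positive; row(s) {list(bad[:5])}")
        if col in PERCENT_TRAITS and ((values <= 0) | (values >= 100)).any():
            bad = values.index[(values <= 0) | (values >= 100)]
            raise PhenotypeTableError(f"trait {col!r} must lie in (0, 100); row(s) {list(bad[:5])}")
    return table


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read and validate a phenotype table from CSV.

    The file must have a header row starting with the key columns.  Trait
    columns beyond the canonical set are preserved.  Non-numeric trait cells
    and duplicate keys are rejected with the offending row named.
    """
    raw = pd.read_csv(path)
    for col in trait_columns(raw):
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = raw.index[coerced.isna() & raw[col].notna()]
        if len(bad):
            raise PhenotypeTableError(
                f"non-numeric trait cell in column {col!r}, file row(s) "
                f"{[int(i) + 2 for i in bad[:5]]} of {path}"  # +2: header + 1-based
            )
        raw[col] = coerced
    return validate_phenotypes(raw)


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    """Write a phenotype table to CSV, lossless to 10+ significant digits."""
    ordered = KEY_COLUMNS + [c for c in TRAITS if c in table.columns]
    extras = [c for c in table.columns if c not in ordered]
    table.loc[:, ordered + extras].to_csv(path, index=False, float_format="%.12g")


def genotype_means(table: pd.DataFrame, per_environment: bool = False) -> pd.DataFrame:
    """Genotype-mean trait matrix from a plot-level table.

    By default replicates and environments are pooled, giving one row per
    genotype (the convention used for the diversity, correlation, clustering
    and selection analyses).  With ``per_environment=True`` the means are kept
    separate per environment (multi-indexed rows).
    """
    cols = trait_columns(table)
    by = ["genotype", "environment"] if per_environment else ["genotype"]
    return table.groupby(by, sort=True)[cols].mean()
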