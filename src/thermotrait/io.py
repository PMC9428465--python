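"""CSV readers/writers for the pipeline's table dialects.

All tables travel as plain RFC-4180 CSV with a header row.  Temperatures
are stored in degrees Celsius everywhere; Kelvin appears only inside the
thermal-model evaluation.  Readers validate the schema (missing required
columns raise a SchemaError naming them; extra columns are dropped with a
warning; non-numeric values raise a ParseError carrying the file line
number) and an empty data section raises EmptyInputError rather than
returning a bare frame.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class ParseError(ValueError):
    """A cell failed to parse; message carries the 1-based file line number."""


class EmptyInputError(ValueError):
    """The file has a header but no data rows."""


PLATE_SCHEMA = dict(
    required=["taxon", "temp_c", "replicate", "time_h", "od600", "is_blank"],
    numeric=["temp_c", "time_h", "od600"],
    integer=["replicate"],
    boolean=["is_blank"],
)
RATES_SCHEMA = dict(
    required=["taxon", "temp_c", "mean_r_per_h", "n_reps_used"],
    numeric=["temp_c", "mean_r_per_h"],
    integer=["n_reps_used"],
    boolean=[],
)
TRAITS_SCHEMA = dict(
    required=["taxon", "ea_ev", "eh_ev", "th_k", "ln_r_tc", "topt_c", "aic",
              "quasi_r2", "n_temps_used"],
    numeric=["ea_ev", "eh_ev", "th_k", "ln_r_tc", "topt_c", "aic", "quasi_r2"],
    integer=["n_temps_used"],
    boolean=[],
)
COUNTS_SCHEMA = dict(
    required=["temp_c", "replicate", "taxon", "count"],
    numeric=["temp_c"],
    integer=["replicate", "count"],
    boolean=[],
)
DIVERSITY_SCHEMA = dict(
    required=["temp_c", "replicate", "richness", "shannon_h", "pielou_j"],
    numeric=["temp_c", "shannon_h", "pielou_j"],
    integer=["replicate", "richness"],
    boolean=[],
)
ABUND_SCHEMA = dict(
    required=["temp_c", "replicate", "taxon", "rel_abund"],
    numeric=["temp_c", "rel_abund"],
    integer=["replicate"],
    boolean=[],
)
BIOMASS_SCHEMA = dict(
    required=["temp_c", "replicate", "biomass_od"],
    numeric=["temp_c", "biomass_od"],
    integer=["replicate"],
    boolean=[],
)

_TRUTHY = {"true", "1", "yes"}
_FALSY = {"false", "0", "no"}


def _read_csv(path, schema) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in schema["required"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in schema["required"]]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", path, extra)
        df = df[schema["required"]]
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")

    def numeric(col, as_int=False):
        raw = df[col].replace({"": np.nan, "NA": np.nan, "nan": np.nan})
        values = pd.to_numeric(raw, errors="coerce")
        bad = values.isna() & raw.notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ParseError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in "
                f"column {col!r} at line {line}")
        if as_int:
            if values.notna().all() and not np.allclose(values % 1, 0):
                raise ParseError(f"{path}: column {col!r} must be integral")
            return values.astype("int64") if values.notna().all() else values
        return values.astype(float)

    out = {}
    for col in schema["required"]:
        if col in schema["numeric"]:
            out[col] = numeric(col)
        elif col in schema["integer"]:
            out[col] = numeric(col, as_int=True)
        elif col in schema["boolean"]:
            lowered = df[col].str.strip().str.lower()
            unknown = ~lowered.isin(_TRUTHY | _FALSY)
            if unknown.any():
                line = int(unknown.idxmax()) + 2
                raise ParseError(f"{path}: unparseable boolean in column "
                                 f"{col!r} at line {line}")
            out[col] = lowered.isin(_TRUTHY)
        else:
            out[col] = df[col]
    return pd.DataFrame(out)


def read_plate_csv(path) -> pd.DataFrame:
    """Read a plate-series CSV (taxon,temp_c,replicate,time_h,od600,is_blank)."""
    return _read_csv(path, PLATE_SCHEMA)


def read_rates_csv(path) -> pd.DataFrame:
    return _read_csv(path, RATES_SCHEMA)


def read_traits_csv(path) -> pd.DataFrame:
    return _read_csv(path, TRAITS_SCHEMA)


def read_counts_csv(path) -> pd.DataFrame:
    return _read_csv(path, COUNTS_SCHEMA)


def read_diversity_csv(path) -> pd.DataFrame:
    return _read_csv(path, DIVERSITY_SCHEMA)


def read_abundance_csv(path) -> pd.DataFrame:
    return _read_csv(path, ABUND_SCHEMA)


def read_biomass_csv(path) -> pd.DataFrame:
    return _read_csv(path, BIOMASS_SCHEMA)


def write_csv(df: pd.DataFrame, path) -> None:
    """Write any pipeline table as RFC-4180 CSV (LF line endings, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")
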