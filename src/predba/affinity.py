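"""Affinity records, the Kd -> ΔG conversion, and feature/affinity tables.

ΔG = -R·T·ln(Kd) with R = 1.987e-3 kcal/(mol·K).  As printed, this yields a
positive dissociation free energy for Kd < 1 M; values are stored exactly as
the formula produces them and never re-signed.

Tables are UTF-8 TSV with '.' decimals and "NA" as the missing marker.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalogue import FEATURE_CATALOGUE

logger = logging.getLogger(__name__)

GAS_CONSTANT = 1.987e-3  # kcal / (mol K)
STANDARD_TEMPERATURE = 298.15  # K
NA_MARKER = "NA"


def delta_g_from_kd(kd: float, temperature: float) -> float:
    """Dissociation Gibbs free energy (kcal/mol) from Kd (M) and T (K)."""
    if kd <= 0:
        raise ValueError(f"kd must be positive, got {kd}")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return -GAS_CONSTANT * temperature * math.log(kd)


@dataclass
class AffinityRecord:
    complex_id: str
    temperature: float  # K
    kd: float | None = None  # M
    delta_g: float | None = None  # kcal/mol

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError(f"{self.complex_id}: temperature must be positive")
        if self.kd is None and self.delta_g is None:
            raise ValueError(f"{self.complex_id}: need kd or delta_g")
        if self.kd is not None and self.kd <= 0:
            raise ValueError(f"{self.complex_id}: kd must be positive")
        if self.delta_g is None:
            self.delta_g = delta_g_from_kd(self.kd, self.temperature)


def _cell(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return float(value)


def read_affinity_table(path) -> list[AffinityRecord]:
    """Read a TSV of complex_id / temperature / kd / delta_g rows.

    A missing temperature defaults to 298.15 K (with a warning); delta_g is
    filled from kd where absent.
    """
    df = pd.read_csv(path, sep="\t", na_values=[NA_MARKER], dtype={"complex_id": str})
    if "complex_id" not in df.columns:
        raise ValueError("affinity table: missing complex_id column")
    dupes = df["complex_id"][df["complex_id"].duplicated()]
    if not dupes.empty:
        raise ValueError(f"affinity table: duplicate complex_id {dupes.iloc[0]!r}")
    records = []
    for _, row in df.iterrows():
        temperature = _cell(row.get("temperature"))
        if temperature is None:
            logger.warning(
                "%s: missing temperature, defaulting to %.2f K",
                row["complex_id"], STANDARD_TEMPERATURE,
            )
            temperature = STANDARD_TEMPERATURE
        records.append(
            AffinityRecord(
                complex_id=row["complex_id"],
                temperature=temperature,
                kd=_cell(row.get("kd")),
                delta_g=_cell(row.get("delta_g")),
            )
        )
    return records


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature TSV indexed by complex_id.

    Unknown columns (not in the 52-feature catalogue) are preserved but
    flagged with a warning; non-numeric cells in numeric columns raise with
    the row and column named.
    """
    df = pd.read_csv(path, sep="\t", na_values=[NA_MARKER], dtype={"complex_id": str})
    if "complex_id" not in df.columns:
        raise ValueError("feature table: missing complex_id column")
    dupes = df["complex_id"][df["complex_id"].duplicated()]
    if not dupes.empty:
        raise ValueError(f"feature table: duplicate complex_id {dupes.iloc[0]!r}")
    df = df.set_index("complex_id")
    unknown = [c for c in df.columns if c not in FEATURE_CATALOGUE]
    if unknown:
        logger.warning("feature table: columns outside the catalogue: %s", unknown)
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].notna() & coerced.isna()
            if bad.any():
                row_id = df.index[bad][0]
                raise ValueError(
                    f"feature table: non-numeric value "
                    f"{df.loc[row_id, col]!r} in column {col!r}, row {row_id!r}"
                )
            df[col] = coerced
    return df


def write_feature_table(df: pd.DataFrame, path) -> None:
    """Write a feature table as TSV ('.' decimals, NA for missing)."""
    out = df.copy()
    out.index.name = "complex_id"
    out.to_csv(path, sep="\t", na_rep=NA_MARKER)


def join_features_affinity(
    features: pd.DataFrame, records: list[AffinityRecord]
) -> tuple[pd.DataFrame, np.ndarray]:
    """Align feature rows with affinity records on complex_id.

    Every affinity record must match a feature row; returns the aligned
    feature frame and the ΔG vector in the same row order.
    """
    ids = [r.complex_id for r in records]
    missing = [i for i in ids if i not in features.index]
    if missing:
        raise ValueError(f"no feature row for complex ids: {missing}")
    X = features.loc[ids]
    y = np.array([r.delta_g for r in records], dtype=float)
    return X, y
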