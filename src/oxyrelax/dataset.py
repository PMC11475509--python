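"""Curated oxygen-relaxivity measurements: loading, validation, conversion.

The bundled dataset collects 28 literature measurements of the
relaxivity of dissolved oxygen (r1Ox) in water, saline, vitreous fluid
and blood plasma, spanning 0.011-8.45 T and 21-40 degC.  Relaxivities
are stored on the 1e-4 s^-1/mmHg scale.  Blood and tissue measurements
are outside the scope of the fitted model (proteins, cells and
deoxyhemoglobin change the R1/pO2 relationship) and are excluded from
the default fit set by material.

CSV schema (UTF-8, comma-delimited, header row)::

    reference,r1ox_1e4,b0_tesla,temp_celsius,material,temperature_assumed[,comments]

``temperature_assumed`` marks records whose source did not report the
sample temperature (assumed 37 degC by the compilers); the flag enables
sensitivity re-runs that exclude them.
"""

from __future__ import annotations

import importlib.resources
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .core import ConditionPoint

__all__ = [
    "MATERIALS",
    "FIT_MATERIALS",
    "RelaxivityRecord",
    "Dataset",
    "SchemaError",
    "load_dataset",
    "load_table1",
    "save_dataset",
    "summarize_dataset",
    "convert_pressure",
    "TABLE1_ERRATA",
]

logger = logging.getLogger(__name__)

MATERIALS = frozenset(
    {"water", "saline", "vitreous", "plasma", "blood", "tissue", "other"}
)

#: Materials included in the dispersion-model fit: simple fluids only.
FIT_MATERIALS = frozenset({"water", "saline", "vitreous", "plasma"})

REQUIRED_COLUMNS = (
    "reference",
    "r1ox_1e4",
    "b0_tesla",
    "temp_celsius",
    "material",
    "temperature_assumed",
)

#: Documented errata for the bundled literature table, keyed by 0-based row
#: index.  The single entry corrects a transposed-digit field strength in the
#: Graf dispersion series (printed 0.159 T; the row sits between the 0.713 and
#: 2.139 T rows of the otherwise field-ordered series, and only 1.059 T is
#: consistent with the series' monotone dispersion and with the published fit).
TABLE1_ERRATA: dict[int, dict[str, float]] = {19: {"b0_tesla": 1.059}}


class SchemaError(ValueError):
    """A dataset file violates the CSV schema; the message names row and column."""


@dataclass(frozen=True)
class RelaxivityRecord:
    """One literature (or synthetic) relaxivity measurement.

    r1ox is on the 1e-4 s^-1/mmHg scale; b0 in tesla; temperature in degC.
    """

    reference: str
    r1ox: float
    b0: float
    temperature: float
    material: str
    temperature_assumed: bool = False
    comments: str = ""

    def __post_init__(self) -> None:
        if self.r1ox <= 0:
            raise ValueError(f"r1ox must be positive, got {self.r1ox}")
        if self.b0 < 0:
            raise ValueError(f"b0 must be non-negative, got {self.b0}")
        if not 0 <= self.temperature <= 100:
            raise ValueError(
                f"temperature must be within [0, 100] C, got {self.temperature}"
            )
        if self.material not in MATERIALS:
            raise ValueError(
                f"unknown material {self.material!r}; expected one of "
                f"{sorted(MATERIALS)}"
            )

    @property
    def condition(self) -> ConditionPoint:
        return ConditionPoint(self.b0, self.temperature)


@dataclass(frozen=True)
class Dataset:
    """An ordered collection of relaxivity records with a label.

    Unit system is fixed: r1ox 1e-4 s^-1/mmHg, b0 tesla, temperature degC.
    """

    records: tuple[RelaxivityRecord, ...]
    name: str = "dataset"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[RelaxivityRecord]:
        return iter(self.records)

    @property
    def r1ox(self) -> np.ndarray:
        return np.array([r.r1ox for r in self.records], dtype=float)

    @property
    def b0(self) -> np.ndarray:
        return np.array([r.b0 for r in self.records], dtype=float)

    @property
    def temperature(self) -> np.ndarray:
        return np.array([r.temperature for r in self.records], dtype=float)

    @property
    def material(self) -> np.ndarray:
        return np.array([r.material for r in self.records])

    def filter(self, materials: Iterable[str]) -> "Dataset":
        materials = set(materials)
        unknown = materials - MATERIALS
        if unknown:
            raise ValueError(f"unknown materials: {sorted(unknown)}")
        kept = tuple(r for r in self.records if r.material in materials)
        return replace(self, records=kept)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reference": [r.reference for r in self.records],
                "r1ox_1e4": [r.r1ox for r in self.records],
                "b0_tesla": [r.b0 for r in self.records],
                "temp_celsius": [r.temperature for r in self.records],
                "material": [r.material for r in self.records],
                "temperature_assumed": [r.temperature_assumed for r in self.records],
                "comments": [r.comments for r in self.records],
            }
        )


def _records_from_frame(frame: pd.DataFrame) -> tuple[RelaxivityRecord, ...]:
    records = []
    for idx, row in frame.iterrows():
        for col in ("r1ox_1e4", "b0_tesla", "temp_celsius"):
            value = pd.to_numeric(pd.Series([row[col]]), errors="coerce").iloc[0]
            if pd.isna(value):
                raise SchemaError(
                    f"row {idx}: column {col!r} is not numeric ({row[col]!r})"
                )
        assumed = row["temperature_assumed"]
        if isinstance(assumed, str):
            lowered = assumed.strip().lower()
            if lowered not in {"true", "false"}:
                raise SchemaError(
                    f"row {idx}: column 'temperature_assumed' must be "
                    f"true/false, got {assumed!r}"
                )
            assumed = lowered == "true"
        comments = row.get("comments", "")
        if pd.isna(comments):
            comments = ""
        try:
            records.append(
                RelaxivityRecord(
                    reference=str(row["reference"]),
                    r1ox=float(row["r1ox_1e4"]),
                    b0=float(row["b0_tesla"]),
                    temperature=float(row["temp_celsius"]),
                    material=str(row["material"]).strip().lower(),
                    temperature_assumed=bool(assumed),
                    comments=str(comments),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"row {idx}: {exc}") from exc
    return tuple(records)


def load_dataset(path, material_filter: Iterable[str] | None = None,
                 name: str | None = None) -> Dataset:
    """Load a relaxivity dataset from CSV, validating every row.

    Out-of-range or malformed rows raise :class:`SchemaError` naming the
    offending row and column.  ``material_filter`` is applied after
    validation.  An empty (header-only) file loads as an empty dataset
    with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype={"reference": str, "material": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    records = _records_from_frame(frame)
    if not records:
        logger.warning("dataset %s is empty (header only)", path)
    ds = Dataset(records=records, name=name or path.stem)
    if material_filter is not None:
        ds = ds.filter(material_filter)
    return ds


def load_table1(corrected: bool = True,
                material_filter: Iterable[str] | None = None) -> Dataset:
    """Load the bundled 28-measurement literature compilation.

    With ``corrected=True`` (default) the documented errata in
    :data:`TABLE1_ERRATA` are applied — currently the single transposed
    field strength in the Graf series (0.159 -> 1.059 T); the affected
    row carries the full explanation in its ``comments`` field.  With
    ``corrected=False`` the table is returned exactly as printed in the
    source compilation.
    """
    resource = importlib.resources.files("oxyrelax.data") / "table1.csv"
    with importlib.resources.as_file(resource) as path:
        ds = load_dataset(path, name="table1")
    if corrected:
        records = list(ds.records)
        for idx, fixes in TABLE1_ERRATA.items():
            updates = {
                {"b0_tesla": "b0", "r1ox_1e4": "r1ox", "temp_celsius": "temperature"}[k]: v
                for k, v in fixes.items()
            }
            records[idx] = replace(records[idx], **updates)
        ds = replace(ds, records=tuple(records), name="table1-corrected")
    if material_filter is not None:
        ds = ds.filter(material_filter)
    return ds


def save_dataset(ds: Dataset, path) -> None:
    """Write a dataset to the standard CSV schema."""
    frame = ds.to_frame()
    frame["temperature_assumed"] = frame["temperature_assumed"].map(
        {True: "true", False: "false"}
    )
    frame.to_csv(path, index=False)


def summarize_dataset(ds: Dataset) -> dict:
    """Counts per material plus field-strength and temperature ranges."""
    if len(ds) == 0:
        raise ValueError("cannot summarize an empty dataset")
    materials, counts = np.unique(ds.material, return_counts=True)
    return {
        "n": len(ds),
        "materials": {m: int(c) for m, c in zip(materials, counts)},
        "b0_range": (float(ds.b0.min()), float(ds.b0.max())),
        "temperature_range": (float(ds.temperature.min()), float(ds.temperature.max())),
        "n_temperature_assumed": int(sum(r.temperature_assumed for r in ds)),
    }


# Pressure-unit conversion: exact linear factors to mmHg.
# 1 atm = 760 mmHg = 101.325 kPa by definition; Torr == mmHg at this precision.
_TO_MMHG = {
    "mmHg": 1.0,
    "Torr": 1.0,
    "kPa": 760.0 / 101.325,
    "atm": 760.0,
}


def convert_pressure(value, from_unit: str, to_unit: str):
    """Convert an oxygen partial pressure between mmHg, Torr, kPa and atm."""
    try:
        factor_in = _TO_MMHG[from_unit]
    except KeyError:
        raise ValueError(f"unknown pressure unit {from_unit!r}") from None
    try:
        factor_out = _TO_MMHG[to_unit]
    except KeyError:
        raise ValueError(f"unknown pressure unit {to_unit!r}") from None
    out = np.asarray(value, dtype=float) * (factor_in / factor_out)
    return out if out.ndim else float(out)
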