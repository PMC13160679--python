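"""Tabular I/O, domain records and run configuration.

All files are plain CSV (comma-separated, UTF-8, one header row,
lower-snake-case column names). Times are stored in minutes at the file
level — matching the sampling schedule of the labeling assay — and
converted to hours exactly once, downstream, because every rate in the
analysis is expressed per hour.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import pandas as pd
import yaml


class SchemaError(ValueError):
    """A table is missing a required column or has an unusable layout."""


class ValidationError(ValueError):
    """A row violates a record invariant; the message names the row."""


#: fraction tokens accepted in intensity tables
FRACTIONS = frozenset(
    {"soluble", "protein", "total", "cytosol_B", "vacuole_C", "medium", "cell_pellet"}
)
#: fractions that enter renewal-fraction computation (labeling rows)
LABELING_FRACTIONS = frozenset({"soluble", "protein", "total"})

INTENSITY_COLUMNS = [
    "sample_id",
    "genotype",
    "replicate",
    "analyte",
    "fraction",
    "time_min",
    "intensity_light",
    "intensity_heavy",
]
STANDARD_COLUMNS = ["analyte", "concentration_mM", "intensity_light", "intensity_heavy"]
GROWTH_COLUMNS = ["sample_id", "time_min", "od600"]
CUCL2_COLUMNS = [
    "sample_id",
    "genotype",
    "analyte",
    "fraction",
    "intensity_analyte",
    "intensity_marker",
]


@dataclass(frozen=True)
class AnalyteID:
    """Identity of a light/heavy isotopologue pair (e.g. lysine, arginine)."""

    name: str
    light_mz: float | None = None
    heavy_mz: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("analyte name must be non-empty")
        if (
            self.light_mz is not None
            and self.heavy_mz is not None
            and self.light_mz == self.heavy_mz
        ):
            raise ValidationError(
                f"analyte {self.name!r}: light and heavy m/z must differ"
            )


@dataclass(frozen=True)
class IntensityRecord:
    """One light/heavy MS intensity pair for an analyte in one sample."""

    sample_id: str
    genotype: str
    replicate: int
    analyte: AnalyteID
    fraction: str
    time_min: float
    intensity_light: float
    intensity_heavy: float

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise ValidationError(f"unknown fraction token {self.fraction!r}")
        if self.replicate < 1:
            raise ValidationError("replicate must be a positive integer")
        if self.time_min < 0:
            raise ValidationError("time_min must be >= 0")
        if self.intensity_light < 0 or self.intensity_heavy < 0:
            raise ValidationError("intensities must be >= 0")
        if (
            self.fraction in LABELING_FRACTIONS
            and self.intensity_light + self.intensity_heavy <= 0
        ):
            raise ValidationError(
                "labeling row has zero total intensity (light + heavy = 0)"
            )


@dataclass(frozen=True)
class StandardRecord:
    """One level of an equimolar light/heavy calibration dilution series."""

    analyte: AnalyteID
    concentration_mM: float
    intensity_light: float
    intensity_heavy: float

    def __post_init__(self) -> None:
        if self.concentration_mM <= 0:
            raise ValidationError("standard concentration must be > 0")
        if self.intensity_light <= 0 or self.intensity_heavy <= 0:
            raise ValidationError("standard intensities must be > 0")


@dataclass(frozen=True)
class GrowthPoint:
    """One turbidity (OD600) reading of a culture."""

    sample_id: str
    time_min: float
    od600: float

    def __post_init__(self) -> None:
        if self.time_min < 0:
            raise ValidationError("time_min must be >= 0")
        if self.od600 <= 0:
            raise ValidationError("od600 must be > 0")


@dataclass
class RunConfig:
    """Analysis configuration; every printed constant of the method is a
    default here, never hard-coded at a use site.

    Bounds are in h^-1. ``s1_cyto`` is the nominal weight of the cytosolic
    pool (small by assumption). ``calibration_convention`` selects how
    equimolar-standard ratios become response weights; see
    :mod:`vacflux.labeling`.
    """

    time_points_min: list[float] = field(default_factory=lambda: [0.0, 20.0, 60.0, 120.0])
    s1_cyto: float = 0.01
    bounds_k_ve: tuple[float, float] = (0.01, 10.0)
    bounds_k_pd: tuple[float, float] = (0.01, 0.05)
    bounds_mu: tuple[float, float] = (0.3, 0.45)
    calibration_convention: str = "inverse_response"
    regression_intercept: bool = False
    epsilon_fraction_floor: float = 1e-6
    multistart_grid: int = 5
    multistart_refine: int = 5
    k_tot_literal_product: bool = False
    renormalize_pools: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bounds_k_ve", "bounds_k_pd", "bounds_mu"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"{name} must be a proper interval, got ({lo}, {hi})")
        if self.calibration_convention not in ("inverse_response", "as_printed"):
            raise ValidationError(
                f"unknown calibration_convention {self.calibration_convention!r}"
            )
        if not 0 < self.s1_cyto < 1:
            raise ValidationError("s1_cyto must be in (0, 1)")
        if self.multistart_grid < 1 or self.multistart_refine < 1:
            raise ValidationError("multistart settings must be >= 1")


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from YAML; absent keys keep their defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    for key in ("bounds_k_ve", "bounds_k_pd", "bounds_mu"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    for key in ("bounds_k_ve", "bounds_k_pd", "bounds_mu"):
        data[key] = list(data[key])
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    return df


def read_intensity_table(
    path: str | Path, config: RunConfig | None = None
) -> list[IntensityRecord]:
    """Read and validate an intensity table.

    Every row is checked against the record invariants; a bad row raises
    :class:`ValidationError` naming its (1-based, header-excluded) row
    number rather than being dropped. When ``config`` is given, labeling
    rows must sit on the configured time schedule.
    """
    df = _read_csv(path, INTENSITY_COLUMNS)
    schedule = set(config.time_points_min) if config is not None else None
    records: list[IntensityRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            rec = IntensityRecord(
                sample_id=str(row.sample_id),
                genotype=str(row.genotype),
                replicate=int(row.replicate),
                analyte=AnalyteID(str(row.analyte)),
                fraction=str(row.fraction),
                time_min=float(row.time_min),
                intensity_light=float(row.intensity_light),
                intensity_heavy=float(row.intensity_heavy),
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
        if (
            schedule is not None
            and rec.fraction in LABELING_FRACTIONS
            and rec.time_min not in schedule
        ):
            raise ValidationError(
                f"row {i}: time {rec.time_min} min not in the configured "
                f"schedule {sorted(schedule)}"
            )
        records.append(rec)
    return records


def read_standards_table(path: str | Path) -> list[StandardRecord]:
    df = _read_csv(path, STANDARD_COLUMNS)
    records: list[StandardRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                StandardRecord(
                    analyte=AnalyteID(str(row.analyte)),
                    concentration_mM=float(row.concentration_mM),
                    intensity_light=float(row.intensity_light),
                    intensity_heavy=float(row.intensity_heavy),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
    return records


def read_growth_table(path: str | Path) -> list[GrowthPoint]:
    """Read OD600 series; per-culture points sorted by time, duplicates rejected."""
    df = _read_csv(path, GROWTH_COLUMNS)
    records: list[GrowthPoint] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                GrowthPoint(
                    sample_id=str(row.sample_id),
                    time_min=float(row.time_min),
                    od600=float(row.od600),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
    seen: set[tuple[str, float]] = set()
    for rec in records:
        key = (rec.sample_id, rec.time_min)
        if key in seen:
            raise ValidationError(f"duplicate growth point for {key}")
        seen.add(key)
    records.sort(key=lambda r: (r.sample_id, r.time_min))
    return records


def read_cucl2_table(path: str | Path) -> pd.DataFrame:
    """Read a CuCl2 permeabilization table (fractions ``cytosol_B``/``vacuole_C``)."""
    df = _read_csv(path, CUCL2_COLUMNS)
    bad = ~df["fraction"].isin(["cytosol_B", "vacuole_C"])
    if bad.any():
        raise ValidationError(
            f"rows {list(df.index[bad] + 1)}: fraction must be cytosol_B or vacuole_C"
        )
    if (df["intensity_marker"] <= 0).any():
        raise ValidationError("marker intensity must be > 0 in every row")
    return df


def intensity_records_to_frame(records: Iterable[IntensityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "genotype": r.genotype,
                "replicate": r.replicate,
                "analyte": r.analyte.name,
                "fraction": r.fraction,
                "time_min": r.time_min,
                "intensity_light": r.intensity_light,
                "intensity_heavy": r.intensity_heavy,
            }
            for r in records
        ],
        columns=INTENSITY_COLUMNS,
    )


def write_intensity_table(records: Iterable[IntensityRecord], path: str | Path) -> None:
    intensity_records_to_frame(records).to_csv(path, index=False)


def write_standards_table(records: Iterable[StandardRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "analyte": r.analyte.name,
                "concentration_mM": r.concentration_mM,
                "intensity_light": r.intensity_light,
                "intensity_heavy": r.intensity_heavy,
            }
            for r in records
        ],
        columns=STANDARD_COLUMNS,
    ).to_csv(path, index=False)


def write_growth_table(records: Iterable[GrowthPoint], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"sample_id": r.sample_id, "time_min": r.time_min, "od600": r.od600}
            for r in records
        ],
        columns=GROWTH_COLUMNS,
    ).to_csv(path, index=False)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "tolist"):  # numpy scalars and arrays
        return obj.tolist()
    return obj


def write_results(results: Any, path: str | Path) -> None:
    """Serialize pipeline outputs (dataclasses, dicts, arrays) to JSON.

    Floats are written at full repr precision so a re-read reproduces every
    numeric field exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(results), fh, indent=2)
        fh.write("\n")


def read_results(path: str | Path) -> Any:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
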