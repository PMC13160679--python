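"""Isotopologue response-factor calibration and renewal fractions.

The light ("old") fraction of an analyte is computed from the integrated
light/heavy MS intensities as

    f = w_L * I_L / (w_L * I_L + w_H * I_H)

where the response weights w_L, w_H (w_L + w_H = 1) are calibrated from
equimolar light/heavy dilution series. Two conventions are implemented:

``inverse_response`` (default)
    w_L / w_H = 1 / mean(I*_L / I*_H). The weights compensate the
    instrument's per-isotopologue response, so the equimolar standard
    itself maps to f = 0.5 exactly — the self-consistency check the
    bracketing standards exist to provide.

``as_printed``
    w_L / w_H = mean(I*_L / I*_H): the larger weight goes to the
    stronger-responding isotopologue, so the equimolar standard maps to
    0.5 only when responses are equal. Kept for comparison; most plausibly
    a subscript transposition in the method write-up.

Also implements the CuCl2 plasma-membrane permeabilization readout:
f_vac = 1 - R_b/R_c, a conservative lower bound on the vacuolar share of
a soluble amino-acid pool (some vacuoles break during the treatment).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .tables_io import (
    AnalyteID,
    IntensityRecord,
    LABELING_FRACTIONS,
    StandardRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

RENEWAL_COLUMNS = ["genotype", "replicate", "analyte", "fraction", "time_h", "f"]


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class ResponseFactors:
    """Calibrated per-analyte signal response weights (w_light + w_heavy = 1)."""

    analyte: AnalyteID
    w_light: float
    w_heavy: float
    mean_standard_ratio: float
    convention: str
    ratio_cv: float = float("nan")
    n_levels: int = 0


@dataclass(frozen=True)
class RenewalPoint:
    """Calibrated light ("old") fraction of an analyte at one labeling time."""

    genotype: str
    replicate: int
    analyte: AnalyteID
    fraction: str
    time_h: float
    f: float


@dataclass(frozen=True)
class VacuolarFraction:
    """CuCl2-derived vacuolar share of a soluble pool (conservative lower bound).

    ``f_vac_raw`` keeps the unclipped value; ``f_vac`` is clipped to [0, 1].
    """

    sample_id: str
    analyte: AnalyteID
    r_b: float
    r_c: float
    f_vac: float
    f_vac_raw: float


def calibrate_response_factors(
    standards: Iterable[StandardRecord],
    convention: str = "inverse_response",
    aggregate: str = "mean",
    allow_single_level: bool = False,
) -> dict[str, ResponseFactors]:
    """Calibrate response weights per analyte from equimolar standards.

    The per-level light/heavy ratios I*_L/I*_H are combined by their
    arithmetic mean (``aggregate="geometric"`` for the geometric mean) and
    the per-level coefficient of variation is reported as a stability
    diagnostic — the ratio should hold over the whole dilution series.
    """
    if convention not in ("inverse_response", "as_printed"):
        raise CalibrationError(f"unknown convention {convention!r}")
    if aggregate not in ("mean", "geometric"):
        raise CalibrationError(f"unknown aggregate {aggregate!r}")

    by_analyte: dict[str, list[StandardRecord]] = {}
    for rec in standards:
        if rec.intensity_light <= 0 or rec.intensity_heavy <= 0:
            raise CalibrationError("standard intensities must be > 0")
        by_analyte.setdefault(rec.analyte.name, []).append(rec)
    if not by_analyte:
        raise CalibrationError("no standards provided")

    out: dict[str, ResponseFactors] = {}
    for name, recs in by_analyte.items():
        if len(recs) < 2 and not allow_single_level:
            raise CalibrationError(
                f"analyte {name!r}: need >= 2 standard levels (got {len(recs)}); "
                "pass allow_single_level=True to override"
            )
        ratios = np.array([r.intensity_light / r.intensity_heavy for r in recs])
        if aggregate == "mean":
            mean_ratio = float(np.mean(ratios))
        else:
            mean_ratio = float(np.exp(np.mean(np.log(ratios))))
        cv = float(np.std(ratios, ddof=1) / np.mean(ratios)) if len(ratios) > 1 else float("nan")
        if convention == "inverse_response":
            # w_L/w_H = 1/ratio: weights undo the per-isotopologue response
            w_light = 1.0 / (1.0 + mean_ratio)
            w_heavy = mean_ratio / (1.0 + mean_ratio)
        else:
            w_heavy = 1.0 / (1.0 + mean_ratio)
            w_light = mean_ratio / (1.0 + mean_ratio)
        logger.info(
            "calibrated %s: mean I*_L/I*_H = %.6g (CV %.3g over %d levels), "
            "convention=%s, w_light=%.6g",
            name, mean_ratio, cv, len(recs), convention, w_light,
        )
        out[name] = ResponseFactors(
            analyte=recs[0].analyte,
            w_light=w_light,
            w_heavy=w_heavy,
            mean_standard_ratio=mean_ratio,
            convention=convention,
            ratio_cv=cv,
            n_levels=len(recs),
        )
    return out


def light_fraction(record: IntensityRecord, factors: ResponseFactors) -> RenewalPoint:
    """Convert one intensity pair into a calibrated renewal point.

    f = w_L I_L / (w_L I_L + w_H I_H); time converted from minutes to hours.
    """
    if record.analyte.name != factors.analyte.name:
        raise CalibrationError(
            f"record analyte {record.analyte.name!r} does not match "
            f"calibration for {factors.analyte.name!r}"
        )
    num = factors.w_light * record.intensity_light
    den = num + factors.w_heavy * record.intensity_heavy
    if den <= 0:
        raise ValidationError("undefined fraction: both intensities are zero")
    f = num / den
    time_h = record.time_min / 60.0
    if time_h == 0 and f < 0.9:
        warnings.warn(
            f"renewal at t=0 is {f:.3f} < 0.9 for {record.sample_id} "
            f"{record.analyte.name}/{record.fraction}; pre-switch sample "
            "should be essentially all light",
            stacklevel=2,
        )
    return RenewalPoint(
        genotype=record.genotype,
        replicate=record.replicate,
        analyte=record.analyte,
        fraction=record.fraction,
        time_h=time_h,
        f=f,
    )


def renewal_table(
    records: Iterable[IntensityRecord],
    factors: dict[str, ResponseFactors],
) -> pd.DataFrame:
    """Apply :func:`light_fraction` to every labeling record.

    Returns a tidy frame with columns genotype, replicate, analyte,
    fraction, time_h, f. Non-labeling fractions (medium, CuCl2 fractions)
    are ignored here.
    """
    rows = []
    for rec in records:
        if rec.fraction not in LABELING_FRACTIONS:
            continue
        if rec.analyte.name not in factors:
            raise CalibrationError(f"no calibration for analyte {rec.analyte.name!r}")
        pt = light_fraction(rec, factors[rec.analyte.name])
        rows.append(
            {
                "genotype": pt.genotype,
                "replicate": pt.replicate,
                "analyte": pt.analyte.name,
                "fraction": pt.fraction,
                "time_h": pt.time_h,
                "f": pt.f,
            }
        )
    return pd.DataFrame(rows, columns=RENEWAL_COLUMNS)


def write_renewal_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_renewal_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RENEWAL_COLUMNS if c not in df.columns]
    if missing:
        from .tables_io import SchemaError

        raise SchemaError(f"renewal table missing columns {missing}")
    return df


def cucl2_vacuolar_fraction(
    sample_id: str,
    analyte: AnalyteID,
    intensity_analyte_b: float,
    intensity_marker_b: float,
    intensity_analyte_c: float,
    intensity_marker_c: float,
) -> VacuolarFraction:
    """Vacuolar share of a soluble pool from a CuCl2 permeabilization pair.

    R_b and R_c are analyte/marker intensity ratios in the cytosol-enriched
    (B) and vacuole-enriched (C) fractions; f_vac = 1 - R_b/R_c. The marker
    (e.g. phenylalanine) is a fiducial cytosolic species.
    """
    if intensity_marker_b <= 0 or intensity_marker_c <= 0:
        raise ValidationError("marker intensity must be > 0 in both fractions")
    if intensity_analyte_b < 0 or intensity_analyte_c < 0:
        raise ValidationError("analyte intensities must be >= 0")
    r_b = intensity_analyte_b / intensity_marker_b
    r_c = intensity_analyte_c / intensity_marker_c
    if r_c == 0:
        raise ValidationError("undefined vacuolar fraction: R_c = 0")
    raw = 1.0 - r_b / r_c
    if raw < 0:
        warnings.warn(
            f"{sample_id}/{analyte.name}: f_vac = {raw:.3f} < 0 clipped to 0 "
            "(measurement noise)",
            stacklevel=2,
        )
    f_vac = min(max(raw, 0.0), 1.0)
    return VacuolarFraction(
        sample_id=sample_id,
        analyte=analyte,
        r_b=r_b,
        r_c=r_c,
        f_vac=f_vac,
        f_vac_raw=raw,
    )


def cucl2_table_fractions(df: pd.DataFrame) -> list[VacuolarFraction]:
    """Pair B/C rows of a CuCl2 table per (sample, analyte) and evaluate f_vac."""
    out = []
    for (sample_id, analyte), grp in df.groupby(["sample_id", "analyte"], sort=True):
        by_frac = {row.fraction: row for row in grp.itertuples(index=False)}
        if set(by_frac) != {"cytosol_B", "vacuole_C"}:
            raise ValidationError(
                f"{sample_id}/{analyte}: need exactly one cytosol_B and one "
                f"vacuole_C row, got {sorted(by_frac)}"
            )
        b, c = by_frac["cytosol_B"], by_frac["vacuole_C"]
        out.append(
            cucl2_vacuolar_fraction(
                str(sample_id),
                AnalyteID(str(analyte)),
                b.intensity_analyte,
                b.intensity_marker,
                c.intensity_analyte,
                c.intensity_marker,
            )
        )
    return out
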