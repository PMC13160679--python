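"""Conservative (log-linear) estimation of vacuolar transport rates.

During balanced exponential growth the vacuolar amino-acid pool turns
over by import and export while growing at the culture rate mu. If every
heavy molecule entering the vacuole is assumed to come straight from the
medium, the light (old) fraction of the vacuolar pool decays as a single
exponential f_sol(t) = exp(-k t), so the bulk import rate k is the slope
of -ln f_sol versus t, and the export rate follows from the steady-state
balance

    k_ve = k - mu .

Because in reality part of the vacuolar influx is recycled *light*
material (protein degradation, re-import), the apparent decay is slower
than the true import flux would give: this estimator systematically
underestimates the true export rate — hence "conservative".

Pool weights S_prot, S_vac partition the cellular pool between
protein-incorporated and soluble (vacuolar) amino acids from the three
fraction-level renewal readouts; they convert the per-pool rates into a
common unit (per protein-pool content):

    K_ve = k_ve * S_vac / S_prot,   K_vi = mu * S_vac / S_prot,
    K_tot = k_tot / S_prot .
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tables_io import AnalyteID, GrowthPoint, RunConfig, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GrowthFit:
    """Exponential growth rate fitted from log-transformed OD600."""

    sample_id: str
    mu: float
    r_squared: float
    n_points: int


@dataclass
class PoolWeights:
    """Relative sizes of the protein (S_prot) and vacuolar (S_vac) pools.

    Per-time-point values come from the renewal triplets; the consensus is
    their mean over the post-switch time points. ``s1_cyto`` is the nominal
    (small) cytosolic weight used by the detailed model.
    """

    genotype: str
    replicate: int
    analyte: AnalyteID
    s_prot_by_time: dict[float, float] = field(default_factory=dict)
    s_vac_by_time: dict[float, float] = field(default_factory=dict)
    s_prot: float = float("nan")
    s_vac: float = float("nan")
    s1_cyto: float = 0.01

    @property
    def vac_to_prot_ratio(self) -> float:
        return self.s_vac / self.s_prot


@dataclass(frozen=True)
class ConservativeRates:
    """Per-replicate conservative transport-rate estimates (all h^-1)."""

    genotype: str
    replicate: int
    analyte: AnalyteID
    k_bulk_vac_import: float
    mu: float
    k_ve: float
    k_vi: float
    k_tot: float
    K_ve: float
    K_vi: float
    K_tot: float
    fit_r_squared: float
    k_ve_clipped: bool = False


def _origin_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope of y ~ slope * t (through the origin) and its R^2.

    R^2 is computed against the same no-intercept model with the uncentered
    total sum of squares; a degenerate all-zero response gives R^2 = 1.
    """
    denom = float(np.dot(t, t))
    if denom == 0:
        raise ValidationError("degenerate series: all time points identical (and zero)")
    slope = float(np.dot(t, y) / denom)
    ss_res = float(np.sum((y - slope * t) ** 2))
    ss_tot = float(np.sum(y**2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, r2


def _intercept_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if len(np.unique(t)) < 2:
        raise ValidationError("degenerate series: all time points identical")
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return float(slope), r2


def fit_growth_rate(
    series: Iterable[GrowthPoint], intercept: bool = False
) -> GrowthFit:
    """Fit mu from ln(OD(t)/OD(0)) = mu * t (t in hours).

    With ``intercept=False`` (default) the regression is forced through the
    origin, as the exponential-growth model dictates; the series must then
    include a t = 0 reading to anchor OD(0).
    """
    pts = sorted(series, key=lambda p: p.time_min)
    if len(pts) < 2:
        raise ValidationError("need at least 2 growth points")
    t = np.array([p.time_min for p in pts]) / 60.0
    od = np.array([p.od600 for p in pts])
    if not intercept and t[0] != 0:
        raise ValidationError("origin regression requires a t = 0 OD reading")
    y = np.log(od / od[0])
    if intercept:
        mu, r2 = _intercept_slope(t, y)
    else:
        mu, r2 = _origin_slope(t, y)
    return GrowthFit(sample_id=pts[0].sample_id, mu=mu, r_squared=r2, n_points=len(pts))


def fit_fractional_rate(
    time_h: Sequence[float],
    f: Sequence[float],
    intercept: bool = False,
    epsilon_floor: float = 1e-6,
) -> tuple[float, float]:
    """Rate from the log-linear decay -ln f(t) = rate * t.

    The through-origin default encodes the model's own boundary condition
    f(0) = 1. Non-positive f values are floored at ``epsilon_floor`` with a
    warning (a logarithm is taken here; stored renewal tables are never
    floored). Returns ``(rate, r_squared)``.
    """
    t = np.asarray(time_h, dtype=float)
    fv = np.asarray(f, dtype=float)
    if t.shape != fv.shape or t.size < 2:
        raise ValidationError("need >= 2 matching (time, f) points")
    if np.any(fv <= 0):
        warnings.warn(
            f"{int(np.sum(fv <= 0))} renewal value(s) <= 0 floored at "
            f"{epsilon_floor} before log transform",
            stacklevel=2,
        )
        fv = np.maximum(fv, epsilon_floor)
    y = -np.log(fv)
    if intercept:
        return _intercept_slope(t, y)
    return _origin_slope(t, y)


def pool_weights(
    triplets: pd.DataFrame,
    config: RunConfig,
    genotype: str = "",
    replicate: int = 0,
    analyte: AnalyteID | None = None,
) -> PoolWeights:
    """Pool weights from renewal triplets (columns time_h, f_tot, f_sol, f_prot).

    Per time point t > 0:

        S_prot(t) = (f_tot - f_sol) / (f_prot - f_sol)
        S_vac(t)  = 1 - S_prot(t)

    t = 0 is excluded (all fractions are 1: 0/0). Points with
    f_prot = f_sol are skipped with a warning; S_prot outside [-0.05, 1.05]
    is rejected as inconsistent with two-pool partitioning; values inside
    that band but outside [0, 1] are clipped with a warning. The consensus
    is the arithmetic mean over the usable time points.
    """
    analyte = analyte or AnalyteID("unknown")
    pw = PoolWeights(
        genotype=genotype, replicate=replicate, analyte=analyte, s1_cyto=config.s1_cyto
    )
    for row in triplets.itertuples(index=False):
        t = float(row.time_h)
        if t == 0:
            continue
        denom = row.f_prot - row.f_sol
        if denom == 0:
            warnings.warn(f"t={t} h: f_prot = f_sol, pool weights undefined; skipped",
                          stacklevel=2)
            continue
        s_prot = (row.f_tot - row.f_sol) / denom
        if not -0.05 <= s_prot <= 1.05:
            warnings.warn(
                f"t={t} h: S_prot = {s_prot:.3f} outside [-0.05, 1.05]; point "
                "rejected as inconsistent",
                stacklevel=2,
            )
            continue
        if not 0.0 <= s_prot <= 1.0:
            warnings.warn(f"t={t} h: S_prot = {s_prot:.3f} clipped to [0, 1]",
                          stacklevel=2)
            s_prot = min(max(s_prot, 0.0), 1.0)
        pw.s_prot_by_time[t] = s_prot
        pw.s_vac_by_time[t] = 1.0 - s_prot
    if not pw.s_prot_by_time:
        raise ValidationError("no usable time points for pool weights")
    pw.s_prot = float(np.mean(list(pw.s_prot_by_time.values())))
    pw.s_vac = 1.0 - pw.s_prot
    return pw


def conservative_rates(
    k: float,
    mu: float,
    k_tot: float,
    weights: PoolWeights,
    genotype: str = "",
    replicate: int = 0,
    analyte: AnalyteID | None = None,
    fit_r_squared: float = float("nan"),
    k_tot_literal_product: bool = False,
) -> ConservativeRates:
    """Combine the log-linear estimates into the conservative rate set.

    k_ve = k - mu, clipped at 0 (a negative export rate is physically
    meaningless and only arises from noise; the clip is flagged). The
    conversions to protein-pool units use the consensus weights; K_tot is
    k_tot / S_prot unless the literal-product switch is set.
    """
    for name, val in (("k", k), ("mu", mu), ("k_tot", k_tot)):
        if not np.isfinite(val):
            raise ValidationError(f"{name} must be finite")
    if weights.s_prot == 0:
        raise ValidationError("S_prot = 0: cannot convert to protein-pool units")
    raw_k_ve = k - mu
    clipped = raw_k_ve < 0
    if clipped:
        logger.info(
            "k - mu = %.4g < 0 for %s/%s: export rate clipped to 0",
            raw_k_ve, genotype, analyte.name if analyte else "?",
        )
    k_ve = max(raw_k_ve, 0.0)
    ratio = weights.s_vac / weights.s_prot
    K_tot = k_tot * weights.s_prot if k_tot_literal_product else k_tot / weights.s_prot
    return ConservativeRates(
        genotype=genotype,
        replicate=replicate,
        analyte=analyte or weights.analyte,
        k_bulk_vac_import=k,
        mu=mu,
        k_ve=k_ve,
        k_vi=mu,
        k_tot=k_tot,
        K_ve=k_ve * ratio,
        K_vi=mu * ratio,
        K_tot=K_tot,
        fit_r_squared=fit_r_squared,
        k_ve_clipped=bool(clipped),
    )


def renewal_triplets(renewal: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy renewal frame into per-time triplets (f_tot, f_sol, f_prot).

    Index columns genotype/replicate/analyte/time_h are preserved; missing
    fractions raise.
    """
    pivot = renewal.pivot_table(
        index=["genotype", "replicate", "analyte", "time_h"],
        columns="fraction",
        values="f",
    ).reset_index()
    for frac in ("soluble", "protein", "total"):
        if frac not in pivot.columns:
            raise ValidationError(f"renewal table lacks fraction {frac!r}")
    return pivot.rename(
        columns={"soluble": "f_sol", "protein": "f_prot", "total": "f_tot"}
    )


def estimate_conservative(
    renewal: pd.DataFrame,
    growth: Iterable[GrowthPoint],
    config: RunConfig,
) -> tuple[list[ConservativeRates], list[PoolWeights], dict[str, GrowthFit]]:
    """Full conservative analysis per (genotype, replicate, analyte).

    Growth series are matched to labeling samples by the convention
    ``sample_id == "{genotype}_rep{replicate}"``; a missing series raises.
    """
    growth_by_sample: dict[str, list[GrowthPoint]] = {}
    for gp in growth:
        growth_by_sample.setdefault(gp.sample_id, []).append(gp)
    growth_fits = {
        sid: fit_growth_rate(pts, intercept=config.regression_intercept)
        for sid, pts in growth_by_sample.items()
    }

    trip = renewal_triplets(renewal)
    rates: list[ConservativeRates] = []
    weights_out: list[PoolWeights] = []
    for (genotype, replicate, analyte), grp in trip.groupby(
        ["genotype", "replicate", "analyte"], sort=True
    ):
        sid = f"{genotype}_rep{replicate}"
        if sid not in growth_fits:
            raise ValidationError(f"no growth series for sample {sid!r}")
        mu = growth_fits[sid].mu
        grp = grp.sort_values("time_h")
        analyte_id = AnalyteID(str(analyte))
        try:
            w = pool_weights(
                grp, config, genotype=str(genotype), replicate=int(replicate),
                analyte=analyte_id,
            )
        except ValidationError:
            # unidentifiable partition (f_prot ~ f_sol throughout, e.g. when
            # both turnover rates are tiny): rates in per-pool units are
            # still defined, only the protein-pool conversions are not
            warnings.warn(
                f"{genotype}/r{replicate}/{analyte}: pool weights "
                "unidentifiable; protein-pool-unit conversions set to NaN",
                stacklevel=2,
            )
            w = PoolWeights(
                genotype=str(genotype), replicate=int(replicate),
                analyte=analyte_id, s1_cyto=config.s1_cyto,
            )
        k, r2 = fit_fractional_rate(
            grp["time_h"], grp["f_sol"],
            intercept=config.regression_intercept,
            epsilon_floor=config.epsilon_fraction_floor,
        )
        k_tot, _ = fit_fractional_rate(
            grp["time_h"], grp["f_tot"],
            intercept=config.regression_intercept,
            epsilon_floor=config.epsilon_fraction_floor,
        )
        rates.append(
            conservative_rates(
                k, mu, k_tot, w,
                genotype=str(genotype), replicate=int(replicate),
                analyte=analyte_id, fit_r_squared=r2,
                k_tot_literal_product=config.k_tot_literal_product,
            )
        )
        weights_out.append(w)
    return rates, weights_out, growth_fits
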