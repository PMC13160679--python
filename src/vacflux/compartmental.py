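"""Detailed three-pool compartmental model of cationic amino-acid transport.

Pools: cytosol (S1), protein-incorporated (S2), vacuole (S3), with weights
summing to 1. Material enters the cytosol from the medium, exchanges with
the protein pool (synthesis / degradation) and the vacuole (import /
export); every pool is also diluted by growth. With contributed turnovers
k_ij expressed per unit of the *recipient* pool size, mass balance during
steady-state exponential growth pins all turnovers to three free rates —
protein degradation k_pd, growth mu and fractional vacuolar export k_ve:

    k_e1 = mu / S1            (external -> cytosol)
    k_21 = k_pd * S2 / S1     (protein -> cytosol)
    k_12 = mu + k_pd          (cytosol -> protein)
    k_31 = k_ve * S3 / S1     (vacuole -> cytosol)
    k_13 = mu + k_ve          (cytosol -> vacuole)

After a full light -> heavy medium switch the light (old) fraction vector
f(t) = (f_cyt, f_prot, f_sol) obeys df/dt = M f with f(0) = 1 and

    M = [[-(k_e1 + k_21 + k_31), k_21, k_31],
         [ k_12,                -k_12,  0  ],
         [ k_13,                 0,   -k_13]] ,

solved here by matrix exponentiation, f(t) = exp(M t) 1. The model assumes
no amino-acid degradation and no export out of the cell.

Free parameters are fitted to the observed protein- and soluble-fraction
renewal series by bounded nonlinear least squares with a deterministic
multi-start (coarse grid screen, best starts refined), under three
scenarios: free k_ve, no export (k_ve pinned at its lower bound), or
k_ve capped at the conservative estimate.
"""

from __future__ import annotations

import logging
from typing import Sequence

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.optimize import least_squares

from .renewal_rates import PoolWeights
from .tables_io import RunConfig, ValidationError

logger = logging.getLogger(__name__)

SCENARIOS = ("free", "no_export", "conservative_cap")


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class ModelParams:
    """Free rates (h^-1) and pool weights of the three-pool model."""

    k_pd: float
    mu: float
    k_ve: float
    s1: float = 0.01
    s2: float = 0.6
    s3: float = 0.39

    def __post_init__(self) -> None:
        if min(self.k_pd, self.mu, self.k_ve) < 0:
            raise ValidationError("rates must be >= 0")
        if min(self.s1, self.s2, self.s3) <= 0:
            raise ValidationError("pool weights must be > 0")

    def renormalized(self) -> "ModelParams":
        """Rescale s2, s3 so that s1 + s2 + s3 = 1 exactly."""
        scale = (1.0 - self.s1) / (self.s2 + self.s3)
        return ModelParams(
            k_pd=self.k_pd, mu=self.mu, k_ve=self.k_ve,
            s1=self.s1, s2=self.s2 * scale, s3=self.s3 * scale,
        )


@dataclass(frozen=True)
class TransitionMatrix:
    """Transition matrix M (pool order: cytosol, protein, vacuole) plus the
    contributed turnovers it was built from."""

    m: np.ndarray
    k_e1: float
    k_12: float
    k_21: float
    k_13: float
    k_31: float


@dataclass
class CompartmentalFit:
    """Result of a bounded multi-start fit of (k_pd, mu, k_ve)."""

    params: ModelParams
    scenario: str
    ssr: float
    residuals: dict[str, list[float]]
    converged: bool
    n_starts: int
    winning_start: int
    K_ve: float
    mu_fixed: bool = False


def build_transition_matrix(params: ModelParams) -> TransitionMatrix:
    """Build M from the mass-balance closed forms above."""
    if params.s1 == 0:
        raise ValidationError("s1 = 0: singular parametrization")
    k_e1 = params.mu / params.s1
    k_21 = params.k_pd * params.s2 / params.s1
    k_12 = params.mu + params.k_pd
    k_31 = params.k_ve * params.s3 / params.s1
    k_13 = params.mu + params.k_ve
    m = np.array(
        [
            [-(k_e1 + k_21 + k_31), k_21, k_31],
            [k_12, -k_12, 0.0],
            [k_13, 0.0, -k_13],
        ]
    )
    return TransitionMatrix(m=m, k_e1=k_e1, k_12=k_12, k_21=k_21, k_13=k_13, k_31=k_31)


def propagate_labeling(matrix: TransitionMatrix | np.ndarray, times: Sequence[float]) -> np.ndarray:
    """Light-fraction trajectories f(t) = exp(M t) 1.

    Returns an array of shape (len(times), 3) with columns (cytosol,
    protein, vacuole). f(0) = (1, 1, 1); each component stays in [0, 1]
    and decays monotonically for any matrix built from valid parameters.
    """
    m = matrix.m if isinstance(matrix, TransitionMatrix) else np.asarray(matrix)
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValidationError("times must be >= 0")
    ones = np.ones(3)
    return np.array([expm(m * ti) @ ones for ti in t])


def model_renewal_observables(
    params: ModelParams, times: Sequence[float]
) -> dict[str, np.ndarray]:
    """Predicted f_sol, f_prot, f_tot (and f_cyt) at the given times (hours).

    f_sol is the vacuole component, f_prot the protein component; f_tot is
    the pool-weighted average over all three compartments (with s1 small
    this differs from the two-pool average by at most s1).
    """
    f = propagate_labeling(build_transition_matrix(params), times)
    s = np.array([params.s1, params.s2, params.s3])
    f_tot = f @ s / s.sum()
    return {
        "f_cyt": f[:, 0],
        "f_prot": f[:, 1],
        "f_sol": f[:, 2],
        "f_tot": f_tot,
    }


def export_rate_protein_units(fit: CompartmentalFit) -> float:
    """Fitted vacuolar export re-expressed per protein-pool content:
    K_ve = k_ve * S3 / S2."""
    if fit.params.s2 == 0:
        raise ValidationError("s2 = 0: cannot convert to protein-pool units")
    return fit.params.k_ve * fit.params.s3 / fit.params.s2


def _params_from_weights(
    x: np.ndarray, weights: PoolWeights, config: RunConfig
) -> ModelParams:
    k_pd, mu, k_ve = x
    p = ModelParams(
        k_pd=float(k_pd), mu=float(mu), k_ve=float(k_ve),
        s1=config.s1_cyto, s2=weights.s_prot, s3=weights.s_vac,
    )
    return p.renormalized() if config.renormalize_pools else p


def fit_detailed_model(
    time_h: Sequence[float],
    f_sol: Sequence[float],
    f_prot: Sequence[float],
    weights: PoolWeights,
    config: RunConfig,
    scenario: str = "free",
    cap: float | None = None,
    fixed_mu: float | None = None,
) -> CompartmentalFit:
    """Fit (k_pd, mu, k_ve) to observed renewal of the soluble and protein pools.

    Minimizes the unweighted sum of squared residuals over both series
    within the configured bounds. ``scenario``:

    - ``"free"``: k_ve free within its bounds;
    - ``"no_export"``: k_ve pinned at its lower bound;
    - ``"conservative_cap"``: k_ve upper bound replaced by ``cap`` (the
      conservative estimate).

    ``fixed_mu`` pins the growth rate to a turbidity-derived value instead
    of fitting it. Multi-start: the SSR is evaluated on a uniform grid over
    the feasible box (``config.multistart_grid`` points per free axis) and
    the best ``config.multistart_refine`` grid points are refined with
    bounded least squares; the overall best refined solution wins. The whole
    procedure is deterministic.
    """
    if scenario not in SCENARIOS:
        raise ScenarioError(f"unknown scenario {scenario!r}")
    t = np.asarray(time_h, dtype=float)
    obs_sol = np.asarray(f_sol, dtype=float)
    obs_prot = np.asarray(f_prot, dtype=float)
    if not (t.shape == obs_sol.shape == obs_prot.shape):
        raise ValidationError("time/f_sol/f_prot must have matching shapes")
    if np.sum(t > 0) < 3:
        raise ValidationError("need >= 3 post-switch time points")

    lo_pd, hi_pd = config.bounds_k_pd
    lo_mu, hi_mu = config.bounds_mu
    lo_ve, hi_ve = config.bounds_k_ve
    if scenario == "conservative_cap":
        if cap is None:
            raise ScenarioError("conservative_cap scenario requires a cap")
        if cap < lo_ve:
            raise ScenarioError(
                f"cap {cap} below the k_ve lower bound {lo_ve}"
            )
        hi_ve = min(hi_ve, cap)
    # a cap at (or below) the lower bound leaves a single feasible k_ve
    pin_ve = scenario == "no_export" or hi_ve <= lo_ve * (1 + 1e-12)
    pin_mu = fixed_mu is not None

    def full_x(free: np.ndarray) -> np.ndarray:
        vals = list(free)
        k_pd = vals.pop(0)
        mu = fixed_mu if pin_mu else vals.pop(0)
        k_ve = lo_ve if pin_ve else vals.pop(0)
        return np.array([k_pd, mu, k_ve])

    def residuals(free: np.ndarray) -> np.ndarray:
        p = _params_from_weights(full_x(free), weights, config)
        pred = model_renewal_observables(p, t)
        return np.concatenate([obs_prot - pred["f_prot"], obs_sol - pred["f_sol"]])

    # deterministic multi-start: grid screen, then refine the best starts
    n = config.multistart_grid
    axes = [np.linspace(lo_pd, hi_pd, n)]
    lo_free, hi_free = [lo_pd], [hi_pd]
    if not pin_mu:
        axes.append(np.linspace(lo_mu, hi_mu, n))
        lo_free.append(lo_mu)
        hi_free.append(hi_mu)
    if not pin_ve:
        # log-spaced in k_ve: the feasible range spans three decades
        axes.append(np.geomspace(lo_ve, hi_ve, n) if hi_ve > lo_ve
                    else np.array([lo_ve]))
        lo_free.append(lo_ve)
        hi_free.append(hi_ve)
    starts = np.array(np.meshgrid(*axes, indexing="ij")).reshape(len(axes), -1).T
    ssr_grid = np.array([float(np.sum(residuals(x) ** 2)) for x in starts])
    order = np.argsort(ssr_grid, kind="stable")[: config.multistart_refine]

    best = None
    best_ssr = np.inf
    winning = -1
    converged = False
    for idx in order:
        try:
            sol = least_squares(
                residuals, starts[idx], bounds=(lo_free, hi_free),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:  # keep scanning other starts
            continue
        ssr = float(2 * sol.cost)
        if ssr < best_ssr:
            best, best_ssr, winning = sol, ssr, int(idx)
            converged = bool(sol.success)
    if best is None:
        # no start converged: fall back to the best grid point, flagged
        winning = int(order[0])
        x_full = full_x(starts[winning])
        best_ssr = ssr_grid[winning]
        res_vec = residuals(starts[winning])
    else:
        x_full = full_x(best.x)
        res_vec = best.fun
    params = _params_from_weights(x_full, weights, config)
    n_obs = len(t)
    fit = CompartmentalFit(
        params=params,
        scenario=scenario,
        ssr=float(best_ssr),
        residuals={
            "time_h": t.tolist(),
            "f_prot": res_vec[:n_obs].tolist(),
            "f_sol": res_vec[n_obs:].tolist(),
        },
        converged=converged,
        n_starts=len(starts),
        winning_start=winning,
        K_ve=0.0,
        mu_fixed=pin_mu,
    )
    fit.K_ve = export_rate_protein_units(fit)
    logger.debug(
        "fit %s: k_pd=%.4g mu=%.4g k_ve=%.4g ssr=%.3e (start %d/%d)",
        scenario, params.k_pd, params.mu, params.k_ve, best_ssr, winning, len(starts),
    )
    return fit


def fit_all_scenarios(
    time_h: Sequence[float],
    f_sol: Sequence[float],
    f_prot: Sequence[float],
    weights: PoolWeights,
    config: RunConfig,
    conservative_k_ve: float | None = None,
    fixed_mu: float | None = None,
) -> dict[str, CompartmentalFit]:
    """Fit the free and no-export scenarios (plus conservative-cap when a
    conservative estimate is available) on the same data."""
    out = {
        "free": fit_detailed_model(
            time_h, f_sol, f_prot, weights, config, "free", fixed_mu=fixed_mu
        ),
        "no_export": fit_detailed_model(
            time_h, f_sol, f_prot, weights, config, "no_export", fixed_mu=fixed_mu
        ),
    }
    if conservative_k_ve is not None:
        cap = max(conservative_k_ve, config.bounds_k_ve[0])
        out["conservative_cap"] = fit_detailed_model(
            time_h, f_sol, f_prot, weights, config, "conservative_cap",
            cap=cap, fixed_mu=fixed_mu,
        )
    return out
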