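# Methods

## Labeling model and assumptions

The analysis treats a yeast culture in balanced exponential growth that
is switched at t = 0 from light to heavy lysine/arginine medium. Three
well-mixed pools hold the cationic amino acids: cytosol (weight S₁),
protein-incorporated (S₂) and vacuolar (S₃), with S₁ + S₂ + S₃ = 1.
Material transfer is described by contributed turnovers k_ij (source i,
recipient j, measured per unit of the *recipient* pool). Mass balance at
steady state leaves three free rates — protein degradation k_pd, growth
μ and fractional vacuolar export k_ve — and fixes the rest:

    k_e1 = μ/S₁,  k_21 = k_pd·S₂/S₁,  k_12 = μ + k_pd,
    k_31 = k_ve·S₃/S₁,  k_13 = μ + k_ve.

The light ("old") fraction vector obeys df/dt = M·f, f(0) = 1, solved by
`scipy.linalg.expm`. The protein and vacuole components of f are the
observables f_prot and f_sol; f_tot is their pool-weighted average
including the cytosol term.

Assumptions inherited by every estimate: balanced growth (constant pool
weights and turnovers over the 2-h window), a full and instantaneous
medium switch, no amino-acid degradation and no export out of the cell,
and a cytosolic pool that is small relative to the other two (S₁ is set
to a nominal 0.01 for computation).

## Calibration

Response weights are calibrated from equimolar light/heavy dilution
series at 0.0005–0.5 mM. Per-level ratios I\*_L/I\*_H are combined by
arithmetic mean (geometric mean available), and their CV is reported as
a stability diagnostic. Two conventions exist:

- `inverse_response` (default): w_L/w_H = 1/mean ratio. The weights undo
  the instrument's per-isotopologue response, so the equimolar standard
  itself maps to f = 0.5 exactly — the self-check that bracketing
  standards exist to provide.
- `as_printed`: w_L/w_H = mean ratio, i.e. the larger weight goes to the
  stronger-responding isotopologue. Under this form the equimolar
  standard does *not* read 0.5 unless responses are equal; it is kept
  for comparison, and we treat the subscripting it transcribes as a typo.

## Conservative estimation

The conservative model assumes every heavy molecule entering the vacuole
comes straight from the medium, giving f_sol(t) = e^(−kt); k is then the
through-origin slope of −ln f_sol vs t, μ the through-origin slope of
ln OD(t)/OD(0), and k_ve = k − μ. Through-origin regression is the
default because f(0) = 1 and OD-ratio(0) = 1 are the model's own
boundary conditions; an intercept option exists for diagnostics only.
Since part of the real vacuolar influx is recycled light material
(protein degradation, re-import), f_sol decays more slowly than
e^(−(μ+k_ve)t) — formally df_sol/dt = k_13(f_cyt − f_sol) ≥ −k_13·f_sol —
so the estimate is a strict lower bound on the true export rate. A
negative k − μ (noise) is clipped to 0 and flagged.

Pool weights follow from the partition identity
f_tot = S_vac·f_sol + S_prot·f_prot with S_vac + S_prot = 1, evaluated
per post-switch time point and averaged. t = 0 is excluded (0/0);
points with S_prot outside [−0.05, 1.05] are rejected as inconsistent,
values slightly outside [0, 1] are clipped with a warning. When both
k_pd and k_ve are very small all pools decay at ≈ μ, f_prot ≈ f_sol,
and the partition is unidentifiable; the pipeline then reports per-pool
rates with NaN protein-pool conversions rather than failing.

Unit conversions: K_ve = k_ve·S_vac/S_prot and K_vi = μ·S_vac/S_prot
re-express vacuolar fluxes per protein-borne pool. K_tot is implemented
as k_tot/S_prot: k_tot is per total pool (S_tot = 1), so conversion to
protein-pool units divides by the target pool weight, consistent with
the K_ve form (multiply by source pool, divide by target pool). A config
switch (`k_tot_literal_product`) restores the product form for
comparison.

## Detailed fitting

(k_pd, μ, k_ve) are estimated by minimizing the unweighted SSR over the
observed f_prot and f_sol series within the bounds
0.01 ≤ k_ve ≤ 10, 0.01 ≤ k_pd ≤ 0.05, 0.3 ≤ μ ≤ 0.45 h⁻¹. μ is free by
default (labeling constrains it better than turbidity); `fixed_mu` pins
it to the OD-derived estimate. Scenarios: `free`; `no_export` (k_ve
pinned at its lower bound); `conservative_cap` (k_ve upper bound set to
the conservative estimate — a cap at the lower bound degenerates to the
pinned case). Their feasible sets are nested, so
SSR(no_export) ≥ SSR(conservative_cap) ≥ SSR(free) always.

The optimizer is `scipy.optimize.least_squares` (trust-region
reflective, xtol = ftol = gtol = 1e−12) with a deterministic multi-start:
the SSR is screened on a grid of 5 points per free axis (k_ve
log-spaced, since its range spans three decades) and the best 5 grid
points are refined; the best refined solution and its start index are
reported. The whole procedure is deterministic for a given
configuration. Estimated pool weights feed the fit with S₂, S₃ rescaled
by (1 − S₁) so the three weights sum to 1 (a ≤ 1% effect; a switch
preserves the unnormalized reading).

Propagation accuracy is stated behaviorally: matrix-exponential
trajectories agree with adaptive ODE integration (LSODA,
rtol 1e−11/atol 1e−13) to ≤ 1e−8 over the bounds box (measured ~1e−10).

## CuCl₂ permeabilization readout

f_vac = 1 − R_b/R_c, with R the analyte/marker (phenylalanine) intensity
ratio in the cytosol-enriched (B) and whole-soluble (C) fractions. Since
CuCl₂ can break some vacuoles, the value is a conservative lower bound;
negative values (noise) are clipped with the raw value retained.

## Synthetic data

The generator emulates the study design: OD₆₀₀ 0.15 at the switch,
sampling at 0/20/60/120 min, n = 3 biological replicates, growth at
μ within 0.3–0.45 h⁻¹, genotype effects as k_ve changes only. Renewal
fractions come from the compartmental model; intensities are
I_L = ρ_L·A·f·ε and I_H = ρ_H·A·(1−f)·ε′ with mean-one multiplicative
lognormal noise (default CV 5%, an assumption of this package — MS
replicate scatter is not modeled in the source assay description — kept
multiplicative to preserve positivity). Defaults chosen once as
realistic: response ratios ρ_L/ρ_H of 1.25 (lysine) and 0.8 (arginine),
abundance scale 10⁶ counts, pool split S₂ = 0.6 / S₃ = 0.39 (a
vacuole-to-protein ratio of 0.65, mid-range for these amino acids), WT
k_ve = 2.0 h⁻¹ with a deletion mutant at 0.4 h⁻¹. Optional injections of
small amino-acid degradation or cellular export quantify sensitivity to
the zero-degradation/zero-export assumption; they are off by default and
the fitter never models them.

What the generator does **not** emulate: chromatographic peak shape and
integration error, natural-abundance isotope overlap, carry-over between
runs, metabolic interconversion of label, replicate-to-replicate
biological parameter variation, or departures from balanced growth.
Passing recovery tests therefore demonstrate the estimators' correctness
and noise behavior under the model's own assumptions, not robustness to
every feature of real chromatograms.

The recovery harness (`recovery_experiment`) by default hands the fitter
the generator's true pool weights, isolating parameter recovery from the
O(S₁) bias of data-derived weights (with estimated weights, noise-free
recovery is exact only to ~S₁, i.e. a few percent); a flag exercises the
fully estimated path.

## Numerical choices and edge cases

- Time is minutes in files, hours internally; conversion happens once at
  read time. All rates are h⁻¹.
- Renewal values ≤ 0 are floored at 1e−6 only where a logarithm is
  taken, never in stored tables.
- Through-origin R² uses the uncentered total sum of squares; an
  all-zero response (flat series) reports R² = 1 with rate 0.
- JSON output preserves full float precision; CSV reads use pandas'
  round-trip float parser so write→read is bit-exact.
- Per-replicate estimation throughout; replicate mean ± SD is the
  reported summary, and pooled fitting is available for diagnostics.

## Problem sizes

Default analyses use 2 genotypes × 2 analytes × 3 replicates at the
4-point schedule; the recovery study runs 10–20 trials per condition and
the conservative-underestimation sweep 50 noise-free parameter draws —
sizes at which every stage completes in seconds while the Monte-Carlo
summaries are stable.

## Known limitations

- k_pd is weakly identified by the 4-point schedule (median relative
  error ~20% at 5% noise, often at a bound); k_ve and μ are well
  identified. This mirrors the narrow prior bounds placed on k_pd.
- With pure-exponential (growth-dilution-only) input, the k_pd ≥ 0.01
  floor forces a slight model mismatch that the optimizer absorbs with a
  small spurious k_ve (≈ 0.05 h⁻¹); export estimates near the lower
  bound should be read as "no detectable export", not as precise rates.
- The pool partition is unidentifiable when protein and soluble pools
  renew at indistinguishable rates (both k_pd and k_ve small).
- The conservative/detailed contrast assumes the same S₁ convention in
  both models; changing S₁ rescales cytosol-coupled turnovers but barely
  affects fitted k_ve (the vacuole row depends on S₁ only through k_31).
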