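"""Growth-rate and conservative-model estimation."""

import numpy as np
import pandas as pd
import pytest

from vacflux import (
    AnalyteID,
    GrowthPoint,
    ModelParams,
    ValidationError,
    conservative_rates,
    fit_fractional_rate,
    fit_growth_rate,
    model_renewal_observables,
    pool_weights,
)
from vacflux.renewal_rates import PoolWeights


def growth_series(mu, times_h, od0=0.15, sample_id="c1", noise=None):
    ods = od0 * np.exp(mu * np.asarray(times_h))
    if noise is not None:
        ods = ods * noise
    return [
        GrowthPoint(sample_id, t * 60.0, float(od))
        for t, od in zip(times_h, ods)
    ]


class TestGrowthRate:
    def test_exact_exponential(self):
        fit = fit_growth_rate(growth_series(0.4, [0.0, 2.0]))
        assert fit.mu == pytest.approx(0.4, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_series_gives_zero(self):
        pts = [GrowthPoint("c1", t, 0.15) for t in (0.0, 60.0, 120.0)]
        assert fit_growth_rate(pts).mu == 0.0

    def test_noisy_recovery_within_three_percent(self):
        rng = np.random.default_rng(5)
        times = [0.0, 1 / 3, 1.0, 2.0]
        noise = np.exp(rng.normal(0.0, 0.01, size=len(times)))
        noise[0] = 1.0  # OD(0) anchors the origin regression
        fit = fit_growth_rate(growth_series(0.35, times, noise=noise))
        assert fit.mu == pytest.approx(0.35, rel=0.03)

    def test_origin_regression_requires_t0(self):
        pts = growth_series(0.4, [0.5, 1.0, 2.0])
        with pytest.raises(ValidationError, match="t = 0"):
            fit_growth_rate(pts)
        assert fit_growth_rate(pts, intercept=True).mu == pytest.approx(0.4, rel=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValidationError, match="2 growth points"):
            fit_growth_rate([GrowthPoint("c1", 0.0, 0.15)])


class TestFractionalRate:
    def test_exact_log_linear_recovery(self):
        t = np.array([0.0, 1 / 3, 1.0, 2.0])
        rate, r2 = fit_fractional_rate(t, np.exp(-0.6 * t))
        assert rate == pytest.approx(0.6, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_no_renewal_gives_zero(self):
        rate, _ = fit_fractional_rate([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])
        assert rate == 0.0

    def test_growth_dilution_floor(self):
        """Pure growth dilution yields rate mu, hence conservative export 0."""
        mu = 0.4
        t = np.array([0.0, 1 / 3, 1.0, 2.0])
        rate, _ = fit_fractional_rate(t, np.exp(-mu * t))
        assert rate == pytest.approx(mu, abs=1e-12)
        assert max(rate - mu, 0.0) == 0.0

    def test_nonpositive_f_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            rate, _ = fit_fractional_rate([0.0, 1.0], [1.0, 0.0], epsilon_floor=1e-6)
        assert rate == pytest.approx(-np.log(1e-6), rel=1e-9)


class TestPoolWeights:
    def triplets(self, rows):
        return pd.DataFrame(rows, columns=["time_h", "f_tot", "f_sol", "f_prot"])

    def test_hand_example(self, config):
        w = pool_weights(self.triplets([(1.0, 0.7, 0.4, 0.9)]), config)
        assert w.s_prot == pytest.approx(0.6, rel=1e-12)
        assert w.s_vac == pytest.approx(0.4, rel=1e-12)
        assert w.vac_to_prot_ratio == pytest.approx(2 / 3, rel=1e-12)

    def test_all_protein_borne(self, config):
        w = pool_weights(self.triplets([(1.0, 0.9, 0.4, 0.9)]), config)
        assert w.s_prot == 1.0
        assert w.s_vac == 0.0

    def test_partition_identity_per_time_point(self, config):
        rng = np.random.default_rng(2)
        rows = []
        for t in (1 / 3, 1.0, 2.0):
            f_sol, f_prot = sorted(rng.uniform(0.1, 0.95, size=2))
            s = rng.uniform(0.0, 1.0)
            rows.append((t, f_sol + s * (f_prot - f_sol), f_sol, f_prot))
        w = pool_weights(self.triplets(rows), config)
        for t in w.s_prot_by_time:
            assert w.s_prot_by_time[t] + w.s_vac_by_time[t] == 1.0

    def test_t0_excluded_and_consensus_is_mean(self, config):
        rows = [(0.0, 1.0, 1.0, 1.0), (1.0, 0.7, 0.4, 0.9), (2.0, 0.5, 0.2, 0.8)]
        w = pool_weights(self.triplets(rows), config)
        assert 0.0 not in w.s_prot_by_time
        assert w.s_prot == pytest.approx(np.mean([0.6, 0.5]), rel=1e-12)

    def test_inconsistent_point_rejected(self, config):
        rows = [(1.0, 0.95, 0.4, 0.5), (2.0, 0.5, 0.2, 0.8)]  # S_prot = 5.5 at t=1
        with pytest.warns(UserWarning, match="rejected"):
            w = pool_weights(self.triplets(rows), config)
        assert list(w.s_prot_by_time) == [2.0]

    def test_degenerate_triplet_skipped(self, config):
        rows = [(1.0, 0.5, 0.5, 0.5)]
        with pytest.warns(UserWarning, match="undefined"):
            with pytest.raises(ValidationError, match="no usable"):
                pool_weights(self.triplets(rows), config)


class TestConservativeRates:
    def weights(self, s_prot=0.6):
        return PoolWeights(
            genotype="WT", replicate=1, analyte=AnalyteID("lysine"),
            s_prot=s_prot, s_vac=1 - s_prot,
        )

    def test_export_rate_from_import_minus_growth(self):
        out = conservative_rates(0.6, 0.4, 0.5, self.weights())
        assert out.k_ve == pytest.approx(0.2, rel=1e-12)
        assert not out.k_ve_clipped

    def test_no_export_limit(self):
        out = conservative_rates(0.4, 0.4, 0.4, self.weights())
        assert out.k_ve == 0.0

    def test_unit_conversions(self):
        w = PoolWeights(
            genotype="WT", replicate=1, analyte=AnalyteID("lysine"),
            s_prot=0.6, s_vac=0.4,
        )
        out = conservative_rates(0.6, 0.4, 0.5, w)
        assert out.K_ve == pytest.approx(0.2 * 0.4 / 0.6, rel=1e-12)
        assert out.K_vi == pytest.approx(0.4 * 0.4 / 0.6, rel=1e-12)
        assert out.K_tot == pytest.approx(0.5 / 0.6, rel=1e-12)
        literal = conservative_rates(0.6, 0.4, 0.5, w, k_tot_literal_product=True)
        assert literal.K_tot == pytest.approx(0.5 * 0.6, rel=1e-12)

    def test_negative_export_clipped_and_flagged(self):
        out = conservative_rates(0.3, 0.4, 0.3, self.weights())
        assert out.k_ve == 0.0
        assert out.k_ve_clipped

    def test_zero_protein_pool_rejected(self):
        with pytest.raises(ValidationError, match="S_prot"):
            conservative_rates(0.6, 0.4, 0.5, self.weights(s_prot=0.0))


def test_conservative_underestimates_true_export(config):
    """Apparent vacuolar decay is slowed by recycled light material, so
    k - mu never exceeds the generating k_ve (sweep within the bounds)."""
    rng = np.random.default_rng(7)
    t = np.array([0.0, 1 / 3, 1.0, 2.0])
    for _ in range(25):
        p = ModelParams(
            k_pd=rng.uniform(0.01, 0.05),
            mu=rng.uniform(0.3, 0.45),
            k_ve=10 ** rng.uniform(-2, 1),
            s1=0.01, s2=0.6, s3=0.39,
        )
        obs = model_renewal_observables(p, t)
        k, _ = fit_fractional_rate(t, obs["f_sol"])
        assert max(k - p.mu, 0.0) <= p.k_ve + 1e-6
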