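"""Exposure-phase dynamics and the binned shift-distribution approximation."""

import numpy as np
import pytest

from avrecal import (ModelSpec, ObserverParams, ShiftDistribution,
                     approximate_shift_distribution, simulate_exposure)
from avrecal.exposure import _final_shifts


def ci_observer_with(**kw):
    base = dict(beta_pre=0.03, tau_a=0.06, tau_v=0.06, criterion=0.08,
                lapse=0.02, alpha=0.01, sigma_c1=0.05, sigma_c2=0.8,
                p_common=0.6)
    base.update(kw)
    return ObserverParams(**base)


class TestTrajectories:
    def test_zero_learning_rate_freezes_bias(self):
        spec = ModelSpec.from_code("ci_ms")
        params = ci_observer_with(alpha=0.0)
        traj = simulate_exposure(spec, params, adapter_soa=0.3, rng_seed=0)
        assert len(traj) == 251
        np.testing.assert_array_equal(traj.shifts, np.zeros(251))

    def test_reproducible_and_starts_at_zero(self):
        spec = ModelSpec.from_code("ac_ms")
        params = ci_observer_with(tau_a=0.05, tau_v=0.09, alpha=0.005)
        a = simulate_exposure(spec, params, -0.2, rng_seed=3)
        b = simulate_exposure(spec, params, -0.2, rng_seed=3)
        np.testing.assert_array_equal(a.shifts, b.shifts)
        assert a.shifts[0] == 0.0

    def test_balanced_adapter_gives_no_mean_drift(self):
        # s + beta_pre = 0 with equal time constants: symmetric measurements,
        # symmetric shrinkage, so the expected causal-inference update is 0
        spec = ModelSpec.from_code("ci_ms")
        params = ci_observer_with(beta_pre=0.05)
        uniforms = np.random.default_rng(4).uniform(size=(1, 1000, 250))
        finals = _final_shifts(spec, params, np.array([-0.05]), uniforms)[0]
        se = finals.std() / np.sqrt(finals.size)
        assert abs(finals.mean()) < 4 * se + 1e-4

    def test_full_attribution_converges_to_compensation(self):
        # p_common=1 with a tiny common-cause spread: the estimate collapses
        # to 0 and the shift approaches -(adapter + beta_pre)
        spec = ModelSpec.from_code("ci_ms")
        params = ci_observer_with(p_common=1.0, sigma_c1=1e-4, alpha=0.01)
        uniforms = np.random.default_rng(5).uniform(size=(1, 1000, 250))
        finals = _final_shifts(spec, params, np.array([0.2]), uniforms)[0]
        target = -(0.2 + params.beta_pre)
        assert finals.mean() == pytest.approx(target, rel=0.1)

    def test_unknown_rule_rejected(self):
        spec = ModelSpec.from_code("ci_ms")
        params = ci_observer_with()
        object.__setattr__(spec, "update_rule", "nonsense")
        with pytest.raises(ValueError):
            simulate_exposure(spec, params, 0.1, rng_seed=0)


class TestShiftDistribution:
    def test_zero_learning_rate_is_point_mass(self):
        spec = ModelSpec.from_code("corr_ms")
        params = ci_observer_with(alpha=0.0)
        dist = approximate_shift_distribution(spec, params, 0.3, n_reps=50,
                                              rng_seed=1)
        assert dist.is_point_mass
        assert dist.mean == 0.0 and dist.sd == 0.0

    def test_summary_matches_sample_moments(self):
        spec = ModelSpec.from_code("ci_ms")
        params = ci_observer_with(tau_a=0.05, tau_v=0.09)
        uniforms = np.random.default_rng(2).uniform(size=(1, 300, 250))
        finals = _final_shifts(spec, params, np.array([-0.3]), uniforms)[0]
        dist = ShiftDistribution.from_samples(finals)
        assert dist.mean == pytest.approx(finals.mean())
        assert dist.sd == pytest.approx(finals.std())

    def test_bin_layout_follows_triple_range_rule(self):
        rng = np.random.default_rng(6)
        samples = rng.normal(0.05, 0.01, size=400)
        dist = ShiftDistribution.from_samples(samples, n_bins=100)
        lo, hi = samples.min(), samples.max()
        span = hi - lo
        assert dist.lower == pytest.approx(lo - span)
        assert dist.upper == pytest.approx(hi + span)
        assert dist.bin_centers.size == 100
        widths = np.diff(dist.bin_centers)
        np.testing.assert_allclose(widths, widths[0])
        # Riemann mass of the Gaussian over the tripled range is ~1
        mass = np.sum(dist.bin_weights) * dist.bin_width
        assert mass == pytest.approx(1.0, abs=1e-3)

    def test_mean_stable_when_doubling_reps(self):
        spec = ModelSpec.from_code("ci_ms")
        params = ci_observer_with(tau_a=0.05, tau_v=0.09)
        d1 = approximate_shift_distribution(spec, params, -0.2, n_reps=400,
                                            rng_seed=7)
        d2 = approximate_shift_distribution(spec, params, -0.2, n_reps=800,
                                            rng_seed=7)
        assert abs(d1.mean - d2.mean) < 3 * d1.sd / np.sqrt(400)


class TestModelContrasts:
    """Qualitative signatures separating the three update rules."""

    def mean_shift(self, code, params, adapter, n_reps=400, seed=8):
        spec = ModelSpec.from_code(code)
        uniforms = np.random.default_rng(seed).uniform(size=(1, n_reps, 250))
        return _final_shifts(spec, params, np.array([adapter]), uniforms)[0].mean()

    def test_contingent_rule_dies_off_at_large_soa(self):
        params = ci_observer_with(beta_pre=0.0, tau_a=0.07, tau_v=0.07,
                                  alpha=0.005)
        near = self.mean_shift("ac_ms", params, -0.2)
        far = self.mean_shift("ac_ms", params, -0.7)
        assert abs(far) < 0.1 * abs(near)

    def test_causal_rule_persists_at_large_soa(self):
        params = ci_observer_with(beta_pre=0.0, tau_a=0.08, tau_v=0.08,
                                  p_common=0.9, sigma_c2=1.0, alpha=0.005)
        spec = ModelSpec.from_code("ci_ms")
        uniforms = np.random.default_rng(9).uniform(size=(1, 1000, 250))
        finals = _final_shifts(spec, params, np.array([0.7]), uniforms)[0]
        se = finals.std() / np.sqrt(finals.size)
        assert abs(finals.mean()) > 3 * se

    def test_asymmetry_tracks_latency_precision(self):
        # more precise audition (small tau_a): auditory-leading adapters
        # recalibrate more; the inequality flips when vision is more precise
        base = dict(beta_pre=0.0, criterion=0.08, lapse=0.02, alpha=0.01,
                    sigma_c1=0.05, sigma_c2=0.8, p_common=0.6)
        sharp_a = ObserverParams(tau_a=0.04, tau_v=0.12, **base)
        sharp_v = ObserverParams(tau_a=0.12, tau_v=0.04, **base)
        aud_lead = self.mean_shift("ci_ms", sharp_a, -0.3, n_reps=600)
        vis_lead = self.mean_shift("ci_ms", sharp_a, +0.3, n_reps=600)
        assert abs(aud_lead) > abs(vis_lead)
        aud_lead2 = self.mean_shift("ci_ms", sharp_v, -0.3, n_reps=600)
        vis_lead2 = self.mean_shift("ci_ms", sharp_v, +0.3, n_reps=600)
        assert abs(vis_lead2) > abs(aud_lead2)
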