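"""Joint likelihood machinery, fitting and model comparison."""

import numpy as np
import pandas as pd
import pytest

from avrecal import (Dataset, JointLikelihoodEngine, ModelSpec, ObserverParams,
                     compare_models, fit_model, joint_loglik, posttest_loglik,
                     pretest_loglik, psychometric_curve)
from avrecal.data import COLUMNS
from avrecal.exposure import ShiftDistribution
from avrecal.synthetic import ExperimentDesign, simulate_experiment

SMALL_DESIGN = ExperimentDesign(adapter_soas=(-0.3, 0.0, 0.3))


def make_dataset(rows):
    return Dataset(pd.DataFrame(rows, columns=COLUMNS))


def corr_mi_observer(**kw):
    base = dict(beta_pre=0.04, tau_a=0.08, tau_v=0.08, criterion=0.1,
                lapse=0.03, alpha=0.008)
    base.update(kw)
    return ObserverParams(**base)


@pytest.fixture(scope="module")
def corr_dataset():
    spec = ModelSpec.from_code("corr_mi")
    return simulate_experiment(spec, corr_mi_observer(), SMALL_DESIGN,
                               rng_seed=31)


class TestPretest:
    def test_single_trial_log_probability(self):
        spec = ModelSpec.from_code("corr_mi")
        params = corr_mi_observer()
        data = make_dataset([("p", 1, 0.0, "pre", 1, -0.1, "A"),
                             ("p", 1, 0.0, "post", 1, -0.1, "A")])
        probs = psychometric_curve(spec, params, [-0.1])[0]
        ll = pretest_loglik(data, spec, params)
        assert ll == pytest.approx(np.log(probs[0]))

    def test_duplicating_trials_doubles_loglik(self, corr_dataset):
        spec = ModelSpec.from_code("corr_mi")
        params = corr_mi_observer()
        ll = pretest_loglik(corr_dataset, spec, params)
        doubled = Dataset(pd.concat([corr_dataset.frame, corr_dataset.frame],
                                    ignore_index=True))
        assert pretest_loglik(doubled, spec, params) == pytest.approx(2 * ll)

    def test_matches_per_trial_loop_oracle(self, corr_dataset):
        spec = ModelSpec.from_code("corr_mi")
        params = corr_mi_observer()
        pre = corr_dataset.phase("pre")
        ll = pretest_loglik(corr_dataset, spec, params)
        total = 0.0
        curve = {s: psychometric_curve(spec, params, [s])[0]
                 for s in corr_dataset.test_soas}
        idx = {"A": 0, "S": 1, "V": 2}
        for _, row in pre.frame.iterrows():
            total += np.log(curve[row.test_soa_s][idx[row.response]])
        assert ll == pytest.approx(total, abs=1e-10)

    def test_trial_order_invariance(self, corr_dataset):
        spec = ModelSpec.from_code("corr_mi")
        params = corr_mi_observer()
        shuffled = Dataset(corr_dataset.frame.sample(frac=1.0, random_state=0))
        assert pretest_loglik(shuffled, spec, params) == pytest.approx(
            pretest_loglik(corr_dataset, spec, params), abs=1e-10)


class TestPosttest:
    def test_zero_learning_rate_reduces_to_pretest_formula(self, corr_dataset):
        """With a point mass at zero shift the post-test likelihood equals
        the pre-test computation applied to the post-test records."""
        spec = ModelSpec.from_code("corr_mi")
        params = corr_mi_observer(alpha=0.0)
        engine = JointLikelihoodEngine(corr_dataset, spec, rng_seed=1,
                                       n_reps=50)
        dists = engine.shift_distributions(params)
        assert all(d.is_point_mass for d in dists)
        post_ll = engine.posttest_loglik(params, dists)
        post_as_pre = engine.pretest_loglik(
            params, counts=corr_dataset.counts("post").sum(axis=0))
        assert post_ll == pytest.approx(post_as_pre, abs=1e-9)

    def test_single_bin_reduces_to_plain_product(self, corr_dataset):
        spec = ModelSpec.from_code("corr_mi")
        params = corr_mi_observer()
        point = [ShiftDistribution.from_samples(np.full(5, 0.02))
                 for _ in range(3)]
        ll = posttest_loglik(corr_dataset, spec, params, point)
        engine = JointLikelihoodEngine(corr_dataset, spec, rng_seed=0,
                                       n_reps=2)
        manual = sum(
            engine._cell_loglik(
                corr_dataset.counts("post")[j],
                engine._prob_fn(params, None)(corr_dataset.test_soas
                                              + params.beta_pre + 0.02))
            for j in range(3))
        assert ll == pytest.approx(manual, abs=1e-10)

    def test_bin_count_converged_at_100(self, corr_dataset):
        spec = ModelSpec.from_code("corr_mi")
        params = corr_mi_observer()
        lls = {}
        for n_bins in (100, 1000):
            engine = JointLikelihoodEngine(corr_dataset, spec, rng_seed=5,
                                           n_reps=200, n_bins=n_bins)
            lls[n_bins] = engine.loglik(params)
        assert abs(lls[100] - lls[1000]) < 0.01

    def test_session_count_mismatch_rejected(self, corr_dataset):
        spec = ModelSpec.from_code("corr_mi")
        params = corr_mi_observer()
        with pytest.raises(ValueError):
            posttest_loglik(corr_dataset, spec, params, shift_dists=[])


class TestJoint:
    def test_decomposes_into_pre_plus_post(self, corr_dataset):
        spec = ModelSpec.from_code("corr_mi")
        params = corr_mi_observer()
        engine = JointLikelihoodEngine(corr_dataset, spec, rng_seed=2,
                                       n_reps=100)
        dists = engine.shift_distributions(params)
        total = engine.loglik(params)
        assert total == pytest.approx(engine.pretest_loglik(params)
                                      + engine.posttest_loglik(params, dists))

    def test_deterministic_given_seed(self, corr_dataset):
        spec = ModelSpec.from_code("corr_mi")
        params = corr_mi_observer()
        a = joint_loglik(corr_dataset, spec, params, rng_seed=9, n_reps=50)
        b = joint_loglik(corr_dataset, spec, params, rng_seed=9, n_reps=50)
        assert a == b

    def test_truth_beats_most_perturbations(self, corr_dataset):
        spec = ModelSpec.from_code("corr_mi")
        params = corr_mi_observer()
        engine = JointLikelihoodEngine(corr_dataset, spec, rng_seed=3,
                                       n_samples=2000, n_reps=100)
        ll_truth = engine.loglik(params)
        rng = np.random.default_rng(4)
        wins = 0
        for _ in range(10):
            factors = 1.0 + 0.07 * rng.choice([-1, 1], size=spec.n_params)
            vec = spec.pack(params) * factors
            wins += ll_truth > engine.loglik(spec.unpack(vec))
        assert wins >= 8


class TestFitting:
    def test_recovers_bias_and_reproduces(self, corr_dataset):
        spec = ModelSpec.from_code("corr_mi")
        fit = fit_model(corr_dataset, spec, n_starts=2, rng_seed=6,
                        n_samples=1000, n_reps=60, maxfev=150)
        assert abs(fit.params.beta_pre - 0.04) < 0.03
        refit = fit_model(corr_dataset, spec, n_starts=2, rng_seed=6,
                          n_samples=1000, n_reps=60, maxfev=150)
        assert refit.loglik == fit.loglik
        assert refit.params == fit.params
        assert fit.loglik >= max(s["loglik"] for s in fit.starts)

    def test_roundtrips_through_json(self, corr_dataset, tmp_path):
        spec = ModelSpec.from_code("corr_mi")
        fit = fit_model(corr_dataset, spec, n_starts=1, rng_seed=6,
                        n_samples=500, n_reps=30, maxfev=60)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        loaded = type(fit).from_json(path)
        assert loaded.params == fit.params
        assert loaded.loglik == fit.loglik


class TestComparison:
    def test_self_comparison_is_zero(self, corr_dataset):
        spec = ModelSpec.from_code("corr_mi")
        fit = fit_model(corr_dataset, spec, n_starts=1, rng_seed=6,
                        n_samples=500, n_reps=30, maxfev=80)
        table = compare_models([fit, fit])
        assert table["log_bf_vs_worst"].tolist() == [0.0, 0.0]
        assert len(table) == 2

    def test_modality_specific_nests_independent(self, corr_dataset):
        mi = fit_model(corr_dataset, ModelSpec.from_code("corr_mi"),
                       n_starts=1, rng_seed=6, n_reps=60, maxfev=150)
        ms = fit_model(corr_dataset, ModelSpec.from_code("corr_ms"),
                       n_starts=1, rng_seed=6, n_reps=60, maxfev=200)
        assert ms.loglik >= mi.loglik - 0.5  # interior constraint, NM slack

    def test_different_data_rejected(self, corr_dataset):
        spec = ModelSpec.from_code("corr_mi")
        fit = fit_model(corr_dataset, spec, n_starts=1, rng_seed=6,
                        n_samples=500, n_reps=30, maxfev=60)
        other = simulate_experiment(spec, corr_mi_observer(), SMALL_DESIGN,
                                    rng_seed=99)
        fit_other = fit_model(other, spec, n_starts=1, rng_seed=6,
                              n_samples=500, n_reps=30, maxfev=60)
        with pytest.raises(ValueError):
            compare_models([fit, fit_other])
        with pytest.raises(ValueError):
            compare_models([fit])
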