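"""Descriptive pre/post psychometric fit, PSS extraction, asymmetry index."""

import numpy as np
import pandas as pd
import pytest

from avrecal import Dataset, asymmetry_index, fit_descriptive, pss
from avrecal.data import COLUMNS
from avrecal.descriptive import _fit_counts, recalibration_summary
from avrecal.psychometrics import RESPONSES, _readout_probs


def counts_from_probs(soas, probs, n, rng):
    out = np.zeros((len(soas), 3), dtype=int)
    for i, row in enumerate(probs):
        out[i] = rng.multinomial(n, row)
    return out


def session_frame(soas, pre_counts, post_counts, session=1, adapter=-0.3):
    rows = []
    for phase, counts in (("pre", pre_counts), ("post", post_counts)):
        trial = 0
        for s, cell in zip(soas, counts):
            for r, c in enumerate(cell):
                for _ in range(int(c)):
                    trial += 1
                    rows.append(("p", session, adapter, phase, trial,
                                 float(s), RESPONSES[r]))
    return pd.DataFrame(rows, columns=COLUMNS)


SOAS = np.array([-0.5, -0.3, -0.2, -0.1, -0.05, 0.0, 0.05, 0.1, 0.2, 0.3, 0.5])


class TestFitDescriptive:
    def test_recovers_pre_and_post_bias(self):
        rng = np.random.default_rng(0)
        shape = (0.06, 0.08, 0.1, 0.02)  # tau_a, tau_v, criterion, lapse
        pre = counts_from_probs(SOAS, _readout_probs(SOAS - 0.02, *shape),
                                100, rng)
        post = counts_from_probs(SOAS, _readout_probs(SOAS - 0.05, *shape),
                                 100, rng)
        fit = _fit_counts(SOAS, pre, post)
        assert fit.beta_pre == pytest.approx(-0.02, abs=0.015)
        assert fit.beta_post == pytest.approx(-0.05, abs=0.015)

    def test_identical_phases_give_equal_biases(self):
        rng = np.random.default_rng(1)
        probs = _readout_probs(SOAS + 0.03, 0.07, 0.07, 0.1, 0.02)
        counts = counts_from_probs(SOAS, probs, 40, rng)
        fit = _fit_counts(SOAS, counts, counts)
        assert fit.beta_pre == pytest.approx(fit.beta_post, abs=2e-3)

    def test_requires_both_phases(self):
        df = session_frame(SOAS, np.ones((len(SOAS), 3), int),
                           np.ones((len(SOAS), 3), int))
        data = Dataset(df[df.phase == "pre"])
        with pytest.raises(ValueError):
            fit_descriptive(data)

    def test_invariant_to_trial_order(self):
        rng = np.random.default_rng(2)
        probs = _readout_probs(SOAS - 0.02, 0.06, 0.09, 0.12, 0.03)
        pre = counts_from_probs(SOAS, probs, 25, rng)
        post = counts_from_probs(SOAS, probs, 25, rng)
        data = Dataset(session_frame(SOAS, pre, post))
        shuffled = Dataset(data.frame.sample(frac=1.0, random_state=3))
        a = fit_descriptive(data)
        b = fit_descriptive(shuffled)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-9)


class TestPss:
    def test_symmetric_model_pss_is_minus_bias(self):
        assert pss(0.06, 0.06, 0.1, 0.02, bias=-0.04) == pytest.approx(
            0.04, abs=1e-4)

    def test_lapse_does_not_move_argmax(self):
        a = pss(0.05, 0.09, 0.12, 0.0, bias=0.03)
        b = pss(0.05, 0.09, 0.12, 0.15, bias=0.03)
        assert a == pytest.approx(b, abs=1e-5)

    def test_grid_and_refinement_agree(self):
        # golden-section refinement never strays far from the 1 ms grid max
        for bias, ta, tv in [(0.0, 0.05, 0.05), (-0.07, 0.04, 0.11),
                             (0.12, 0.14, 0.03)]:
            grid = np.arange(-0.6, 0.6 + 1e-3, 1e-3)
            p = _readout_probs(grid + bias, ta, tv, 0.1, 0.02)[:, 1]
            coarse = grid[np.argmax(p)]
            assert abs(pss(ta, tv, 0.1, 0.02, bias) - coarse) < 1e-3


class TestAsymmetryIndex:
    def test_antisymmetric_effects_cancel(self):
        effects = {j: e for j, e in zip(range(1, 10),
                                        [-0.3, -0.2, -0.1, -0.05, 0.0,
                                         0.05, 0.1, 0.2, 0.3])}
        assert asymmetry_index(effects) == pytest.approx(0.0)

    def test_linear_in_constant_offset(self):
        effects = {j: 0.01 * j for j in range(1, 10)}
        shifted = {j: v + 0.01 for j, v in effects.items()}
        assert asymmetry_index(shifted) - asymmetry_index(effects) == \
            pytest.approx(0.09)

    def test_missing_sessions_listed(self):
        with pytest.raises(ValueError, match=r"\[8, 9\]"):
            asymmetry_index({j: 0.0 for j in range(1, 8)})


class TestSummary:
    @staticmethod
    @pytest.fixture(scope="class")
    def nine_session_data():
        rng = np.random.default_rng(5)
        frames = []
        adapters = [-0.7, -0.3, -0.2, -0.1, 0.0, 0.1, 0.2, 0.3, 0.7]
        for j, adapter in enumerate(adapters, start=1):
            shift = -0.1 * np.sign(adapter)  # synthetic PSS shifts
            pre = counts_from_probs(SOAS, _readout_probs(SOAS + 0.02, 0.06,
                                                         0.08, 0.1, 0.02),
                                    20, rng)
            post = counts_from_probs(SOAS, _readout_probs(SOAS + 0.02 + shift,
                                                          0.06, 0.08, 0.1,
                                                          0.02), 20, rng)
            frames.append(session_frame(SOAS, pre, post, session=j,
                                        adapter=adapter))
        return Dataset(pd.concat(frames, ignore_index=True))

    def test_effects_track_generated_shifts(self, nine_session_data):
        summary = recalibration_summary(nine_session_data, n_boot=20,
                                        rng_seed=0)
        effects = summary.table.set_index("session")["effect"]
        # constructed bias shift of -0.1*sign(adapter) moves the PSS by
        # about +0.1*sign(adapter) (the mapping PSS ~ -bias is monotone)
        for j, adapter in zip(summary.table.session,
                              summary.table.adapter_soa_s):
            if adapter < 0:
                assert effects[j] < -0.05
            elif adapter > 0:
                assert effects[j] > 0.05
            else:
                assert abs(effects[j]) < 0.04
        assert summary.asymmetry == pytest.approx(effects.sum())
        lo, hi = summary.asymmetry_ci
        assert lo < hi

    def test_incomplete_design_rejected(self, nine_session_data):
        partial = Dataset(
            nine_session_data.frame[nine_session_data.frame.session <= 3])
        with pytest.raises(ValueError, match="missing sessions"):
            recalibration_summary(partial, n_boot=5)
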