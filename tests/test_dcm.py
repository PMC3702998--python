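"""Model space, forward prediction, variational inversion and comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from prestim_extinct import dcm, synthetic
from prestim_extinct.config import (
    GroundTruth,
    HemodynamicParams,
    null_truth,
    strong_modulation_truth,
)
from prestim_extinct.dcm import (
    DCMModel,
    compare_models,
    connectivity_report,
    default_priors,
    enumerate_model_space,
    family_inference,
    predict_bold,
    two_step_search,
    unpack_theta,
    variational_laplace,
)


class TestModelSpace:
    def test_sixteen_models_in_factorial_order(self):
        space = enumerate_model_space()
        assert len(space.models) == 16
        assert [m.index for m in space.models] == list(range(16))
        assert len(space.intrinsic_families) == 4
        assert all(len(v) == 4 for v in space.intrinsic_families.values())
        assert len(space.extrinsic_families) == 4

    def test_families_partition_the_space(self):
        space = enumerate_model_space()
        for fams in (space.intrinsic_families, space.extrinsic_families):
            all_idx = sorted(i for v in fams.values() for i in v)
            assert all_idx == list(range(16))

    def test_null_model_mask_empty(self):
        m = DCMModel("neither", "neither")
        assert not m.b_mask().any()

    def test_every_level_structured_mask_appears_exactly_once(self):
        """Enumeration oracle: build the 16 expected masks directly from the
        level definitions and match them one-to-one."""
        diag_patterns = {
            "both": (True, True),
            "left": (True, False),
            "right": (False, True),
            "neither": (False, False),
        }
        off_patterns = {
            "both": (True, True),  # (left->right, right->left)
            "left_to_right": (True, False),
            "right_to_left": (False, True),
            "neither": (False, False),
        }
        expected = set()
        for d in diag_patterns.values():
            for o in off_patterns.values():
                m = np.zeros((2, 2), bool)
                m[0, 0], m[1, 1] = d
                m[1, 0], m[0, 1] = o
                expected.add(m.tobytes())
        got = [m.b_mask().tobytes() for m in enumerate_model_space().models]
        assert len(set(got)) == 16
        assert set(got) == expected

    def test_unknown_levels_rejected(self):
        with pytest.raises(ValueError):
            DCMModel("bilateral", "both")


class TestPredictBold:
    def test_prior_mean_predicts_flat_signal(self, strong_dataset):
        m = DCMModel("both", "both")
        y = predict_bold(
            m,
            A=np.array([[-0.5, 0.0], [0.0, -0.5]]),
            B3=np.zeros((2, 2)),
            C=np.zeros((2, 3)),
            inputs=strong_dataset.inputs,
            fine_dt=strong_dataset.fine_dt,
        )
        assert np.allclose(y, 0.0, atol=1e-12)

    def test_truth_parameters_reproduce_generator_output(self, strong_dataset):
        """Single source of truth: the inversion-side forward model under
        the generating parameters equals the generator's noiseless BOLD."""
        truth = strong_dataset.truth
        m = DCMModel("both", "both")
        y = predict_bold(
            m,
            A=truth.A,
            B3=truth.B[2],
            C=truth.C,
            inputs=strong_dataset.inputs,
            fine_dt=strong_dataset.fine_dt,
        )
        assert np.allclose(y, strong_dataset.clean_bold, atol=1e-12)

    def test_masked_modulations_have_no_effect(self, strong_dataset):
        m = DCMModel("left", "neither")  # only B3[0,0] is free
        truth = strong_dataset.truth
        kw = dict(
            A=truth.A, C=truth.C, inputs=strong_dataset.inputs,
            fine_dt=strong_dataset.fine_dt,
        )
        base = predict_bold(m, B3=np.diag([0.3, 0.0]), **kw)
        poked = predict_bold(
            m, B3=np.array([[0.3, 9.0], [9.0, 9.0]]), **kw
        )
        assert np.array_equal(base, poked)


class TestComparison:
    def test_equal_evidence_splits_evenly(self):
        assert np.allclose(compare_models([3.0, 3.0]), [0.5, 0.5])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=16))
    def test_posteriors_normalised_even_for_extreme_evidence(self, F):
        p = compare_models(F)
        assert np.isfinite(p).all()
        assert p.sum() == pytest.approx(1.0)

    def test_log_evidence_difference_sets_odds(self):
        p = compare_models([0.0, np.log(100.0)])
        assert p[1] / p[0] == pytest.approx(100.0, rel=1e-9)

    def test_family_posteriors_flat_for_flat_evidence(self):
        space = enumerate_model_space()
        post = compare_models(np.zeros(16))
        fam = family_inference(post, space.intrinsic_families)
        assert all(v == pytest.approx(0.25) for v in fam.values())

    def test_unequal_family_sizes_reweighted(self):
        """With flat evidence over 6 models split 2/4, equalised family
        priors keep the family posteriors at one half each."""
        post = np.full(6, 1 / 6)
        fam = family_inference(post, {"small": [0, 1], "big": [2, 3, 4, 5]})
        assert fam["small"] == pytest.approx(0.5)
        assert fam["big"] == pytest.approx(0.5)

    def test_dominant_model_dominates_its_family(self):
        space = enumerate_model_space()
        F = np.zeros(16)
        F[5] = 50.0
        fam = family_inference(compare_models(F), space.intrinsic_families)
        winner = space.models[5].intrinsic_level
        assert fam[winner] == pytest.approx(1.0, abs=1e-10)

    def test_incomplete_partition_rejected(self):
        with pytest.raises(ValueError):
            family_inference(np.full(4, 0.25), {"a": [0, 1], "b": [1, 2, 3]})

    def test_no_fits_rejected(self):
        with pytest.raises(ValueError):
            compare_models([])


class TestVariationalLaplace:
    def test_posterior_stays_at_prior_for_prior_generated_data(self):
        """Data generated at the prior mean (flat signal) with no noise:
        the posterior mean must not move."""
        m = DCMModel("both", "both")
        n = 60
        U = np.zeros((n * 16, 3))
        fit = variational_laplace(np.zeros((n, 2)), m, U, max_iter=16)
        priors = default_priors(m)
        assert np.allclose(fit.posterior_mean, priors.mu0, atol=1e-8)

    def test_free_energy_trace_monotonic(self, strong_dataset, dcm_confounds):
        m = DCMModel("both", "both")
        fit = variational_laplace(
            strong_dataset.roi_series,
            m,
            strong_dataset.inputs,
            confounds=dcm_confounds,
        )
        assert fit.converged
        assert np.all(np.diff(fit.trace) >= 0)

    def test_true_model_beats_null_model(self, strong_dataset, dcm_confounds):
        kw = dict(
            inputs=strong_dataset.inputs, confounds=dcm_confounds
        )
        f_true = variational_laplace(
            strong_dataset.roi_series, DCMModel("both", "both"), **kw
        ).free_energy
        f_null = variational_laplace(
            strong_dataset.roi_series, DCMModel("neither", "neither"), **kw
        ).free_energy
        assert f_true > f_null

    def test_occam_property_for_nested_models(self, reduced_schedule, dcm_confounds):
        """On data from the smaller (no-modulation) model, the larger model
        cannot beat it by more than noise-level jitter."""
        ds = synthetic.generate_dataset(reduced_schedule, null_truth(), seed=77)
        kw = dict(inputs=ds.inputs, confounds=dcm_confounds)
        f_small = variational_laplace(
            ds.roi_series, DCMModel("neither", "neither"), **kw
        ).free_energy
        f_big = variational_laplace(
            ds.roi_series, DCMModel("both", "both"), **kw
        ).free_energy
        assert f_big <= f_small + 3.0

    def test_misaligned_inputs_rejected(self, strong_dataset):
        with pytest.raises(ValueError, match="aligned"):
            variational_laplace(
                strong_dataset.roi_series[:-1],
                DCMModel("both", "both"),
                strong_dataset.inputs,
            )

    def test_posterior_covariance_symmetric_psd(self, strong_dataset, dcm_confounds):
        fit = variational_laplace(
            strong_dataset.roi_series,
            DCMModel("both", "both"),
            strong_dataset.inputs,
            confounds=dcm_confounds,
        )
        S = fit.posterior_cov
        assert np.allclose(S, S.T, atol=1e-10)
        assert np.min(np.linalg.eigvalsh(S)) > -1e-12


class TestTwoStepSearch:
    def test_winner_belongs_to_winning_family(self, strong_dataset, dcm_confounds):
        res = two_step_search(
            strong_dataset.roi_series,
            strong_dataset.inputs,
            confounds=dcm_confounds,
        )
        win = res.winning_model
        assert win.intrinsic_level == res.winning_intrinsic
        assert res.model_posteriors.sum() == pytest.approx(1.0)
        assert sum(res.intrinsic_family_posteriors.values()) == pytest.approx(1.0)

    def test_tie_break_warns_and_picks_first(self):
        from prestim_extinct.dcm import _argmax_with_tiebreak

        with pytest.warns(UserWarning, match="tie"):
            got = _argmax_with_tiebreak({"a": 0.5, "b": 0.5}, "family")
        assert got == "a"


class TestConnectivityReport:
    @staticmethod
    def _fit_with(A_entries, B_entries, model):
        priors = default_priors(model)
        theta = priors.mu0.copy()
        theta[:4] = A_entries
        n_b = int(model.b_mask().sum())
        theta[4 : 4 + n_b] = B_entries
        return dcm.DCMFit(
            model=model,
            posterior_mean=theta,
            posterior_cov=np.eye(len(theta)) * 1e-4,
            names=priors.names,
            free_energy=0.0,
            log_precision=1.0,
            trace=[0.0],
            converged=True,
            predicted=np.zeros((1, 2)),
            n_effective=2,
        )

    def test_self_inhibition_decrease_percentage(self):
        m = DCMModel("left", "neither")
        fit = self._fit_with([-0.5, -0.5, 0.0, 0.0], [0.3], m)
        rep = connectivity_report(fit).set_index("connection")
        assert rep.loc["left_self", "self_inhibition_change_pct"] == pytest.approx(60.0)
        assert rep.loc["left_self", "modulated"] == pytest.approx(-0.2)

    def test_inhibitory_to_excitatory_switch_detected(self):
        m = DCMModel("neither", "right_to_left")
        fit = self._fit_with([-0.5, -0.5, -0.1, -0.1], [0.3], m)
        rep = connectivity_report(fit).set_index("connection")
        assert bool(rep.loc["right_to_left", "sign_switch"])
        assert not bool(rep.loc["left_to_right", "sign_switch"])

    def test_zero_modulation_leaves_baseline(self):
        m = DCMModel("neither", "neither")
        fit = self._fit_with([-0.5, -0.5, -0.1, -0.1], [], m)
        rep = connectivity_report(fit)
        assert np.allclose(rep["baseline"], rep["modulated"])

    def test_zero_diagonal_flagged_undefined(self):
        m = DCMModel("left", "neither")
        fit = self._fit_with([0.0, -0.5, 0.0, 0.0], [0.2], m)
        rep = connectivity_report(fit).set_index("connection")
        assert np.isnan(rep.loc["left_self", "self_inhibition_change_pct"])


def test_unpack_roundtrip_matches_mask():
    m = DCMModel("right", "left_to_right")
    priors = default_priors(m)
    theta = np.arange(1.0, len(priors.mu0) + 1)
    A, B, C, scales = unpack_theta(theta, m)
    assert A[0, 0] == 1.0 and A[1, 1] == 2.0 and A[0, 1] == 3.0 and A[1, 0] == 4.0
    B3 = B[2]
    assert B3[1, 1] == 5.0 and B3[1, 0] == 6.0  # masked order: diag then off
    assert B3[0, 0] == 0.0 and B3[0, 1] == 0.0
    assert C[0, 0] == 7.0 and C[1, 1] == 10.0
    assert scales.shape == (2, 2)
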