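"""Forward model and synthetic-data generator."""

import numpy as np
import pytest

from prestim_extinct import forward, paradigm, synthetic
from prestim_extinct.config import GroundTruth, HemodynamicParams
from prestim_extinct.synthetic import (
    PRESTIM_ALL,
    PRESTIM_SEEN,
    STIM_ONSET,
    build_dcm_inputs,
    embed_volume,
    generate_dataset,
)

FINE_DT = 0.125


def single_trial_schedule(label="BS", onset=100.0):
    import pandas as pd

    ev = pd.DataFrame(
        {
            "run": [0],
            "onset": [onset],
            "duration": [0.14],
            "trial_type": ["bilateral"],
            "response": ["both" if label == "BS" else "right"],
            "label": [label],
        }
    )
    return paradigm.TrialSchedule(ev, n_runs=1, run_length=100)


class TestDCMInputs:
    def test_single_seen_trial_boxcars(self):
        sch = single_trial_schedule("BS", onset=100.0)
        U = build_dcm_inputs(sch, prestim_len=7.0, fine_dt=FINE_DT)
        t = np.arange(U.shape[0]) * FINE_DT
        in_window = (t >= 93.0) & (t < 100.0)
        assert np.array_equal(U[:, PRESTIM_ALL], in_window.astype(float))
        assert np.array_equal(U[:, PRESTIM_SEEN], U[:, PRESTIM_ALL])
        assert U[:, STIM_ONSET].sum() == 1.0
        assert U[np.argmin(np.abs(t - 100.0)), STIM_ONSET] == 1.0

    def test_no_seen_trials_means_zero_third_input(self):
        sch = single_trial_schedule("BU")
        U = build_dcm_inputs(sch, fine_dt=FINE_DT)
        assert np.all(U[:, PRESTIM_SEEN] == 0)
        assert U[:, PRESTIM_ALL].sum() > 0

    def test_seen_input_pointwise_below_all_bilateral_input(self, default_schedule):
        U = build_dcm_inputs(default_schedule)
        assert np.all(U[:, PRESTIM_SEEN] <= U[:, PRESTIM_ALL])

    def test_unlabelled_schedule_rejected(self):
        sch = paradigm.generate_schedule(n_runs=1, seed=3)
        with pytest.raises(ValueError, match="unlabelled"):
            build_dcm_inputs(sch)


class TestNeuralModel:
    def test_zero_input_fixed_point(self):
        U = np.zeros((800, 3))
        Z = synthetic.simulate_neural(GroundTruth(), U, FINE_DT)
        assert np.all(Z == 0)

    def test_scalar_linear_step_matches_closed_form(self):
        """One region, A=-1, C=1, unit step input: z(t) = 1 - exp(-t)."""
        n = 1600
        U = np.ones((n, 1))
        Z = forward.simulate_neural_states(
            A=np.array([[-1.0]]), B=[np.zeros((1, 1))], C=np.array([[1.0]]),
            U=U, fine_dt=FINE_DT,
        )
        t = np.arange(n) * FINE_DT
        assert np.max(np.abs(Z[:, 0] - (1 - np.exp(-t)))) < 1e-4

    def test_step_halving_convergence(self):
        """Halving the integration step changes shared-grid states < 1e-6."""
        n = 640
        t = np.arange(n) * FINE_DT
        box = ((t >= 10) & (t < 40)).astype(float)
        U = np.column_stack([box, np.zeros(n), box])
        truth = GroundTruth()
        Z1 = synthetic.simulate_neural(truth, U, FINE_DT)
        U2 = np.repeat(U, 2, axis=0)
        Z2 = synthetic.simulate_neural(truth, U2, FINE_DT / 2)
        assert np.max(np.abs(Z2[::2] - Z1)) < 1e-6

    def test_unstable_system_refused(self):
        with pytest.raises(ValueError, match="unstable"):
            forward.simulate_neural_states(
                A=np.array([[0.1, 0.0], [0.0, -0.5]]),
                B=[np.zeros((2, 2))],
                C=np.zeros((2, 1)),
                U=np.zeros((10, 1)),
                fine_dt=FINE_DT,
            )


class TestBalloonModel:
    def test_resting_state_gives_flat_bold(self):
        Z = np.zeros((400, 2))
        Y = synthetic.simulate_bold(Z, HemodynamicParams(), tr=2.0, fine_dt=FINE_DT)
        assert np.allclose(Y, 0.0, atol=1e-12)

    def test_bold_peak_lags_neural_burst_by_4_to_6_s(self):
        n = 3200
        t = np.arange(n) * FINE_DT
        Z = np.zeros((n, 1))
        Z[(t >= 20.0) & (t < 21.0), 0] = 1.0  # 1 s neural burst at t=20
        Y = forward.simulate_bold_fine(Z, HemodynamicParams(), FINE_DT)
        lag = t[np.argmax(Y[:, 0])] - 20.0
        assert 4.0 <= lag <= 6.0

    def test_near_linearity_at_low_amplitude(self):
        """BOLD of a 1 s box ~ sum of the two half-box responses (< 5% of
        peak), so HRF convolution is an adequate local description."""
        n = 3200
        t = np.arange(n) * FINE_DT
        amp = 0.05
        hemo = HemodynamicParams()

        def bold(lo, hi):
            Z = np.zeros((n, 1))
            Z[(t >= lo) & (t < hi), 0] = amp
            return forward.simulate_bold_fine(Z, hemo, FINE_DT)[:, 0]

        whole = bold(20.0, 21.0)
        parts = bold(20.0, 20.5) + bold(20.5, 21.0)
        err = np.max(np.abs(whole - parts)) / np.max(np.abs(whole))
        assert err < 0.05

    def test_invalid_hemodynamics_rejected(self):
        with pytest.raises(ValueError):
            synthetic.simulate_bold(
                np.zeros((10, 2)), HemodynamicParams(tau=-1.0), tr=2.0, fine_dt=FINE_DT
            )


class TestGenerateDataset:
    def test_noiseless_dataset_is_exact_and_clean(self, reduced_schedule):
        truth = GroundTruth(sigma_noise=0.0, drift_amp=0.0, run_offset_amp=0.0)
        a = generate_dataset(reduced_schedule, truth, seed=1)
        b = generate_dataset(reduced_schedule, truth, seed=2)
        assert np.array_equal(a.roi_series, a.clean_bold)
        assert np.array_equal(a.roi_series, b.roi_series)

    def test_same_seed_bit_identical(self, reduced_schedule):
        a = generate_dataset(reduced_schedule, GroundTruth(), seed=5)
        b = generate_dataset(reduced_schedule, GroundTruth(), seed=5)
        assert np.array_equal(a.roi_series, b.roi_series)

    def test_prestimulus_bold_higher_before_seen_trials(self, default_schedule):
        """With all four modulations positive before seen trials, the mean
        noiseless BOLD over [-7, -1] s is higher before BS than BU trials
        in both regions."""
        truth = GroundTruth(sigma_noise=0.0, drift_amp=0.0, run_offset_amp=0.0)
        ds = generate_dataset(default_schedule, truth, seed=0)
        onsets = default_schedule.concat_onsets()
        labels = default_schedule.events["label"].to_numpy()
        tr = default_schedule.tr

        def prestim_mean(lab):
            vals = []
            for o in onsets[labels == lab]:
                scans = np.arange(int(np.ceil((o - 7) / tr)), int((o - 1) // tr) + 1)
                vals.append(ds.clean_bold[scans].mean(axis=0))
            return np.mean(vals, axis=0)

        bs, bu = prestim_mean("BS"), prestim_mean("BU")
        assert bs[0] > bu[0] and bs[1] > bu[1]

    def test_no_modulation_means_no_seen_unseen_asymmetry(self, reduced_schedule):
        from prestim_extinct.config import null_truth

        truth = null_truth(sigma_noise=0.0)
        ds = generate_dataset(reduced_schedule, truth, seed=0)
        ev = reduced_schedule.events
        onsets = reduced_schedule.concat_onsets()
        bs = np.array(
            [ds.clean_bold[int(o // 2)] for o, l in zip(onsets, ev["label"]) if l == "BS"]
        )
        bu = np.array(
            [ds.clean_bold[int(o // 2)] for o, l in zip(onsets, ev["label"]) if l == "BU"]
        )
        # identical drive and coupling: onset-locked levels differ only by
        # trial-history sampling, so means agree within 3 standard errors
        se = np.sqrt(bs.var(axis=0) / len(bs) + bu.var(axis=0) / len(bu))
        assert np.all(np.abs(bs.mean(axis=0) - bu.mean(axis=0)) < 3 * se)

    def test_causality_under_input_truncation(self, reduced_schedule):
        """Editing inputs after time T leaves BOLD before T unchanged."""
        truth = GroundTruth(sigma_noise=0.0, drift_amp=0.0, run_offset_amp=0.0)
        ds = generate_dataset(reduced_schedule, truth, seed=0)
        U = ds.inputs.copy()
        cut = U.shape[0] // 2
        U[cut:] = 0.0
        Z = synthetic.simulate_neural(truth, U, ds.fine_dt)
        Y = synthetic.simulate_bold(Z, truth.hemo, reduced_schedule.tr, ds.fine_dt)
        n_scans_before = cut // round(reduced_schedule.tr / ds.fine_dt)
        assert np.allclose(Y[:n_scans_before], ds.clean_bold[:n_scans_before], atol=1e-12)

    def test_bounded_dynamics_at_defaults(self, default_dataset):
        assert np.all(np.isfinite(default_dataset.roi_series))
        assert np.max(np.abs(default_dataset.clean_bold)) < 20.0


class TestEmbedVolume:
    def test_delta_blob_occupies_single_voxel(self, reduced_schedule):
        truth = GroundTruth(sigma_noise=0.0, drift_amp=0.0, run_offset_amp=0.0)
        ds = generate_dataset(reduced_schedule, truth, seed=0)
        vol_ds = embed_volume(ds, grid_shape=(8, 6, 4), blob_sigma=0.0, noise_sd=0.0)
        nonzero = np.any(vol_ds.volume != 0, axis=-1)
        assert nonzero.sum() == 2
        assert vol_ds.roi_masks.sum() == 2

    def test_blob_centre_carries_roi_series(self, reduced_schedule):
        truth = GroundTruth(sigma_noise=0.0, drift_amp=0.0, run_offset_amp=0.0)
        ds = generate_dataset(reduced_schedule, truth, seed=0)
        vol_ds = embed_volume(ds, blob_sigma=1.0, noise_sd=0.0)
        for r, c in enumerate(vol_ds.blob_centres):
            series = vol_ds.volume[tuple(c)]
            rho = np.corrcoef(series, ds.roi_series[:, r])[0, 1]
            assert rho >= 0.99

    def test_total_signal_equals_kernel_sum(self, reduced_schedule):
        truth = GroundTruth(sigma_noise=0.0, drift_amp=0.0, run_offset_amp=0.0)
        ds = generate_dataset(reduced_schedule, truth, seed=0)
        sigma = 1.0
        vol_ds = embed_volume(ds, grid_shape=(14, 10, 8), blob_sigma=sigma, noise_sd=0.0)
        ix, iy, iz = np.meshgrid(
            np.arange(14), np.arange(10), np.arange(8), indexing="ij"
        )
        expected = np.zeros(ds.n_scans)
        for r, c in enumerate(vol_ds.blob_centres):
            d2 = (ix - c[0]) ** 2 + (iy - c[1]) ** 2 + (iz - c[2]) ** 2
            expected += np.exp(-0.5 * d2 / sigma**2).sum() * ds.roi_series[:, r]
        got = vol_ds.volume.sum(axis=(0, 1, 2))
        assert np.allclose(got, expected, atol=1e-8)

    def test_overlapping_blobs_rejected(self, reduced_schedule):
        ds = generate_dataset(reduced_schedule, GroundTruth(), seed=0)
        with pytest.raises(ValueError, match="overlap|grid"):
            embed_volume(ds, grid_shape=(4, 4, 4), blob_sigma=2.0)


def test_roi_tsv_roundtrip(tmp_path, reduced_schedule):
    ds = generate_dataset(reduced_schedule, GroundTruth(), seed=0)
    p = ds.roi_to_tsv(tmp_path / "roi.tsv")
    back = synthetic.read_roi_tsv(p)
    assert back.shape == ds.roi_series.shape
    assert np.allclose(back, ds.roi_series, atol=1e-5)


def test_volume_nifti_records_tr(tmp_path, reduced_schedule):
    import nibabel as nib

    truth = GroundTruth(sigma_noise=0.0, drift_amp=0.0, run_offset_amp=0.0)
    ds = generate_dataset(reduced_schedule, truth, seed=0)
    vol_ds = embed_volume(ds, noise_sd=0.0)
    p = vol_ds.volume_to_nifti(tmp_path / "bold.nii.gz")
    img = nib.load(str(p))
    assert img.shape == vol_ds.volume.shape
    assert img.header.get_zooms()[3] == pytest.approx(reduced_schedule.tr)
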