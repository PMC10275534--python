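"""FIR design construction, nuisance assembly and GLM residualization."""

import logging

import numpy as np
import pytest

from bgconn.filtering import highpass
from bgconn.synthetic import GroundTruthSpec, make_onsets, simulate_subject
from bgconn.task_removal import (
    build_fir_design,
    build_nuisance,
    fir_residuals,
    lpf_dataset,
)
from bgconn.types import ConfoundSet, ParcelTimeSeries

from conftest import small_spec


def ts_from(data: np.ndarray, tr: float = 2.0) -> ParcelTimeSeries:
    ids = tuple(f"p{i}" for i in range(data.shape[1]))
    return ParcelTimeSeries(data, tr, ids, task="task")


def ols_residuals_oracle(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent normal-equations solve: beta = (X'X)^-1 X'y."""
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return y - X @ beta


class TestFIRDesign:
    def test_default_trial_train_placement(self):
        onsets = make_onsets(GroundTruthSpec(n_subjects=1))
        design = build_fir_design(onsets, 2.0, 110)
        assert design.matrix.shape == (110, 6)
        expected_rows = np.arange(2, 105, 6)  # volumes 2, 8, ..., 104
        np.testing.assert_array_equal(
            np.flatnonzero(design.matrix[:, 0]), expected_rows
        )
        assert (design.matrix.sum(axis=0) == 18).all()

    def test_single_onset_at_zero_gives_identity(self):
        design = build_fir_design([0.0], 2.0, 6)
        np.testing.assert_array_equal(design.matrix, np.eye(6))

    def test_non_overlapping_windows_are_orthogonal(self):
        design = build_fir_design([0.0, 12.0, 24.0], 2.0, 36)
        gram = design.matrix.T @ design.matrix
        np.testing.assert_array_equal(gram - np.diag(np.diag(gram)), 0.0)

    def test_window_truncated_at_run_end(self):
        design = build_fir_design([4.0], 2.0, 5)  # window runs past volume 4
        assert design.matrix[:, 0].sum() == 1
        assert design.matrix[:, 3:].sum() == 0

    def test_onset_beyond_run_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            build_fir_design([4.0, 300.0], 2.0, 110)


class TestNuisance:
    def _confounds(self, motion, physio):
        return ConfoundSet(
            motion=motion, csf=physio[:, 0], white_matter=physio[:, 1],
            global_signal=physio[:, 2],
        )

    def test_constant_confounds_center_to_zero(self):
        conf = self._confounds(np.ones((10, 6)), np.full((10, 3), 5.0))
        np.testing.assert_allclose(build_nuisance(conf), 0.0, atol=1e-12)

    def test_ramp_motion_gives_constant_derivative(self):
        motion = np.outer(np.arange(10), 0.1 * np.ones(6))
        conf = self._confounds(motion, np.zeros((10, 3)))
        mat = build_nuisance(conf)
        # columns 9..14 are motion derivatives; rows >= 1 equal 0.1 pre-centering
        deriv = mat[:, 9:15] + 0.1 * 9 / 10  # undo mean-centering of [0, .1 x 9]
        np.testing.assert_allclose(deriv[1:], 0.1, atol=1e-12)
        np.testing.assert_allclose(deriv[0], 0.0, atol=1e-12)

    def test_eighteen_columns(self):
        rng = np.random.default_rng(0)
        conf = self._confounds(rng.normal(size=(10, 6)), rng.normal(size=(10, 3)))
        assert build_nuisance(conf).shape == (10, 18)


class TestFIRResiduals:
    def test_signal_in_model_span_removed(self):
        design = build_fir_design([0.0, 12.0], 2.0, 14)
        betas = np.array([3.0, -1.0, 2.0, 0.5, 4.0, -2.0])
        ts = ts_from((design.matrix @ betas)[:, None] + 9.0)
        out = fir_residuals(ts, design)
        assert np.abs(out.data).max() < 1e-8

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(1)
        design = build_fir_design([0.0, 12.0, 24.0], 2.0, 40)
        nuisance = rng.normal(size=(40, 4))
        ts = ts_from(rng.normal(size=(40, 3)))
        out = fir_residuals(ts, design, nuisance)
        X = np.column_stack([np.ones(40), design.matrix, nuisance])
        inner = np.abs(X.T @ out.data) / 40
        assert inner.max() < 1e-8

    def test_residual_variance_never_increases(self):
        rng = np.random.default_rng(2)
        design = build_fir_design([0.0, 12.0], 2.0, 30)
        ts = ts_from(rng.normal(size=(30, 2)))
        out = fir_residuals(ts, design)
        assert (out.data.var(axis=0) <= ts.data.var(axis=0) + 1e-12).all()

    def test_matches_normal_equations_oracle(self):
        # small instances: residuals must agree with an independently coded
        # normal-equations solve to 1e-10
        rng = np.random.default_rng(3)
        design = build_fir_design([0.0, 12.0], 2.0, 20)
        nuisance = rng.normal(size=(20, 3))
        ts = ts_from(rng.normal(size=(20, 3)))
        out = fir_residuals(ts, design, nuisance)
        X = np.column_stack([np.ones(20), design.matrix, nuisance])
        expected = ols_residuals_oracle(X, ts.data)
        np.testing.assert_allclose(out.data, expected, atol=1e-10)

    def test_recovers_intrinsic_signal(self):
        # observed = intrinsic + design @ betas: residuals are the intrinsic
        # component minus its (small) projection on the model
        rng = np.random.default_rng(4)
        onsets = list(make_onsets(GroundTruthSpec(n_subjects=1)))
        design = build_fir_design(onsets, 2.0, 110)
        intrinsic = rng.normal(size=(110, 2))
        betas = rng.normal(size=(6, 2)) * 3
        ts = ts_from(intrinsic + design.matrix @ betas)
        out = fir_residuals(ts, design)
        for j in range(2):
            assert np.corrcoef(out.data[:, j], intrinsic[:, j])[0, 1] > 0.95

    def test_collinear_columns_pruned_with_warning(self, caplog):
        design = build_fir_design([0.0], 2.0, 12)
        nuisance = np.zeros((12, 2))  # zero columns: exactly collinear
        ts = ts_from(np.random.default_rng(5).normal(size=(12, 1)))
        with caplog.at_level(logging.WARNING):
            fir_residuals(ts, design, nuisance)
        assert "collinear" in caplog.text


@pytest.fixture(scope="module")
def task_run():
    spec = GroundTruthSpec(n_subjects=1, seed=11, spike_prob=0.0)
    subj = simulate_subject(spec, 0)
    return spec, subj.task_runs[0]


class TestTaskRemovalEndToEnd:
    def _trial_locked_peak(self, data, onset_vols, amp_mask):
        epochs = np.stack([data[v : v + 6, amp_mask] for v in onset_vols])
        mean_response = epochs.mean(axis=(0, 2))
        return np.ptp(mean_response)

    def test_both_methods_suppress_trial_locked_mean(self, task_run):
        spec, run = task_run
        onset_vols = [int(o / spec.tr_s) for o in run.onsets_s]
        responsive = spec.task_amplitude > 0
        hp = highpass(run.ts)
        raw_peak = self._trial_locked_peak(hp.data, onset_vols, responsive)
        design = build_fir_design(list(run.onsets_s), spec.tr_s, run.ts.n_volumes)
        for removed in (lpf_dataset(hp), fir_residuals(hp, design)):
            peak = self._trial_locked_peak(removed.data, onset_vols, responsive)
            assert peak < 0.10 * raw_peak

    def test_lpf_crushes_task_frequency_bin(self, task_run):
        spec, run = task_run
        hp = highpass(run.ts)
        out = lpf_dataset(hp)
        freqs = np.fft.rfftfreq(run.ts.n_volumes, spec.tr_s)
        band = (freqs > 1 / 13.5) & (freqs < 1 / 10.5)
        responsive = spec.task_amplitude > 0
        power_in = (np.abs(np.fft.rfft(hp.data[:, responsive], axis=0)) ** 2)[band]
        power_out = (np.abs(np.fft.rfft(out.data[:, responsive], axis=0)) ** 2)[band]
        assert power_out.sum() < 0.01 * power_in.sum()

    def test_fir_preserves_offband_spectrum(self, task_run):
        # residualization should leave broadband intrinsic content intact
        # away from the trial frequency and its harmonics
        spec, run = task_run
        hp = highpass(run.ts)
        design = build_fir_design(list(run.onsets_s), spec.tr_s, run.ts.n_volumes)
        out = fir_residuals(hp, design)
        freqs = np.fft.rfftfreq(run.ts.n_volumes, spec.tr_s)
        harmonics = np.arange(1, 4) / 12.0
        offband = np.ones_like(freqs, dtype=bool)
        for h in harmonics:
            offband &= np.abs(freqs - h) > 0.01
        offband &= freqs > 0
        p_in = (np.abs(np.fft.rfft(hp.data, axis=0)) ** 2)[offband].sum()
        p_out = (np.abs(np.fft.rfft(out.data, axis=0)) ** 2)[offband].sum()
        assert p_out / p_in > 0.90

    def test_zero_input_zero_output(self):
        ts = ts_from(np.zeros((30, 2)))
        assert np.abs(lpf_dataset(ts).data).max() < 1e-12
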