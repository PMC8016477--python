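"""Trial extraction, z-scoring, outlier fences, net AUC, aggregation."""
import numpy as np
import pytest

from photoperant import perievent
from photoperant.photometry import DffTrace
from photoperant.perievent import (
    PeriEventTensor,
    aggregate,
    bin_centers,
    extract_trials,
    net_auc,
    remove_outlier_trials,
    zscore_trials,
)


def make_dff(values, fs=20.0):
    t = np.arange(values.size) / fs
    return DffTrace(t, values, np.ones_like(values), sampling_rate_hz=fs)


CENTERS = bin_centers()


class TestExtractTrials:
    def test_bin_count_is_200(self):
        dff = make_dff(np.zeros(20 * 60))
        raw, kept, dropped = extract_trials(dff, np.array([30.0]))
        assert raw.shape == (1, 200)
        assert dropped == 0

    def test_edge_events_dropped(self):
        dff = make_dff(np.zeros(20 * 60))
        raw, kept, dropped = extract_trials(dff, np.array([3.0, 30.0, 58.0]))
        assert raw.shape[0] == 1
        assert dropped == 2
        np.testing.assert_allclose(kept, [30.0])

    def test_impulse_lands_in_zero_bin(self):
        values = np.zeros(20 * 60)
        values[int(30.0 * 20)] = 1.0
        raw, _, _ = extract_trials(make_dff(values), np.array([30.0]))
        peak_bin = np.argmax(raw[0])
        assert CENTERS[peak_bin] == pytest.approx(0.025)  # bin containing t=0

    def test_no_valid_events_is_empty_not_error(self):
        dff = make_dff(np.zeros(20 * 8))
        raw, kept, dropped = extract_trials(dff, np.array([1.0]))
        assert raw.shape == (0, 200)
        assert dropped == 1

    def test_bin_means_against_direct_average(self, rng):
        """Each 50 ms bin holds the mean of its samples (40 Hz: 2 per bin)."""
        fs = 40.0
        values = rng.normal(size=int(fs * 30))
        dff = DffTrace(np.arange(values.size) / fs, values,
                       np.ones_like(values), sampling_rate_hz=fs)
        raw, _, _ = extract_trials(dff, np.array([15.0]))
        i0 = int((15.0 - 5.0) * fs)
        expected = values[i0:i0 + 400].reshape(200, 2).mean(axis=1)
        np.testing.assert_allclose(raw[0], expected, atol=1e-12)


class TestZscoreTrials:
    def test_pooled_baseline_standardized(self, rng):
        raw = rng.normal(3.0, 2.0, size=(10, 200))
        t = zscore_trials(raw, CENTERS, session_id="s1")
        bmask = t.window_mask((-5.0, -2.0))
        base = t.z[:, bmask].ravel()
        assert base.mean() == pytest.approx(0.0, abs=1e-9)
        assert base.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_constant_trial_at_baseline_mean_is_zero(self, rng):
        raw = rng.normal(0.0, 1.0, size=(5, 200))
        mu = raw[:, CENTERS < -2.0].mean()
        raw = np.vstack([raw, np.full((1, 200), mu)])
        t = zscore_trials(raw, CENTERS)
        np.testing.assert_allclose(t.z[-1], 0.0, atol=1e-9)

    def test_planted_three_sigma_response(self, rng):
        raw = rng.normal(0.0, 1.0, size=(50, 200))
        sd = raw[:, CENTERS < -2.0].std(ddof=1)
        resp = (CENTERS >= 0) & (CENTERS < 1)
        raw[:, resp] += 3.0 * sd
        t = zscore_trials(raw, CENTERS)
        assert t.z[:, resp].mean() == pytest.approx(3.0, abs=0.2)

    def test_zero_variance_rejected(self):
        with pytest.raises(perievent.PeriEventError):
            zscore_trials(np.ones((3, 200)), CENTERS)


class TestRemoveOutlierTrials:
    @staticmethod
    def tensor_from_peaks(peaks):
        z = np.zeros((len(peaks), 200))
        mid = np.argmin(np.abs(CENTERS))  # a bin inside the analysis window
        z[:, mid] = peaks
        return PeriEventTensor(z=z, bin_centers_s=CENTERS)

    def test_hand_worked_fence(self):
        # peaks {1,2,3,4,100}: median 3, scaled MAD 1.4826 -> only 100 is out
        t, keep = remove_outlier_trials(self.tensor_from_peaks([1, 2, 3, 4, 100]))
        assert t.n_trials == 4
        assert not keep[-1]

    def test_identical_peaks_kept(self):
        t, keep = remove_outlier_trials(self.tensor_from_peaks([2, 2, 2, 2]))
        assert keep.all()

    def test_mad_zero_warns(self):
        with pytest.warns(UserWarning, match="zero MAD"):
            t, keep = remove_outlier_trials(self.tensor_from_peaks([1, 2, 2, 2, 2]))
        assert t.n_trials == 4

    def test_normal_tail_fraction(self, rng):
        # scaled MAD is sigma-consistent: ~0.27% of N(0,1) peaks removed
        peaks = rng.standard_normal(10_000)
        _, keep = remove_outlier_trials(self.tensor_from_peaks(peaks))
        frac = 1.0 - keep.mean()
        assert 0.0005 < frac < 0.007

    def test_signed_extremum_is_used(self):
        t = self.tensor_from_peaks([-1.0, -1.0, -1.0, -1.0])
        peaks = perievent.trial_peaks(t)
        np.testing.assert_allclose(peaks, -1.0)


class TestNetAuc:
    def test_unit_constant_is_exactly_four(self):
        z = np.ones(200)
        assert net_auc(z, CENTERS) == pytest.approx(4.0, abs=1e-12)

    def test_half_sine_matches_analytic(self):
        z = np.where((CENTERS >= -2) & (CENTERS < 2),
                     np.sin(np.pi * (CENTERS + 2.0) / 4.0), 0.0)
        assert net_auc(z, CENTERS) == pytest.approx(8.0 / np.pi, abs=1e-3)

    def test_antisymmetric_is_zero(self):
        z = np.where((CENTERS >= -2) & (CENTERS < 2), CENTERS, 0.0)
        assert net_auc(z, CENTERS) == pytest.approx(0.0, abs=1e-9)

    def test_linearity(self, rng):
        z1 = rng.normal(size=200)
        z2 = rng.normal(size=200)
        lhs = net_auc(2.0 * z1 - 3.0 * z2, CENTERS)
        rhs = 2.0 * net_auc(z1, CENTERS) - 3.0 * net_auc(z2, CENTERS)
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_matrix_rows(self, rng):
        z = rng.normal(size=(7, 200))
        rows = net_auc(z, CENTERS)
        assert rows.shape == (7,)
        assert rows[3] == pytest.approx(net_auc(z[3], CENTERS))


class TestAggregate:
    @staticmethod
    def tensor_with_sessions(rng, trials_per_session):
        parts = []
        for sid, n in trials_per_session.items():
            raw = rng.normal(size=(n, 200))
            parts.append(zscore_trials(raw, CENTERS, session_id=sid))
        return perievent.concat_tensors(parts)

    def test_row_counts(self, rng):
        t = self.tensor_with_sessions(rng, {"a": 10, "b": 10, "c": 10})
        rows_all, _, auc_all = aggregate(t, "all_event_trials")
        rows_sess, ids, auc_sess = aggregate(t, "session_average")
        assert rows_all.shape[0] == 30
        assert rows_sess.shape[0] == 3
        assert list(ids) == ["a", "b", "c"]
        assert auc_all.size == 30 and auc_sess.size == 3

    def test_single_trial_sessions_coincide(self, rng):
        t = self.tensor_with_sessions(rng, {"a": 4})
        # one session -> session_average is the mean of its trials
        rows_sess, _, _ = aggregate(t, "session_average")
        np.testing.assert_allclose(rows_sess[0], t.z.mean(axis=0))

    def test_session_mean_vs_trial_mean_weighting(self, rng):
        """With unequal trial counts the session-average grand mean is the
        unweighted mean of session means, not the pooled trial mean."""
        t = self.tensor_with_sessions(rng, {"a": 2, "b": 40})
        rows_sess, _, _ = aggregate(t, "session_average")
        grand_sess = rows_sess.mean(axis=0)
        expected = 0.5 * (t.z[:2].mean(axis=0) + t.z[2:].mean(axis=0))
        np.testing.assert_allclose(grand_sess, expected, atol=1e-12)
        trial_mean = t.z.mean(axis=0)
        assert not np.allclose(grand_sess, trial_mean)

    def test_unknown_mode(self, rng):
        t = self.tensor_with_sessions(rng, {"a": 3})
        with pytest.raises(perievent.PeriEventError):
            aggregate(t, "bogus")
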