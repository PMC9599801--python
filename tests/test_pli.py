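"""Phase lag index core: phase extraction, pairwise PLI, connectivity
matrices and the global synchronization measure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plimci.pli import (
    ALPHA,
    BANDS,
    ConnectivityMatrix,
    band_phase,
    connectivity_matrix,
    extract_pairs,
    global_pli,
    pli_pair,
    wrap_phase,
)
from plimci.preprocess import segment_epochs
from plimci.recording import EEGRecording, EpochSet
from plimci.synth import RecordingSpec, generate_recording


def _matrix(values, labels=None, band=ALPHA):
    labels = labels or [f"ch{i}" for i in range(values.shape[0])]
    return ConnectivityMatrix(values=values, band=band, channel_labels=labels,
                              n_epochs_averaged=1)


@given(st.floats(-50, 50))
def test_wrap_phase_matches_complex_angle(phi):
    wrapped = wrap_phase(phi)
    assert -np.pi < wrapped <= np.pi + 1e-12
    assert np.isclose(np.angle(np.exp(1j * phi)), wrapped, atol=1e-9) or np.isclose(
        abs(wrapped), np.pi, atol=1e-9
    )


class TestPliPair:
    def test_identical_channels_give_zero(self, rng):
        phases = rng.uniform(-np.pi, np.pi, 500)
        assert pli_pair(phases, phases) == 0.0

    def test_constant_quarter_cycle_lag_gives_one(self, rng):
        phases = rng.uniform(-np.pi, np.pi, 500)
        assert pli_pair(wrap_phase(phases + np.pi / 2), phases) == 1.0

    def test_empty_sequences_raise(self):
        with pytest.raises(ValueError):
            pli_pair(np.array([]), np.array([]))

    def test_independent_phases_near_iid_floor(self, rng):
        # light version of the estimator-floor check (the full 1e4-replicate
        # version lives in the acceptance suite)
        n, reps = 1500, 2000
        values = [
            pli_pair(rng.uniform(-np.pi, np.pi, n), rng.uniform(-np.pi, np.pi, n))
            for _ in range(reps)
        ]
        floor = np.sqrt(2 / (np.pi * n))
        se = np.std(values) / np.sqrt(reps)
        assert abs(np.mean(values) - floor) < 4 * se


class TestBandPhase:
    def test_pure_alpha_tone_phase_velocity(self, sinusoid_factory):
        rec = sinusoid_factory(10.0, fs=500.0, duration=9.0)
        es = segment_epochs(rec, 3.0)
        ps = band_phase(es, ALPHA)
        unwrapped = np.unwrap(ps.phases[1, 0])
        slope = np.polyfit(np.arange(unwrapped.size) / 500.0, unwrapped, 1)[0]
        assert abs(slope - 2 * np.pi * 10.0) < 0.1

    def test_quadrature_phase_difference(self, quadrature_epochs):
        ps = band_phase(quadrature_epochs, ALPHA)
        delta = wrap_phase(ps.phases[:, 0] - ps.phases[:, 1])
        # residual filter/Hilbert edge curvature reaches ~0.03 rad at the
        # trim boundary; the lag itself is recovered everywhere
        np.testing.assert_allclose(delta, np.pi / 2, atol=0.05)

    def test_zero_signal_flagged_as_undefined_phase(self):
        es = EpochSet(
            epochs=np.zeros((2, 2, 300)), epoch_length=3.0, sampling_rate=100.0,
            channel_labels=["a", "b"], kept_epoch_indices=np.arange(2),
        )
        with pytest.raises(ValueError, match="phase"):
            band_phase(es, ALPHA)

    def test_band_outside_nyquist_rejected(self, quadrature_epochs):
        quadrature_epochs.sampling_rate = 20.0
        with pytest.raises(ValueError, match="Nyquist"):
            band_phase(quadrature_epochs, ALPHA)

    def test_edge_trim_bounds(self, quadrature_epochs):
        with pytest.raises(ValueError):
            band_phase(quadrature_epochs, ALPHA, edge_trim=0.5)


class TestConnectivityMatrix:
    def test_identical_channels_give_zero_matrix(self, rng):
        base = rng.standard_normal(3000)
        data = np.stack([base, base, base])
        rec = EEGRecording(channel_labels=["a", "b", "c"], sampling_rate=500.0, data=data)
        cm = connectivity_matrix(segment_epochs(rec, 3.0), ALPHA)
        np.testing.assert_array_equal(cm.values, 0.0)

    def test_noiseless_lagged_pair_locks_fully(self):
        # a quarter-cycle lag with no noise: every retained sample leads, so
        # PLI -> 1 (exactly 1 in the narrowband limit; a 1 Hz-wide source
        # keeps the lag-induced decorrelation negligible)
        spec = RecordingSpec(
            n_channels=2, sampling_rate=250.0, duration=30.0,
            coupling_strength={"alpha": 1.0},
            oscillator_bands={"alpha": (10.5, 1.0)},
            channel_phase_lags=np.array([0.0, np.pi / 2]),
            noise_sd=0.0,
        )
        rec = generate_recording(spec, seed=0)
        cm = connectivity_matrix(segment_epochs(rec, 3.0), ALPHA)
        assert cm.values[0, 1] >= 0.995

    def test_sinusoidal_quadrature_pair_gives_exactly_one(self, quadrature_epochs):
        cm = connectivity_matrix(quadrature_epochs, ALPHA)
        assert cm.values[0, 1] == 1.0

    def test_invariants_on_noisy_data(self, rng):
        rec = EEGRecording(
            channel_labels=[f"c{i}" for i in range(5)], sampling_rate=250.0,
            data=rng.standard_normal((5, 7500)),
        )
        for band in BANDS.values():
            cm = connectivity_matrix(segment_epochs(rec, 3.0), band)
            assert np.all(cm.values >= 0) and np.all(cm.values <= 1)
            np.testing.assert_array_equal(cm.values, cm.values.T)
            np.testing.assert_array_equal(np.diag(cm.values), 0.0)

    def test_single_channel_rejected(self, rng):
        rec = EEGRecording(channel_labels=["a"], sampling_rate=250.0,
                           data=rng.standard_normal((1, 750)))
        with pytest.raises(ValueError):
            connectivity_matrix(segment_epochs(rec, 3.0), ALPHA)

    def test_channel_permutation_consistency(self, rng):
        data = rng.standard_normal((4, 7500))
        labels = ["a", "b", "c", "d"]
        rec = EEGRecording(channel_labels=labels, sampling_rate=250.0, data=data)
        cm = connectivity_matrix(segment_epochs(rec, 3.0), ALPHA)
        perm = [2, 0, 3, 1]
        rec_p = EEGRecording(channel_labels=[labels[i] for i in perm],
                             sampling_rate=250.0, data=data[perm])
        cm_p = connectivity_matrix(segment_epochs(rec_p, 3.0), ALPHA)
        np.testing.assert_allclose(cm_p.values, cm.values[np.ix_(perm, perm)])
        assert np.isclose(global_pli(cm_p), global_pli(cm))

    def test_volume_conduction_vs_lagged_copy(self, rng):
        # zero-lag mixtures of one source must look like no coupling, while a
        # quarter-cycle lagged copy locks at PLI ~ 1: the defining robustness
        # of the phase lag index.
        lagged_spec = RecordingSpec(
            n_channels=2, sampling_rate=250.0, duration=60.0,
            coupling_strength={"alpha": 1.0},
            oscillator_bands={"alpha": (10.5, 5.0)},
            channel_phase_lags=np.array([0.0, np.pi / 2]),
            noise_sd=0.3, noise_color="white",
        )
        zero_lag_spec = RecordingSpec(
            n_channels=2, sampling_rate=250.0, duration=60.0,
            coupling_strength={"alpha": 1.0},
            oscillator_bands={"alpha": (10.5, 5.0)},
            channel_phase_lags=np.array([0.0, 0.0]),
            noise_sd=0.3, noise_color="white",
        )
        rec = generate_recording(lagged_spec, seed=1)
        lagged = connectivity_matrix(segment_epochs(rec, 3.0), ALPHA).values[0, 1]
        assert lagged > 0.9
        rec = generate_recording(zero_lag_spec, seed=1)
        zero_lag = connectivity_matrix(segment_epochs(rec, 3.0), ALPHA).values[0, 1]
        assert zero_lag < 0.25  # at the epoch-averaged estimator floor


class TestGlobalPli:
    def test_zero_matrix(self):
        assert global_pli(_matrix(np.zeros((4, 4)))) == 0.0

    def test_constant_off_diagonal(self):
        v = np.full((5, 5), 0.37)
        np.fill_diagonal(v, 0.0)
        assert np.isclose(global_pli(_matrix(v)), 0.37)

    def test_matches_explicit_enumeration(self, rng):
        n = 62
        v = rng.uniform(0, 1, (n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        cm = _matrix(v)
        total, count = 0.0, 0
        for i in range(n):
            for j in range(i + 1, n):
                total += v[i, j]
                count += 1
        assert count == 1891
        assert np.isclose(global_pli(cm), total / count, rtol=1e-12)


class TestExtractPairs:
    def _planted(self):
        labels = ["F4", "P3", "C3", "O1"]
        v = np.zeros((4, 4))
        v[0, 1] = v[1, 0] = 0.41
        v[2, 1] = v[1, 2] = 0.17
        return _matrix(v, labels)

    def test_exact_retrieval_and_symmetry(self):
        cm = self._planted()
        assert extract_pairs(cm, [("F4", "P3")]) == [0.41]
        assert extract_pairs(cm, [("P3", "F4")]) == [0.41]
        assert extract_pairs(cm, [("C3", "P3"), ("F4", "P3")]) == [0.17, 0.41]

    def test_diagonal_pair_is_zero(self):
        assert extract_pairs(self._planted(), [("C3", "C3")]) == [0.0]

    def test_unknown_label_named_in_error(self):
        with pytest.raises(KeyError, match="Cz"):
            extract_pairs(self._planted(), [("Cz", "P3")])


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_pli_pair_bounds_property(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 50))
    p1 = rng.uniform(-np.pi, np.pi, n)
    p2 = rng.uniform(-np.pi, np.pi, n)
    v = pli_pair(p1, p2)
    assert 0.0 <= v <= 1.0
    assert np.isclose(v, pli_pair(p2, p1))  # symmetric under channel swap
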