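"""Synthetic cohort generator: determinism, signal model, analytic ground
truth, and the cohort table."""

import numpy as np
import pytest

from plimci.pli import ALPHA
from plimci.preprocess import segment_epochs
from plimci.pli import connectivity_matrix, global_pli
from plimci.synth import (
    CohortSpec,
    GroundTruth,
    MocaModel,
    RecordingSpec,
    default_phase_lags,
    generate_cohort,
    generate_recording,
    phase_difference_density,
    pli_infinity,
    reduced_recording_spec,
    subject_seed,
    true_global_pli,
)


def small_spec(**kw):
    base = dict(n_channels=4, sampling_rate=250.0, duration=30.0)
    base.update(kw)
    return RecordingSpec(**base)


class TestGenerateRecording:
    def test_deterministic_given_seed(self):
        spec = small_spec()
        a = generate_recording(spec, seed=3)
        b = generate_recording(spec, seed=3)
        np.testing.assert_array_equal(a.data, b.data)
        c = generate_recording(spec, seed=4)
        assert not np.array_equal(a.data, c.data)

    def test_sample_count_matches_duration(self):
        spec = RecordingSpec(n_channels=4, sampling_rate=1000.0, duration=300.0)
        rec = generate_recording(spec, seed=0)
        assert rec.n_samples == 300_000

    def test_aux_channels_appended(self):
        rec = generate_recording(small_spec(include_aux=True), seed=0)
        assert rec.channel_labels[-4:] == ["M1", "M2", "HEO", "VEO"]

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            RecordingSpec(n_channels=1)
        with pytest.raises(ValueError):
            RecordingSpec(n_channels=4, duration=-1.0)
        with pytest.raises(ValueError):
            RecordingSpec(n_channels=4, duration=0.0015, sampling_rate=1000.0)
        with pytest.raises(ValueError):
            small_spec(coupling_strength={"alpha": -0.1})
        with pytest.raises(ValueError):
            small_spec(noise_color="blue")

    def test_mean_alpha_pli_monotone_in_coupling(self):
        # estimator-level monotonicity over a kappa grid, averaged over seeds
        means = []
        for kappa in (0.05, 0.2, 0.5, 1.0):
            vals = []
            for seed in range(8):
                spec = small_spec(
                    coupling_strength={"alpha": kappa}, noise_color="white"
                )
                rec = generate_recording(spec, seed)
                cm = connectivity_matrix(segment_epochs(rec, 3.0), ALPHA)
                vals.append(global_pli(cm))
            means.append(np.mean(vals))
        assert all(a <= b + 1e-9 for a, b in zip(means, means[1:]))


class TestGroundTruth:
    @pytest.mark.parametrize("gamma,theta", [
        (0.3, 1.0), (0.6, 0.4), (0.85, np.pi / 2), (0.5, -1.2), (0.4, 0.0),
    ])
    def test_pli_infinity_matches_gaussian_simulation(self, gamma, theta, rng):
        n = 200_000
        u = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        v = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        z2 = gamma * np.exp(-1j * theta) * u + np.sqrt(1 - gamma**2) * v
        psi = np.angle(u * np.conj(z2))
        mc = abs(np.mean(np.sign(psi)))
        se = 3.0 / np.sqrt(n)
        assert abs(pli_infinity(gamma, theta)[0] - mc) < 4 * se + 1e-3

    def test_density_normalises_to_one(self):
        psi = np.linspace(-np.pi, np.pi, 20001)
        for gamma, theta in [(0.0, 0.0), (0.5, 1.0), (0.9, -0.5)]:
            mass = np.trapezoid(phase_difference_density(psi, gamma, theta), psi)
            assert abs(mass - 1.0) < 1e-6

    def test_pli_infinity_monotone_in_coherence(self):
        gammas = np.linspace(0, 0.95, 20)
        vals = pli_infinity(gammas, np.full(20, 1.0))
        assert np.all(np.diff(vals) > 0)
        # zero-lag coupling of any strength yields zero
        np.testing.assert_allclose(pli_infinity(gammas, np.zeros(20)), 0, atol=1e-9)

    def test_truth_matches_empirical_coherence(self):
        spec = small_spec(
            duration=120.0,
            channel_phase_lags=np.array([0.0, 0.6, -0.4, 1.1]),
        )
        gamma_t, theta_t = GroundTruth(spec).pair_coherence()
        from scipy import signal

        nyq = spec.sampling_rate / 2
        sos = signal.butter(4, [8 / nyq, 13 / nyq], btype="bandpass", output="sos")
        iu, ju = np.triu_indices(4, k=1)
        cohs = []
        for seed in range(6):
            rec = generate_recording(spec, seed)
            z = signal.hilbert(signal.sosfiltfilt(sos, rec.data, axis=-1),
                               axis=-1)[:, 1000:-1000]
            cross = (z[iu] * np.conj(z[ju])).mean(axis=-1)
            auto = (np.abs(z) ** 2).mean(axis=-1)
            cohs.append(cross / np.sqrt(auto[iu] * auto[ju]))
        coh = np.mean(cohs, axis=0)
        np.testing.assert_allclose(np.abs(coh), gamma_t, atol=0.04)
        np.testing.assert_allclose(np.angle(coh), theta_t, atol=0.06)

    def test_scaled_ground_truth_agrees_with_direct_computation(self):
        spec = small_spec()
        gt = GroundTruth(spec)
        for kappa in (0.1, 0.32, 0.7):
            coupling = dict(spec.coupling_strength)
            coupling["alpha"] = kappa
            direct = true_global_pli(
                RecordingSpec(
                    n_channels=4, sampling_rate=250.0, duration=30.0,
                    coupling_strength=coupling,
                    channel_phase_lags=spec.channel_phase_lags.copy(),
                )
            )
            assert abs(gt.global_pli(kappa) - direct) < 1e-9


class TestCohort:
    def test_table_shape_and_groups(self):
        cs = CohortSpec(n_per_group=30, recording=reduced_recording_spec(), seed=1)
        table, recs = generate_cohort(cs, include_recordings=False)
        assert len(table) == 60
        assert (table.group == "MCI").sum() == 30
        assert (table.group == "NC").sum() == 30
        assert recs == {}
        assert table.subject_id.is_unique
        assert table.moca.between(0, 30).all()
        assert (table.t2dm_duration_years > 0).all()

    def test_cohort_fully_reproducible(self):
        cs = CohortSpec(n_per_group=3, recording=small_spec(), seed=9)
        t1, r1 = generate_cohort(cs)
        t2, r2 = generate_cohort(cs)
        assert t1.equals(t2)
        for sid in r1:
            np.testing.assert_array_equal(r1[sid].data, r2[sid].data)

    def test_patient_group_truth_lower_under_effect(self):
        cs = CohortSpec(n_per_group=30, group_effect=0.7,
                        recording=reduced_recording_spec(), seed=2)
        table, _ = generate_cohort(cs, include_recordings=False)
        mci = table[table.group == "MCI"].true_global_alpha_pli
        nc = table[table.group == "NC"].true_global_alpha_pli
        assert mci.mean() < nc.mean()

    def test_exchangeable_groups_without_effect(self):
        # group_effect = 1 with identical MoCA models: expected group
        # difference in ground-truth PLI is zero
        from plimci.synth import NC_MOCA

        diffs = []
        for seed in range(25):
            cs = CohortSpec(
                n_per_group=20, group_effect=1.0,
                recording=reduced_recording_spec(),
                moca_models={"MCI": NC_MOCA, "NC": NC_MOCA}, seed=seed,
            )
            table, _ = generate_cohort(cs, include_recordings=False)
            mci = table[table.group == "MCI"].true_global_alpha_pli
            nc = table[table.group == "NC"].true_global_alpha_pli
            diffs.append(mci.mean() - nc.mean())
        t = np.mean(diffs) / (np.std(diffs, ddof=1) / np.sqrt(len(diffs)))
        assert abs(t) < 3.5

    def test_subject_seeds_are_independent_streams(self):
        a = np.random.default_rng(subject_seed(0, 0)).random(5)
        b = np.random.default_rng(subject_seed(0, 1)).random(5)
        assert not np.allclose(a, b)
        again = np.random.default_rng(subject_seed(0, 0)).random(5)
        np.testing.assert_array_equal(a, again)

    def test_invalid_cohort_specs(self):
        with pytest.raises(ValueError):
            CohortSpec(n_per_group=1)
        with pytest.raises(ValueError):
            CohortSpec(group_effect=0.0)
        with pytest.raises(ValueError):
            MocaModel(20.0, 10.0, 0.0)


def test_default_phase_lags_are_distinct_and_bounded():
    lags = default_phase_lags(62)
    assert len(np.unique(np.round(lags, 12))) == 62
    assert np.all(np.abs(lags) <= np.pi / 4 + 1e-12)


def test_moca_model_implied_r_closed_form():
    m = MocaModel(intercept=17.0, slope=20.0, residual_sd=2.0)
    sd = 0.05
    expected = 20.0 * sd / np.hypot(20.0 * sd, 2.0)
    assert np.isclose(m.implied_r(sd), expected)
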