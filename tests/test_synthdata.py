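"""Generator contracts: Markov hypnograms, spectral shaping, cohort bookkeeping."""

import numpy as np
import pytest

from sleepprint.preprocess import reject_artifacts
from sleepprint.recording import STAGES
from sleepprint.spectra import feature_matrix
from sleepprint.synthdata import (
    ArtifactSpec,
    CohortSpec,
    ConfigurationError,
    FingerprintPrior,
    GroupDynamics,
    SubjectFingerprint,
    default_group_dynamics,
    generate_cohort,
    generate_epoch_signal,
    generate_hypnogram,
)


def count_transitions(hyp):
    """Independent counting oracle for transition-probability estimates."""
    idx = {s: i for i, s in enumerate(STAGES)}
    counts = np.zeros((5, 5))
    for a, b in zip(hyp[:-1], hyp[1:]):
        counts[idx[a], idx[b]] += 1
    with np.errstate(invalid="ignore"):
        return counts / counts.sum(axis=1, keepdims=True)


class TestHypnogram:
    def test_absorbing_chain_stays_in_state(self, rng):
        dyn = GroupDynamics(np.eye(5), np.array([0, 0, 1.0, 0, 0]))
        hyp = generate_hypnogram(dyn, 960, rng)
        assert hyp == ["N2"] * 960

    def test_deterministic_two_cycle(self, rng):
        t = np.eye(5)
        t[0, 0], t[0, 1] = 0.0, 1.0  # W -> N1
        t[1, 1], t[1, 0] = 0.0, 1.0  # N1 -> W
        dyn = GroupDynamics(t, np.array([1.0, 0, 0, 0, 0]))
        assert generate_hypnogram(dyn, 4, rng) == ["W", "N1", "W", "N1"]

    def test_long_chain_recovers_planted_matrix(self, rng):
        t = np.full((5, 5), 0.025)
        np.fill_diagonal(t, 0.9)
        dyn = GroupDynamics(t, np.full(5, 0.2))
        hyp = generate_hypnogram(dyn, 10_000, rng)
        est = count_transitions(hyp)
        assert np.nanmax(np.abs(est - t)) <= 0.02

    def test_default_dynamics_rows_converge_within_sampling_error(self, rng):
        # max-abs row error <= 3*sqrt(p(1-p)/n) for rows with >= 200 visits
        dyn = default_group_dynamics()["GSC"]
        hyp = generate_hypnogram(dyn, 50_000, rng)
        est = count_transitions(hyp)
        idx = {s: i for i, s in enumerate(STAGES)}
        visits = np.array([hyp[:-1].count(s) for s in STAGES])
        for i in range(5):
            if visits[i] < 200:
                continue
            p = dyn.transition[i]
            bound = 3 * np.sqrt(np.maximum(p * (1 - p), 1e-12) / visits[i])
            assert np.all(np.abs(est[i] - p) <= np.maximum(bound, 3 / visits[i]))

    def test_non_stochastic_row_rejected(self, rng):
        t = np.eye(5)
        t[2, 2] = 0.5
        with pytest.raises(ConfigurationError):
            generate_hypnogram(GroupDynamics(t, np.full(5, 0.2)), 10, rng)


class TestEpochSignal:
    def test_pure_power_law_slope_recovered(self):
        from sleepprint.spectra import welch_psd

        fp = SubjectFingerprint(offset=2.0, knee=0.0, exponent=1.0)
        psds = []
        for i in range(30):
            x = generate_epoch_signal(fp, "R", 0, 30.0, 200.0,
                                      np.random.default_rng(i))
            f, psd = welch_psd(x, 200.0)
            psds.append(psd)
        mean_psd = np.mean(psds, axis=0)
        sel = (f >= 1.0) & (f <= 45.0)
        slope = np.polyfit(-np.log10(f[sel]), np.log10(mean_psd[sel]), 1)[0]
        assert abs(slope - 1.0) <= 0.15

    def test_no_peaks_means_flat_flattened_spectrum(self):
        from sleepprint.spectra import welch_psd

        fp = SubjectFingerprint(offset=1.5, knee=5.0, exponent=2.0,
                                peaks=[(10.0, 0.0, 1.0)])
        psds = []
        for i in range(40):
            x = generate_epoch_signal(fp, "R", 0, 30.0, 200.0,
                                      np.random.default_rng(50 + i))
            f, psd = welch_psd(x, 200.0)
            psds.append(psd)
        logp = np.log10(np.mean(psds, axis=0)[1:])
        f = f[1:]
        target = fp.log10_psd(f)
        sel = (f >= 2.0) & (f <= 45.0)
        assert np.mean(np.abs(logp[sel] - target[sel])) < 0.05

    def test_same_seed_bit_identical(self):
        fp = SubjectFingerprint(offset=1.0, knee=1.0, exponent=1.5)
        a = generate_epoch_signal(fp, "N2", 0, 30.0, 200.0,
                                  np.random.default_rng(7))
        b = generate_epoch_signal(fp, "N2", 0, 30.0, 200.0,
                                  np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_invalid_exponent_rejected(self, rng):
        fp = SubjectFingerprint(offset=1.0, knee=0.0, exponent=-1.0)
        with pytest.raises(ConfigurationError):
            generate_epoch_signal(fp, "R", 0, 30.0, 200.0, rng)


class TestCohort:
    def test_bookkeeping(self, small_cohort):
        # 3 groups x 2 subjects x 2 nights, one trait fingerprint per subject
        assert len(small_cohort.recordings) == 12
        assert len(small_cohort.fingerprints) == 6
        meta = small_cohort.metadata
        assert set(meta["group"]) == {"GSC", "MI", "MSI"}
        from sleepprint.synthdata import ISI_INTERVALS

        for _, row in meta.iterrows():
            lo, hi = ISI_INTERVALS[row["group"]]
            assert lo <= row["isi_score"] <= hi

    def test_fixed_seed_bit_identical_cohorts(self):
        spec = CohortSpec(n_subjects_per_group=1, n_nights=1,
                          epochs_per_night=4, n_channels=3, seed=99)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        for ra, rb in zip(a.recordings, b.recordings):
            assert np.array_equal(ra.data, rb.data)
            assert ra.hypnogram == rb.hypnogram

    def test_zero_artifact_probability_rejects_almost_nothing(self, small_cohort):
        flags = [
            reject_artifacts(r).rejected for r in small_cohort.recordings
        ]
        rejected = np.concatenate(flags)
        assert rejected.mean() < 0.01

    def test_two_nights_of_subject_are_nearest_in_feature_space(self):
        # when trait variance clearly dominates night drift (here ~60x),
        # every subject-night's closest other night-mean belongs to the
        # same subject (diagonal dominance consumed by the similarity
        # analysis)
        prior = FingerprintPrior(night_drift_offset_sd=0.02,
                                 night_drift_exponent_sd=0.01)
        spec = CohortSpec(n_subjects_per_group=2, n_nights=2,
                          epochs_per_night=150, n_channels=6, seed=11)
        cohort = generate_cohort(spec, prior, artifacts=None)
        from sleepprint.spectra import build_feature_table

        small_table = build_feature_table(cohort.recordings)
        nrem = small_table[small_table["stage"] == "NREM"]
        means = {}
        for (subj, night), sub in nrem.groupby(["subject", "night"]):
            X, _ = feature_matrix(sub)
            means[(subj, night)] = X.mean(axis=0)
        keys = list(means)
        for key in keys:
            others = [k for k in keys if k != key]
            dists = [np.linalg.norm(means[key] - means[k]) for k in others]
            nearest = others[int(np.argmin(dists))]
            assert nearest[0] == key[0]

    def test_artifact_spec_validation(self):
        with pytest.raises(ConfigurationError):
            ArtifactSpec(epoch_probability=1.5).validate()
        with pytest.raises(ConfigurationError):
            ArtifactSpec(transient_amplitude_uv=-1.0).validate()


class TestFingerprintPrior:
    def test_draw_respects_invariants(self, rng):
        prior = FingerprintPrior()
        for _ in range(20):
            fp = prior.draw(8, rng)
            fp.validate()
            assert fp.exponent > 0
            assert all(0.5 <= c <= 100 for c, _, _ in fp.peaks)

    def test_zero_variance_prior_collapses_identity_information(self, rng):
        # all subjects share one spectrum: classifying *subject identity*
        # from pooled epochs falls to chance
        prior = FingerprintPrior(
            offset_sd=0.0, knee_sd=0.0, exponent_sd=0.0,
            peak_templates=((10.0, 0.0, 0.3, 0.0, 1.2, 0.0),),
            channel_gain_log10_sd=0.0, night_drift_offset_sd=0.0,
            night_drift_exponent_sd=0.0,
        )
        spec = CohortSpec(n_subjects_per_group=2, n_nights=1,
                          epochs_per_night=60, n_channels=6, seed=21)
        cohort = generate_cohort(spec, prior, artifacts=None)
        from sleepprint.spectra import build_feature_table

        table = build_feature_table(cohort.recordings)
        from sleepprint.classify import ClassifierConfig, SplitRegime, run_regime

        regime = SplitRegime("intra_individual", repetitions=4, stage="NREM")
        report, _ = run_regime(
            table, regime,
            ClassifierConfig(n_estimators=50, max_depth=4), label="subject",
            seed=5,
        )
        acc = report.metrics["accuracy"][0] / 100.0
        chance = 1.0 / table["subject"].nunique()
        n_test = regime.repetitions * 0.2 * (table["stage"] == "NREM").sum()
        # three binomial standard errors above chance on the pooled test size
        assert acc < chance + 3 * np.sqrt(chance * (1 - chance) / n_test)
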