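"""Generator contracts: hypnograms, recordings, beats, cohorts and the
Spearman-calibrated copula."""

import numpy as np
import pytest
from scipy import stats

from psgstats.behavior import minute_hr
from psgstats.preprocess import segment
from psgstats.spectra import band_power, detect_cycles, spectrum
from psgstats.synth import (CohortConfig, PlantedAssociation, generate_beats,
                            generate_cohort, generate_hypnogram,
                            generate_recording, gaussian_r_for_spearman,
                            gaussian_r_for_spearman_poisson,
                            spearman_of_gaussian_poisson, synthetic_cap)


class TestHypnogram:
    def test_stage_proportions_within_tolerance(self):
        hyp = generate_hypnogram(480, {"N2": 0.56, "N3": 0.14, "REM": 0.21},
                                 90, seed=1)
        frac = {s: np.mean(hyp.stages == s) for s in ("N2", "N3", "REM")}
        assert abs(frac["N2"] - 0.56) <= 0.05
        assert abs(frac["N3"] - 0.14) <= 0.05
        assert abs(frac["REM"] - 0.21) <= 0.05

    def test_deterministic(self):
        h1 = generate_hypnogram(480, seed=1)
        h2 = generate_hypnogram(480, seed=1)
        assert (h1.stages == h2.stages).all()
        assert (h1.artifact == h2.artifact).all()

    def test_n3_declines_across_cycles(self):
        hyp = generate_hypnogram(480, seed=1)
        cycles = detect_cycles(hyp)
        assert len(cycles) >= 3
        def n3(c):
            return sum(hyp.stages[e] == "N3"
                       for e in range(c.nrem_start, c.nrem_end))
        assert n3(cycles[0]) > n3(cycles[-1])

    def test_cyclic_alternation(self):
        hyp = generate_hypnogram(450, cycle_len_min=90, seed=2)
        assert len(detect_cycles(hyp)) == 5

    def test_invalid_duration(self):
        with pytest.raises(ValueError):
            generate_hypnogram(0)

    def test_invalid_proportions(self):
        with pytest.raises(ValueError):
            generate_hypnogram(400, {"N2": 0.9, "REM": 0.3})


class TestRecording:
    def test_theta_gain_monotone_on_every_eeg_channel(self, cap8,
                                                      short_night):
        rec1, _ = generate_recording(short_night, cap8, seed=9,
                                     theta_gain=1.0, spindle_rate=0.0)
        rec2, _ = generate_recording(short_night, cap8, seed=9,
                                     theta_gain=2.0, spindle_rate=0.0)
        eeg = [i for i, t in enumerate(rec1.types) if t == "EEG"]
        t1 = band_power(spectrum(segment(rec1, short_night, {"REM"})),
                        (4.25, 8.0))[eeg]
        t2 = band_power(spectrum(segment(rec2, short_night, {"REM"})),
                        (4.25, 8.0))[eeg]
        assert np.all(t2 > t1)

    def test_zero_rate_no_events(self, cap8, short_night):
        _, events = generate_recording(short_night, cap8, seed=1,
                                       spindle_rate=0.0)
        assert events == []

    def test_spindle_band_power_n2_exceeds_rem(self, small_recording,
                                               short_night):
        rec, _ = small_recording
        eeg = [i for i, t in enumerate(rec.types) if t == "EEG"]
        n2 = band_power(spectrum(segment(rec, short_night, {"N2", "N3"})),
                        (12.0, 16.0))[eeg]
        rem = band_power(spectrum(segment(rec, short_night, {"REM"})),
                         (12.0, 16.0))[eeg]
        assert np.all(n2 > rem)

    def test_injected_events_only_in_clean_n23(self, cap8):
        hyp = generate_hypnogram(60, cycle_len_min=30, seed=8,
                                 artifact_frac=0.15)
        rec, events = generate_recording(hyp, cap8, seed=8, spindle_rate=2.0)
        mask = hyp.sample_mask({"N2", "N3"}, rec.fs, rec.n_samples)
        assert events
        for e in events:
            lo = int(round(e.onset_s * rec.fs))
            hi = int(round(e.offset_s * rec.fs))
            assert mask[lo:hi].all()
            assert 0.5 <= e.duration_s <= 2.0

    def test_deterministic(self, cap8, short_night):
        r1, e1 = generate_recording(short_night, cap8, seed=3)
        r2, e2 = generate_recording(short_night, cap8, seed=3)
        np.testing.assert_array_equal(r1.data, r2.data)
        assert [(e.channel, e.onset_s) for e in e1] == \
            [(e.channel, e.onset_s) for e in e2]

    def test_length_matches_hypnogram(self, cap8, short_night):
        rec, _ = generate_recording(short_night, cap8, seed=0)
        assert rec.n_samples == int(short_night.duration_s * rec.fs)


class TestBeats:
    def test_neutral_flat_profile(self):
        hr = minute_hr(generate_beats("neutral", 12, 70, 15, seed=2), 12)
        assert np.all(np.abs(hr - 70.0) <= 2.0)

    def test_trauma_window_elevated(self):
        hr = minute_hr(generate_beats("trauma", 12, 70, 15, seed=2), 12)
        assert np.nanmean(hr[6:9]) > np.nanmean(hr[:6]) + 10

    def test_zero_reactivity_indistinguishable(self):
        ok = 0
        n_rep = 100
        for seed in range(n_rep):
            a = minute_hr(generate_beats("trauma", 12, 70, 0.0,
                                         seed=2 * seed), 12)
            b = minute_hr(generate_beats("neutral", 12, 70, 0.0,
                                         seed=2 * seed + 1), 12)
            p = stats.ttest_rel(a, b).pvalue
            ok += p > 0.05
        assert ok / n_rep >= 0.90

    def test_invalid_bpm(self):
        with pytest.raises(ValueError):
            generate_beats("neutral", base_bpm=0.0)


class TestCopulaCalibration:
    def test_continuous_map_is_standard_formula(self):
        assert gaussian_r_for_spearman(0.5) == pytest.approx(
            2 * np.sin(np.pi * 0.5 / 6))

    def test_poisson_map_roundtrip(self):
        for target in (-0.6, 0.3):
            r = gaussian_r_for_spearman_poisson(target, 2.24)
            assert spearman_of_gaussian_poisson(r, 2.24) == pytest.approx(
                target, abs=1e-4)
            assert abs(r) > abs(target)   # ties attenuate; r compensates

    def test_infeasible_target(self):
        with pytest.raises(ValueError):
            gaussian_r_for_spearman_poisson(0.999, 0.3)


class TestCohort:
    def _cfg(self, n, rho, channels=None, nch=8):
        assoc = (PlantedAssociation("a", "rem_theta", "intrusions", rho,
                                    channels),) if rho is not None else ()
        return CohortConfig(n_subjects=n, n_channels=nch,
                            target_assoc=assoc)

    def test_planted_negative_association(self):
        co = generate_cohort(config=self._cfg(200, -0.6), seed=5)
        L = np.array([co.truth.latents["rem_theta"][s] for s in co.subjects])
        y = co.outcome_vector("intrusions")
        rho = stats.spearmanr(L, y).statistic
        assert -0.70 <= rho <= -0.50

    def test_null_association(self):
        co = generate_cohort(config=self._cfg(200, None), seed=6)
        L = np.array([co.truth.latents["rem_theta"][s] for s in co.subjects])
        y = co.outcome_vector("intrusions")
        assert abs(stats.spearmanr(L, y).statistic) <= 0.15

    def test_copula_targeting_unbiased_over_cohorts(self):
        # long-run mean of the sample Spearman stays within 0.03 of target
        vals = []
        for seed in range(100):
            co = generate_cohort(config=self._cfg(200, -0.6), seed=seed)
            L = np.array([co.truth.latents["rem_theta"][s]
                          for s in co.subjects])
            vals.append(stats.spearmanr(L,
                                        co.outcome_vector("intrusions"))
                        .statistic)
        assert abs(np.mean(vals) - (-0.6)) <= 0.03

    def test_byte_identical_diaries_under_same_seed(self):
        c1 = generate_cohort(config=self._cfg(12, -0.5), seed=9)
        c2 = generate_cohort(config=self._cfg(12, -0.5), seed=9)
        assert c1.diary.to_csv(index=False) == c2.diary.to_csv(index=False)
        assert c1.affect.to_csv(index=False) == c2.affect.to_csv(index=False)

    def test_minimum_subjects(self):
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=4)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            PlantedAssociation("a", "rem_theta", "intrusions", -1.0)

    def test_jointly_infeasible_targets(self):
        assoc = (PlantedAssociation("a", "rem_theta", "intrusions", -0.9),
                 PlantedAssociation("b", "spindle_count", "intrusions", -0.9))
        with pytest.raises(ValueError, match="infeasible"):
            generate_cohort(config=CohortConfig(n_subjects=10, n_channels=8,
                                                target_assoc=assoc), seed=0)

    def test_hr_outcome_reflects_reactivity(self):
        co = generate_cohort(config=self._cfg(30, None), seed=3)
        d = co.outcome_vector("hr")
        react = np.array([co.truth.hr_reactivity[s] for s in co.subjects])
        assert np.corrcoef(d, react)[0, 1] > 0.9

    def test_eeg_mode_maps_match_truth_ordering(self):
        cfg = CohortConfig(n_subjects=5, n_channels=6, signal_mode="eeg",
                           total_sleep_min=45, cycle_len_min=22.5,
                           theta_gain_sigma=0.5, target_assoc=())
        co = generate_cohort(config=cfg, seed=2)
        from psgstats.pipeline import StudyConfig, cohort_maps
        maps = cohort_maps(co, StudyConfig(n_perm=50))
        change = (maps["rem_theta"]["trauma"]
                  - maps["rem_theta"]["neutral"]).mean(axis=1)
        L = np.array([co.truth.latents["rem_theta"][s] for s in co.subjects])
        assert stats.spearmanr(change, L).statistic == pytest.approx(1.0)
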