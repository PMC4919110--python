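"""Imaging pipeline: hand examples, brute-force oracles, invariances."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from obnorm import imaging, profiles, synth
from obnorm.io import summaries_to_frame

from conftest import make_dff, make_trial


def brute_force_calls(dff, threshold_multiplier, min_frames=3, window_s=10.0):
    """Frame-enumeration oracle for detect_responses (slow, obvious)."""
    out = []
    frame_dt = 1.0 / dff.frame_rate_hz
    for c in range(dff.n_cells):
        above_frames = []
        for j in range(dff.n_frames):
            t = j * frame_dt
            in_window = dff.odor_onset_s <= t < dff.odor_onset_s + window_s
            if in_window and dff.dff[c, j] > threshold_multiplier * dff.baseline_sd[c]:
                above_frames.append(j)
        responsive = len(above_frames) >= min_frames
        out.append(responsive)
    return out


class TestRegistration:
    def _image(self, rng):
        return rng.random((64, 64))

    def test_identical_frames_zero_shift(self, rng):
        img = self._image(rng)
        dy, dx = imaging.register_translation(img, img, upsample=1)
        assert (dy, dx) == (0.0, 0.0)

    def test_integer_shift_recovered(self, rng):
        img = self._image(rng)
        moved = np.roll(img, (3, -2), axis=(0, 1))
        dy, dx = imaging.register_translation(img, moved, upsample=1)
        assert (dy, dx) == pytest.approx((3.0, -2.0))

    def test_subpixel_shift_recovered_to_tenth_pixel(self, rng):
        # half-pixel shift applied in the Fourier domain (periodic boundary)
        img = self._image(rng)
        ky = np.fft.fftfreq(64)[:, None]
        moved = np.real(np.fft.ifft2(np.fft.fft2(img)
                                     * np.exp(-2j * np.pi * ky * 0.5)))
        dy, dx = imaging.register_translation(img, moved, upsample=10)
        assert dy == pytest.approx(0.5, abs=0.1)
        assert dx == pytest.approx(0.0, abs=0.1)

    def test_all_zero_image_rejected(self):
        with pytest.raises(ValueError):
            imaging.register_translation(np.zeros((8, 8)), np.zeros((8, 8)))


class TestComputeDff:
    def test_constant_trace(self):
        trial = make_trial(np.full((2, 90), 100.0))
        dff = imaging.compute_dff(trial)
        np.testing.assert_allclose(dff.dff, 0.0)
        np.testing.assert_allclose(dff.baseline_sd, 0.0)
        np.testing.assert_allclose(dff.f0, 100.0)

    def test_hand_computed_f0_and_dff(self):
        # F0 window [2, 6) s at 1 Hz = frames 2..5
        values = np.full((1, 40), 110.0)
        values[0, 2:6] = [90.0, 100.0, 120.0, 130.0]   # median 110
        values[0, 25] = 165.0
        trial = make_trial(values, frame_rate_hz=1.0, odor_onset_s=20.0)
        dff = imaging.compute_dff(trial)
        assert dff.f0[0] == pytest.approx(110.0)
        assert dff.dff[0, 25] == pytest.approx(0.5)

    def test_scale_invariance(self, rng):
        # dF/F is unchanged by F -> cF
        values = 100.0 + 10.0 * rng.random((3, 90))
        a = imaging.compute_dff(make_trial(values))
        b = imaging.compute_dff(make_trial(3.7 * values))
        np.testing.assert_allclose(a.dff, b.dff, atol=1e-12)
        np.testing.assert_allclose(a.baseline_sd, b.baseline_sd, atol=1e-12)

    def test_generator_baseline_sd_matches_noise(self):
        prof = replace(profiles.CTRL_MC_LOW, n_sites=1, n_odors=2,
                       cells_per_site=30)
        ds = synth.generate_imaging_site(prof, 5)
        sds = np.concatenate([imaging.compute_dff(t).baseline_sd
                              for t in ds.trials])
        assert np.mean(sds) == pytest.approx(prof.noise_sd, rel=0.05)

    def test_too_short_preodor_rejected(self):
        with pytest.raises(ValueError):
            imaging.compute_dff(make_trial(np.full((1, 40), 50.0),
                                           odor_onset_s=4.0))

    def test_nonpositive_f0_rejected(self):
        with pytest.raises(ValueError, match="degenerate baseline"):
            imaging.compute_dff(make_trial(np.full((1, 90), -5.0)))


class TestDetectResponses:
    def test_all_zero_dff_no_calls(self):
        dff = make_dff(np.zeros((4, 90)), baseline_sd=0.03)
        calls = imaging.detect_responses(dff, 3.2)
        assert not calls["responsive"].any()

    @pytest.mark.parametrize("n_frames_above,expected", [(3, True), (2, False)])
    def test_three_frame_boundary(self, n_frames_above, expected):
        dff_arr = np.zeros((1, 90))
        onset_frame = int(20.0 * 2.53) + 1
        dff_arr[0, onset_frame:onset_frame + n_frames_above] = 5 * 0.03
        dff = make_dff(dff_arr, baseline_sd=0.03)
        calls = imaging.detect_responses(dff, 3.2)
        assert bool(calls.loc[0, "responsive"]) is expected

    def test_consecutive_switch(self):
        # 3 scattered frames pass the default rule but not consecutive=True
        dff_arr = np.zeros((1, 90))
        f0 = int(20.0 * 2.53) + 1
        dff_arr[0, [f0, f0 + 4, f0 + 8]] = 0.2
        dff = make_dff(dff_arr, baseline_sd=0.03)
        assert bool(imaging.detect_responses(dff, 3.2).loc[0, "responsive"])
        assert not bool(imaging.detect_responses(
            dff, 3.2, consecutive=True).loc[0, "responsive"])

    def test_cell_class_default_thresholds(self):
        dff = make_dff(np.zeros((1, 90)), baseline_sd=0.03)
        assert imaging.detect_responses(dff)["threshold_multiplier"].iloc[0] == 3.2
        dff.cell_class = "pg"
        assert imaging.detect_responses(dff)["threshold_multiplier"].iloc[0] == 3.4

    def test_matches_brute_force_oracle_on_random_trials(self, rng):
        # 1000 random small cell-trials against the frame-enumeration oracle
        for _ in range(200):
            n_cells = int(rng.integers(1, 6))
            dff_arr = rng.normal(0, 0.03, (n_cells, 90))
            # sprinkle transients
            for c in range(n_cells):
                if rng.random() < 0.5:
                    start = int(rng.integers(45, 80))
                    dff_arr[c, start:start + int(rng.integers(1, 8))] += \
                        rng.uniform(0.05, 0.4)
            sd = rng.uniform(0.01, 0.05)
            mult = float(rng.choice([2.0, 3.2, 3.4, 3.8]))
            dff = make_dff(dff_arr, baseline_sd=sd)
            calls = imaging.detect_responses(dff, mult)
            assert calls["responsive"].tolist() == brute_force_calls(dff, mult)

    def test_duration_spans_first_to_last_crossing(self):
        dff_arr = np.zeros((1, 90))
        f0 = int(20.0 * 2.53) + 1
        dff_arr[0, [f0, f0 + 2, f0 + 6]] = 0.2
        dff = make_dff(dff_arr, baseline_sd=0.03)
        calls = imaging.detect_responses(dff, 3.2)
        assert calls.loc[0, "duration_s"] == pytest.approx(7 / 2.53)

    def test_nan_frames_excluded(self):
        dff_arr = np.zeros((2, 90))
        dff_arr[0, 60] = np.nan
        calls = imaging.detect_responses(make_dff(dff_arr, 0.03), 3.2)
        assert calls["cell"].tolist() == [1]


class TestCalibrateFpr:
    def test_zero_noise_gives_zero(self):
        dff = make_dff(np.zeros((50, 90)), baseline_sd=0.0)
        assert imaging.calibrate_fpr([dff], 3.2) == 0.0

    def test_matches_binomial_closed_form(self, rng):
        # iid Gaussian noise with known SD, 25-frame window: FPR is the
        # binomial tail P(X >= 3), X ~ Bin(25, P(Z > mult)).
        from scipy.stats import binom, norm
        n_cells, mult = 10000, 2.0
        noise = rng.normal(0, 0.03, (n_cells, 90))
        dff = make_dff(noise, baseline_sd=0.03)
        fpr = imaging.calibrate_fpr([dff], mult)
        t = np.arange(90) / 2.53
        n_win = int(((t >= 20.0) & (t < 30.0)).sum())
        p_frame = norm.sf(mult)
        expected = binom.sf(2, n_win, p_frame)
        se = np.sqrt(expected * (1 - expected) / n_cells)
        assert abs(fpr - expected) < 3 * se + 1e-4

    def test_monotone_in_threshold(self, rng):
        noise = rng.normal(0, 0.03, (4000, 90))
        dff = make_dff(noise, baseline_sd=0.03)
        fprs = [imaging.calibrate_fpr([dff], m) for m in (1.5, 2.0, 2.5, 3.2)]
        assert all(a >= b for a, b in zip(fprs, fprs[1:]))


class TestPopulationSummaries:
    def _calls(self, responsive_by_trial, n_cells=20):
        rows = []
        for trial, n_resp in enumerate(responsive_by_trial):
            for cell in range(n_cells):
                rows.append({"cell": cell, "odor": "odorA",
                             "concentration": 1e-4, "trial": trial,
                             "responsive": cell < n_resp, "peak_dff": np.nan,
                             "duration_s": np.nan, "threshold_multiplier": 3.2,
                             "site_id": "s0"})
        return pd.DataFrame(rows)

    def test_hand_example_2_2_4_4_of_20(self):
        summ = imaging.fraction_responsive(self._calls([2, 2, 4, 4]))
        assert summ[0].frac_responsive == pytest.approx(0.15)

    def test_all_responsive_gives_one(self):
        summ = imaging.fraction_responsive(self._calls([20, 20, 20, 20]))
        assert summ[0].frac_responsive == 1.0

    def test_permutation_invariance(self, rng):
        calls = self._calls([3, 5, 2, 7])
        shuffled = calls.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = imaging.fraction_responsive(calls)[0].frac_responsive
        b = imaging.fraction_responsive(shuffled)[0].frac_responsive
        # relabeling trials permutes terms of the same mean
        relabeled = calls.copy()
        relabeled["trial"] = relabeled["trial"].map({0: 2, 1: 3, 2: 0, 3: 1})
        c = imaging.fraction_responsive(relabeled)[0].frac_responsive
        assert a == b == c

    def test_reliable_responders_two_of_four_rule(self):
        calls = self._calls([2, 2, 0, 0])   # cells 0,1 respond twice
        rel = imaging.reliable_responders(calls)
        assert rel.loc[rel.cell == 0, "reliable"].item()
        assert rel.loc[rel.cell == 1, "reliable"].item()
        assert not rel.loc[rel.cell == 2, "reliable"].any()
        calls1 = self._calls([1, 0, 0, 0])  # one trial only: excluded
        rel1 = imaging.reliable_responders(calls1)
        assert not rel1["reliable"].any()

    def test_reliability_histogram_printed_counts(self):
        # counts {1: 28, 2: 10, 3: 5, 4: 7} -> (0.56, 0.20, 0.10, 0.14)
        rows = []
        cell = 0
        for k, n in ((1, 28), (2, 10), (3, 5), (4, 7)):
            for _ in range(n):
                for trial in range(4):
                    rows.append({"cell": cell, "odor": "o", "concentration": 1,
                                 "trial": trial, "responsive": trial < k,
                                 "site_id": "s0"})
                cell += 1
        hist = imaging.reliability_histogram(pd.DataFrame(rows))
        np.testing.assert_allclose(hist, [0.56, 0.20, 0.10, 0.14])

    def test_all_four_of_four(self):
        calls = self._calls([5, 5, 5, 5])
        hist = imaging.reliability_histogram(calls)
        np.testing.assert_allclose(hist, [0, 0, 0, 1.0])

    def test_tuning_distribution_no_responses(self):
        calls = self._calls([0, 0, 0, 0])
        tune = imaging.tuning_distribution(calls, n_odors=13)
        assert tune[0] == 1.0 and tune.sum() == pytest.approx(1.0)


class TestPatternCorrelations:
    def test_constant_dff_fills_matrix(self):
        dffs = [make_dff(np.full((3, 90), 0.2), 0.01, trial=t) for t in range(2)]
        mat, cols = imaging.response_pattern_matrix(dffs)
        np.testing.assert_allclose(mat, 0.2)
        assert cols == [("odorA", 0), ("odorA", 1)]

    def test_panel_shape(self):
        dffs = [make_dff(np.zeros((5, 90)), 0.01, odor=f"o{o}", trial=t)
                for o in range(13) for t in range(4)]
        mat, cols = imaging.response_pattern_matrix(dffs)
        assert mat.shape == (5, 52)

    def test_window_mean_matches_kernel_integral(self):
        # single exponential transient: window mean = integral / window
        fr, tau, peak = 2.53, 1.5, 0.8
        t = np.arange(90) / fr
        onset = 20.0
        trace = np.where(t >= onset, peak * np.exp(-(t - onset) / tau), 0.0)
        dffs = [make_dff(trace[None, :].repeat(2, 0), 0.01)]
        mat, _ = imaging.response_pattern_matrix(dffs, avg_window_s=4.0)
        win = (t >= onset) & (t < onset + 4.0)
        assert mat[0, 0] == pytest.approx(trace[win].mean())

    def test_duplicated_columns_correlate_perfectly(self, rng):
        col = rng.random(6)
        corr, within = imaging.cross_trial_correlations(
            np.column_stack([col, col]), [("o", 0), ("o", 1)])
        assert within["o"] == pytest.approx(1.0)

    def test_hand_example_anticorrelated_patterns(self):
        mat = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        corr, within = imaging.cross_trial_correlations(
            mat, [("o", 0), ("o", 1)])
        assert within["o"] == pytest.approx(-0.5)

    def test_matrix_is_symmetric_unit_diagonal_bounded(self, rng):
        mat = rng.random((10, 8))
        cols = [(f"o{i % 2}", i // 2) for i in range(8)]
        corr, _ = imaging.cross_trial_correlations(mat, cols)
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        assert np.nanmax(np.abs(corr)) <= 1.0 + 1e-12

    def test_zero_variance_column_flagged(self, rng):
        mat = np.column_stack([rng.random(5), np.full(5, 0.3)])
        corr, within = imaging.cross_trial_correlations(
            mat, [("o", 0), ("o", 1)])
        assert np.isnan(corr[0, 1])
        assert np.isnan(within["o"])


class TestConcentrationSeries:
    def _summaries(self, fracs_by_conc, odor="acetophenone", n_sites=4):
        from obnorm.datatypes import SiteSummary
        out = []
        for conc, frac in fracs_by_conc.items():
            for s in range(n_sites):
                out.append(SiteSummary(site_id=f"s{s}", genotype="x",
                                       odor=odor, concentration=conc,
                                       frac_responsive=frac, n_cells=30))
        return out

    def test_flat_series_zero_lc(self):
        summ = (self._summaries({1e-4: 0.2, 1e-3: 0.2, 1e-2: 0.2})
                + self._summaries({1e-4: 0.2, 1e-3: 0.2, 1e-2: 0.2},
                                  odor="ethyl_acetate"))
        res = imaging.concentration_series_analysis(summ, "acetophenone",
                                                    "ethyl_acetate")
        assert res.lc_test == pytest.approx(0.0, abs=1e-12)
        assert res.delta_lc == pytest.approx(0.0, abs=1e-12)

    def test_hand_ols_slope_per_decade(self):
        summ = self._summaries({1e-4: 0.1, 1e-3: 0.2, 1e-2: 0.3})
        res = imaging.concentration_series_analysis(summ, "acetophenone")
        assert res.lc_test == pytest.approx(0.1)
        assert res.pearson_r_test == pytest.approx(1.0)

    def test_single_concentration_rejected(self):
        with pytest.raises(ValueError, match="single"):
            imaging.concentration_series_analysis(
                self._summaries({1e-4: 0.1}), "acetophenone")

    def test_per_site_option_matches_pooled_for_balanced_design(self):
        summ = self._summaries({1e-4: 0.1, 1e-3: 0.25, 1e-2: 0.32})
        pooled = imaging.concentration_series_analysis(summ, "acetophenone")
        per_site = imaging.concentration_series_analysis(summ, "acetophenone",
                                                         per_site=True)
        assert per_site.lc_test == pytest.approx(pooled.lc_test)


class TestStringency:
    def test_stricter_threshold_never_increases_counts(self):
        prof = replace(profiles.CTRL_MC_LOW, n_sites=3, n_odors=3,
                       cells_per_site=25)
        for ds in synth.generate_imaging_sites(prof, 77):
            lax = imaging.detect_dataset(ds, threshold_multiplier=3.2)
            strict = imaging.detect_dataset(ds, threshold_multiplier=3.8)
            merged = lax.merge(strict, on=["cell", "odor", "trial"],
                               suffixes=("_32", "_38"))
            assert not (merged["responsive_38"]
                        & ~merged["responsive_32"]).any()
            assert strict["responsive"].sum() <= lax["responsive"].sum()
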