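"""Recompute the study's headline population statistics from scratch.

Each target function simulates the corresponding experiment at the study's
size with the named default profile, runs the full analysis pipeline on the
simulated raw data, and returns the recovered statistic.  Because a single
study-sized simulation has substantial sampling error (e.g. 10 imaging
sites with an across-site SD of 26 percentage points), every target is
averaged over replicate simulated studies; ``n`` reports the total problem
size actually used.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import behavior, ephys, imaging, profiles, synth

TARGET_IDS = ["t1", "t2", "t3", "t4", "t5", "t6", "t7", "t8", "t9", "t10", "t11"]


def _child_seeds(seed: int, label: str, n: int):
    """Deterministic per-target child seeds below 2**31."""
    root = np.random.SeedSequence([seed, abs(hash(label)) % (2**31)])
    return [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n)]


def _imaging_study(profile, seed):
    """One simulated multi-site study: calls, site fractions, pooled corr."""
    sites = synth.generate_imaging_sites(profile, seed)
    calls, fracs, per_site_dffs = [], [], []
    for ds in sites:
        c = imaging.detect_dataset(ds)
        calls.append(c)
        fracs.append(np.mean([s.frac_responsive
                              for s in imaging.fraction_responsive(c)]))
        per_site_dffs.append([imaging.compute_dff(t) for t in ds.trials])
    corr = imaging.pooled_within_odor_correlation(per_site_dffs)
    return pd.concat(calls, ignore_index=True), fracs, corr


def mitral_panel_statistics(profile, seed: int, n_reps: int):
    """Fraction responsive, pooled within-odor correlation, k-of-4 histogram."""
    fracs, cors, hists = [], [], []
    for s in _child_seeds(seed, profile.name, n_reps):
        calls, f, corr = _imaging_study(profile, s)
        fracs.extend(f)
        cors.append(corr)
        hists.append(imaging.reliability_histogram(calls))
    return (float(np.mean(fracs)), float(np.nanmean(cors)),
            np.mean(hists, axis=0), n_reps * profile.n_sites)


def sniff_novelty(seed: int, n_pairs: int = 27, n_reps: int = 40):
    """Mean 1st- and 2nd/3rd-presentation sniff responses over mouse-odor pairs."""
    r1, r23 = [], []
    for s in _child_seeds(seed, "sniff", n_reps):
        responses = []
        for i, s2 in enumerate(_child_seeds(s, "pair", n_pairs)):
            ses = synth.generate_sniff_session(profiles.CTRL_SNIFF, 3, s2,
                                               session_id=f"m{i:02d}")
            responses.extend(behavior.session_responses(ses))
        m1, m23, _t, _p, _n = behavior.adaptation_test(responses)
        r1.append(m1)
        r23.append(m23)
    return float(np.mean(r1)), float(np.mean(r23)), n_reps * n_pairs


def series_fraction(series, conc: float, seed: int, n_reps: int,
                    odor: str = "acetophenone"):
    """Across-site mean responsive fraction at one concentration."""
    vals = []
    n_sites = next(iter(series.values())).n_sites
    for s in _child_seeds(seed, f"series-{conc}", n_reps):
        for ds in synth.generate_concentration_study(series, s, odor_label=odor):
            calls = imaging.detect_dataset(ds)
            for summ in imaging.fraction_responsive(calls):
                if summ.concentration == conc:
                    vals.append(summ.frac_responsive)
    return float(np.mean(vals)), n_reps * n_sites


def series_concentration_correlation(seed: int, n_reps: int = 20):
    """Pearson r between site responsive fraction and log10 dilution."""
    rs = []
    n_sites = next(iter(profiles.M71_ACET.values())).n_sites
    for s in _child_seeds(seed, "series-r", n_reps):
        summaries = []
        for ds in synth.generate_concentration_study(profiles.M71_ACET, s,
                                                     odor_label="acetophenone"):
            summaries.extend(
                imaging.fraction_responsive(imaging.detect_dataset(ds)))
        res = imaging.concentration_series_analysis(summaries, "acetophenone")
        rs.append(res.pearson_r_test)
    return float(np.mean(rs)), n_reps * n_sites * 3


def awake_evoked_vm(seed: int, n_pairs: int = 27, n_reps: int = 25,
                    n_trials: int = 3):
    """Mean 1-s evoked Vm across simulated awake control cell-odor pairs."""
    vals = []
    for s in _child_seeds(seed, "ephys-ctrl", n_reps):
        for rec in synth.generate_ephys_panel(profiles.CTRL_MTC_AWAKE,
                                              n_pairs, n_trials, s):
            vals.append(ephys.analyze_awake_recording(rec).dvm_1s_mv)
    return float(np.mean(vals)), len(vals)


def run_targets(seed: int, scale: float = 1.0, progress=None) -> dict:
    """Compute every acceptance target; ``scale`` scales replicate counts."""
    warnings.filterwarnings("ignore")
    n = lambda k: max(2, int(round(k * scale)))
    out: dict[str, dict] = {}

    def _put(key, value, size):
        out[key] = {"value": float(value), "n": int(size)}
        if progress:
            progress(key, out[key])

    frac, corr, hist, n_sites = mitral_panel_statistics(
        profiles.CTRL_MC_LOW, seed, n_reps=n(40))
    _put("t1", 100.0 * frac, n_sites)
    _put("t2", corr, n_sites)
    _put("t4", 100.0 * hist[3], n_sites)

    frac_m, corr_m, hist_m, n_sites_m = mitral_panel_statistics(
        profiles.M71_MC_LOW, seed + 1, n_reps=n(40))
    _put("t3", corr_m, n_sites_m)
    _put("t5", 100.0 * hist_m[3], n_sites_m)

    r1, r23, n_pairs = sniff_novelty(seed + 2, n_reps=n(250))
    _put("t6", r1, n_pairs)
    _put("t7", r23, n_pairs)

    pg_mid, n_pg = series_fraction(profiles.M71_PG, 1e-3, seed + 3,
                                   n_reps=n(20))
    _put("t8", 100.0 * pg_mid, n_pg)

    top, n_acet = series_fraction(profiles.M71_ACET, 1e-2, seed + 4,
                                  n_reps=n(25))
    _put("t9", 100.0 * top, n_acet)

    r_conc, n_points = series_concentration_correlation(seed + 5, n_reps=n(20))
    _put("t10", r_conc, n_points)

    dvm, n_cells = awake_evoked_vm(seed + 6, n_reps=n(25))
    _put("t11", dvm, n_cells)

    return {k: out[k] for k in TARGET_IDS}
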