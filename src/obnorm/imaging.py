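"""Calcium-imaging pipeline: motion correction, dF/F, response calling,
population statistics and the concentration-series linear-change statistic.

The response criterion follows the study's rule: a cell is responsive on a
trial if its dF/F exceeds ``threshold_multiplier`` x its baseline SD on at
least ``min_frames`` frames (total, not necessarily consecutive) within the
10-s window after odor onset; 3.2 x SD is used for mitral cells and 3.4 x SD
for periglomerular cells.  All windows are half-open ``[start, end)``.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from skimage.registration import phase_cross_correlation

from .datatypes import (
    ConcentrationSeriesResult,
    DffTrial,
    ImagingDataset,
    SiteSummary,
    TrialFluorescence,
)
from . import stats as _stats

logger = logging.getLogger(__name__)

MITRAL_THRESHOLD = 3.2
PG_THRESHOLD = 3.4
STRINGENT_THRESHOLD = 3.8


def register_translation(reference_frame, moving_frame, upsample: int = 10):
    """Subpixel (dy, dx) shift of ``moving_frame`` relative to the reference.

    Frequency-domain phase correlation refined to 1/upsample pixel.  The
    returned shift is the translation that was applied to the reference to
    produce the moving frame (apply its negation to re-align).
    """
    ref = np.asarray(reference_frame, dtype=float)
    mov = np.asarray(moving_frame, dtype=float)
    if ref.shape != mov.shape:
        raise ValueError("frames must have equal shapes")
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    if not ref.any() or not mov.any():
        raise ValueError("all-zero image: correlation peak undefined")
    shift, _error, _phase = phase_cross_correlation(
        ref, mov, upsample_factor=upsample, normalization=None)
    # phase_cross_correlation returns the shift that maps moving -> reference
    dy, dx = -shift[0], -shift[1]
    return float(dy), float(dx)


def compute_dff(trial: TrialFluorescence) -> DffTrial:
    """dF/F0 with F0 = per-cell median of seconds [2, 6) of the pre-odor period.

    The baseline SD (per cell) is the SD of dF/F over the entire pre-odor
    period; it defines the trial's response threshold.
    """
    if trial.odor_onset_s < 6.0:
        raise ValueError("pre-odor period must be at least 6 s for the F0 window")
    t = trial.frame_times()
    f0_win = (t >= 2.0) & (t < 6.0)
    if not f0_win.any():
        raise ValueError("no frames fall inside the F0 window [2, 6) s")
    f0 = np.median(trial.values[:, f0_win], axis=1)
    bad = f0 <= 0
    if bad.any():
        raise ValueError(
            f"degenerate baseline (F0 <= 0) for cells {np.flatnonzero(bad).tolist()}")
    dff = (trial.values - f0[:, None]) / f0[:, None]
    pre = t < trial.odor_onset_s
    baseline_sd = np.std(dff[:, pre], axis=1)
    return DffTrial(dff=dff, f0=f0, baseline_sd=baseline_sd,
                    frame_rate_hz=trial.frame_rate_hz,
                    odor_onset_s=trial.odor_onset_s,
                    odor_offset_s=trial.odor_offset_s,
                    odor_label=trial.odor_label,
                    concentration=trial.concentration,
                    trial_index=trial.trial_index,
                    site_id=trial.site_id,
                    cell_class=trial.cell_class)


def detect_responses(dff: DffTrial, threshold_multiplier: float | None = None,
                     min_frames: int = 3, window_s: float = 10.0,
                     consecutive: bool = False) -> pd.DataFrame:
    """Response calls for one trial: one row per cell.

    Columns: cell, odor, concentration, trial, responsive, peak_dff,
    duration_s, threshold_multiplier.  ``peak_dff``/``duration_s`` are NaN for
    non-responsive cells.  Duration runs from the first supra-threshold frame
    to the end of the last supra-threshold run inside the window.  Cells with
    NaN frames in the window are excluded (dropped with a logged warning).
    """
    if threshold_multiplier is None:
        threshold_multiplier = (PG_THRESHOLD if dff.cell_class == "pg"
                                else MITRAL_THRESHOLD)
    t = np.arange(dff.n_frames) / dff.frame_rate_hz
    win = (t >= dff.odor_onset_s) & (t < dff.odor_onset_s + window_s)
    if win.sum() < min_frames:
        raise ValueError("analysis window does not fit within the trial")
    x = dff.dff[:, win]
    thresh = threshold_multiplier * dff.baseline_sd
    if np.any((dff.baseline_sd == 0) & (np.abs(x).max(axis=1) > 0)):
        logger.warning("zero baseline SD with nonzero dF/F; threshold is 0 "
                       "for those cells")

    rows = []
    frame_dt = 1.0 / dff.frame_rate_hz
    for c in range(dff.n_cells):
        xi = x[c]
        if np.isnan(xi).any():
            logger.warning("cell %d trial %d: NaN frames, excluded",
                           c, dff.trial_index)
            continue
        above = xi > thresh[c]
        n_above = int(above.sum())
        if consecutive:
            best_run = 0
            run = 0
            for a in above:
                run = run + 1 if a else 0
                best_run = max(best_run, run)
            hit = best_run >= min_frames
        else:
            hit = n_above >= min_frames
        if hit:
            idx = np.flatnonzero(above)
            peak = float(xi.max())
            duration = float((idx[-1] - idx[0] + 1) * frame_dt)
        else:
            peak = np.nan
            duration = np.nan
        rows.append((c, dff.odor_label, dff.concentration, dff.trial_index,
                     bool(hit), peak, duration, threshold_multiplier,
                     dff.site_id))
    return pd.DataFrame(rows, columns=[
        "cell", "odor", "concentration", "trial", "responsive", "peak_dff",
        "duration_s", "threshold_multiplier", "site_id"])


def detect_dataset(dataset: ImagingDataset,
                   threshold_multiplier: float | None = None,
                   min_frames: int = 3, window_s: float = 10.0,
                   consecutive: bool = False) -> pd.DataFrame:
    """Run compute_dff + detect_responses over every trial of a dataset."""
    tables = [
        detect_responses(compute_dff(trial), threshold_multiplier,
                         min_frames=min_frames, window_s=window_s,
                         consecutive=consecutive)
        for trial in dataset.trials
    ]
    return pd.concat(tables, ignore_index=True)


def calibrate_fpr(noise_only_dff, threshold_multiplier: float,
                  min_frames: int = 3, window_s: float = 10.0) -> float:
    """Empirical false-positive rate on response-free dF/F trials."""
    total = 0
    positive = 0
    for dff in noise_only_dff:
        calls = detect_responses(dff, threshold_multiplier,
                                 min_frames=min_frames, window_s=window_s)
        total += len(calls)
        positive += int(calls["responsive"].sum())
    if total == 0:
        raise ValueError("no cell-trials supplied")
    return positive / total


def fraction_responsive(calls: pd.DataFrame,
                        group_cols=("site_id", "odor", "concentration"),
                        genotype: str = "") -> list[SiteSummary]:
    """Responsive fraction per group: mean over trials of (responsive / cells)."""
    summaries = []
    for key, grp in calls.groupby(list(group_cols), sort=True):
        per_trial = grp.groupby("trial")["responsive"].mean()
        if per_trial.empty:
            warnings.warn(f"empty group {key}: excluded")
            continue
        key = key if isinstance(key, tuple) else (key,)
        info = dict(zip(group_cols, key))
        summaries.append(SiteSummary(
            site_id=str(info.get("site_id", "")), genotype=genotype,
            odor=str(info.get("odor", "")),
            concentration=float(info.get("concentration", np.nan)),
            frac_responsive=float(per_trial.mean()),
            n_cells=int(grp["cell"].nunique())))
    return summaries


_PAIR_COLS = ["site_id", "cell", "odor", "concentration"]


def reliable_responders(calls: pd.DataFrame, min_trials: int = 2,
                        n_trials: int = 4) -> pd.DataFrame:
    """Cells responding on >= min_trials of n_trials trials, per (cell, odor).

    This is the inclusion rule for odor maps and tuning curves (2 of 4).
    Cell-odor pairs are keyed by site as well, so calls pooled across sites
    keep their identities separate.
    """
    counts = (calls.groupby(_PAIR_COLS)["responsive"]
              .agg(["sum", "count"]).reset_index())
    if (counts["count"] > n_trials).any():
        raise ValueError("more trials present than n_trials")
    counts["reliable"] = counts["sum"] >= min_trials
    return counts.rename(columns={"sum": "n_responsive"})[
        _PAIR_COLS + ["n_responsive", "reliable"]]


def reliability_histogram(calls: pd.DataFrame, n_trials: int = 4) -> np.ndarray:
    """P(k) over k = 1..n_trials among cells responding at least once.

    Cell-odor pairs are pooled (count-weighted) over everything present in
    ``calls`` — sites included — matching a pooled "percent of responsive
    cells" readout.
    """
    counts = calls.groupby(_PAIR_COLS)["responsive"].sum().to_numpy()
    counts = counts[counts >= 1]
    if counts.size == 0:
        warnings.warn("no responsive cell-odor pairs; empty histogram")
        return np.zeros(n_trials)
    hist = np.bincount(counts.astype(int), minlength=n_trials + 1)[1:n_trials + 1]
    return hist / hist.sum()


def tuning_distribution(calls: pd.DataFrame, n_odors: int = 13,
                        min_trials: int = 2, n_trials: int = 4) -> np.ndarray:
    """Fraction of cells whose reliable responses cover N odorants, N=0..n_odors.

    Cells are pooled across sites (keyed by site_id + cell).
    """
    rel = reliable_responders(calls, min_trials=min_trials, n_trials=n_trials)
    per_cell = rel.groupby(["site_id", "cell"])["reliable"].sum()
    all_cells = calls[["site_id", "cell"]].drop_duplicates()
    idx = pd.MultiIndex.from_frame(all_cells)
    breadth = per_cell.reindex(idx, fill_value=0).to_numpy().astype(int)
    hist = np.bincount(breadth, minlength=n_odors + 1)[:n_odors + 1]
    return hist / hist.sum()


def response_pattern_matrix(dff_trials, avg_window_s: float = 4.0):
    """Cells x (odor, trial) matrix of mean dF/F over the 4 s after onset.

    All cells enter the matrix (not only responsive ones).  Returns
    ``(matrix, columns)`` where columns is a list of (odor, trial) tuples.
    """
    mats = []
    columns = []
    n_cells = None
    for dff in dff_trials:
        if n_cells is None:
            n_cells = dff.n_cells
        elif dff.n_cells != n_cells:
            raise ValueError("all trials must share the cell population")
        t = np.arange(dff.n_frames) / dff.frame_rate_hz
        win = (t >= dff.odor_onset_s) & (t < dff.odor_onset_s + avg_window_s)
        mats.append(dff.dff[:, win].mean(axis=1))
        columns.append((dff.odor_label, dff.trial_index))
    if n_cells is not None and n_cells < 2:
        raise ValueError("need at least 2 cells")
    return np.column_stack(mats), columns


def cross_trial_correlations(matrix, columns):
    """Trial x trial Pearson correlation matrix of population patterns.

    Returns ``(corr, within_odor_means)``: the full symmetric matrix with a
    unit diagonal (NaN where a column has zero variance), and a dict mapping
    odor -> mean of its within-odor off-diagonal entries.
    """
    matrix = np.asarray(matrix, dtype=float)
    n_col = matrix.shape[1]
    sd = matrix.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(matrix, rowvar=False)
    corr = np.atleast_2d(corr)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn("zero-variance pattern column(s); entries set to NaN")
        corr[zero_var, :] = np.nan
        corr[:, zero_var] = np.nan
    np.fill_diagonal(corr, 1.0)

    odors = [c[0] for c in columns]
    within: dict[str, float] = {}
    for odor in dict.fromkeys(odors):
        idx = [i for i, o in enumerate(odors) if o == odor]
        vals = [corr[i, j] for a, i in enumerate(idx) for j in idx[a + 1:]]
        vals = [v for v in vals if not np.isnan(v)]
        within[odor] = float(np.mean(vals)) if vals else np.nan
    return corr, within


def within_odor_mean_correlation(dff_trials, avg_window_s: float = 4.0) -> float:
    """Mean over odors of the within-odor cross-trial pattern correlation."""
    matrix, columns = response_pattern_matrix(dff_trials, avg_window_s)
    _, within = cross_trial_correlations(matrix, columns)
    vals = [v for v in within.values() if not np.isnan(v)]
    return float(np.mean(vals))


def pooled_within_odor_correlation(dff_trials_per_site,
                                   avg_window_s: float = 4.0) -> float:
    """Within-odor correlation of the cell-pooled population pattern matrix.

    Cells from every site are combined into a single cells x (odor, trial)
    matrix (site trial k lines up with trial k elsewhere); the within-odor
    cross-trial correlations of that matrix are averaged over odors.  This is
    the pooled-population readout used for trial-to-trial similarity.
    """
    blocks = []
    columns0 = None
    for dffs in dff_trials_per_site:
        matrix, columns = response_pattern_matrix(dffs, avg_window_s)
        if columns0 is None:
            columns0 = columns
        else:
            if columns != columns0:
                order = {c: i for i, c in enumerate(columns)}
                matrix = matrix[:, [order[c] for c in columns0]]
        blocks.append(matrix)
    pooled = np.vstack(blocks)
    _, within = cross_trial_correlations(pooled, columns0)
    vals = [v for v in within.values() if not np.isnan(v)]
    return float(np.mean(vals))


def concentration_series_analysis(summaries, test_stimulus: str,
                                  reference_stimulus: str | None = None,
                                  log_x: bool = True,
                                  per_site: bool = False
                                  ) -> ConcentrationSeriesResult:
    """Linear change (LC) of responsive fraction with stimulus intensity.

    LC is the OLS slope of fraction responsive on log10(dilution) (or linear
    concentration with ``log_x=False``), pooled over sites by default or
    averaged over per-site slopes with ``per_site=True``.  ``delta_lc`` is
    LC(test) - LC(reference).
    """
    df = pd.DataFrame([{
        "site_id": s.site_id, "odor": s.odor, "concentration": s.concentration,
        "frac_responsive": s.frac_responsive} for s in summaries])

    def _lc(stim: str) -> tuple[float, float]:
        sub = df[df["odor"] == stim]
        if sub["concentration"].nunique() < 2:
            raise ValueError(f"LC undefined: stimulus {stim!r} has a single "
                             "concentration")
        x_all = (np.log10(sub["concentration"].to_numpy()) if log_x
                 else sub["concentration"].to_numpy())
        y_all = sub["frac_responsive"].to_numpy()
        if per_site:
            slopes = []
            for _, grp in sub.groupby("site_id"):
                x = (np.log10(grp["concentration"].to_numpy()) if log_x
                     else grp["concentration"].to_numpy())
                slopes.append(np.polyfit(x, grp["frac_responsive"].to_numpy(), 1)[0])
            slope = float(np.mean(slopes))
        else:
            slope = float(np.polyfit(x_all, y_all, 1)[0])
        r = (_stats.pearson_r(x_all, y_all)
             if np.std(y_all) > 0 else 0.0)
        return slope, r

    lc_test, r_test = _lc(test_stimulus)
    if reference_stimulus is not None:
        lc_ref, _ = _lc(reference_stimulus)
        delta = lc_test - lc_ref
    else:
        lc_ref = np.nan
        delta = np.nan
    return ConcentrationSeriesResult(lc_test=lc_test, lc_reference=lc_ref,
                                     delta_lc=delta, pearson_r_test=r_test,
                                     points=df)
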