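"""Whole-cell Vm analysis: spike clipping, evoked responses, theta coupling.

Awake protocol: per trial the baseline Vm is the mean over the 2 s before
valve opening; response windows (1/2/5 s) start at the first inhalation after
valve opening.  Anesthetized protocol: traces are aligned to respiration
cycle peaks, the mean baseline cycle waveform is subtracted from the first
complete post-valve cycle, and the evoked Vm is the mean of that residual.
Theta coupling is measured from sniff cycles of 0.2-0.32 s duration within
inter-trial intervals: each cycle's Vm is resampled to phase, averaged, and
the coupling strength is half the peak-to-trough of the mean waveform.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as _signal

from .datatypes import EvokedResponse, SpikeClippedVm, ThetaCoupling, VmRecording
from . import stats as _stats

N_PHASE_BINS = 64


def detect_spikes_and_clip(rec: VmRecording,
                           threshold_mv_above_median: float = 20.0,
                           clip_window_ms: float = 6.0) -> SpikeClippedVm:
    """Detect spikes (upward threshold crossings) and interpolate them away.

    A spike is an upward crossing of median(Vm) + threshold with a 1-ms
    refractory period; each spike's clip window (centered slightly before
    the crossing to catch the upstroke) is replaced by linear interpolation.
    """
    vm = np.asarray(rec.vm, dtype=float)
    if not np.isfinite(vm).all():
        raise ValueError("Vm must be finite")
    fs = rec.sample_rate_hz
    thresh = np.median(vm) + threshold_mv_above_median
    above = vm > thresh
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if crossings.size:
        keep = np.concatenate([[True], np.diff(crossings) > 0.001 * fs])
        crossings = crossings[keep]

    clipped = vm.copy()
    half = int(round(clip_window_ms / 1000.0 * fs / 2.0))
    pre = max(half // 2, 1)
    for idx in crossings:
        lo = max(idx - pre, 0)
        hi = min(idx - pre + 2 * half, vm.size - 1)
        if hi <= lo:
            continue
        clipped[lo:hi + 1] = np.linspace(clipped[lo], clipped[hi], hi - lo + 1)
    return SpikeClippedVm(vm_clipped=clipped,
                          spike_times_s=crossings / fs,
                          sample_rate_hz=fs)


def baseline_firing_rate(spike_times_s, windows) -> float:
    """Spike count / total duration over the given (start, end) windows."""
    spikes = np.asarray(spike_times_s, dtype=float)
    total = 0.0
    count = 0
    for start, end in windows:
        if end <= start:
            continue
        total += end - start
        count += int(np.sum((spikes >= start) & (spikes < end)))
    if total <= 0:
        raise ValueError("total baseline duration must be positive")
    return count / total


def baseline_windows(rec: VmRecording, pre_pad_s: float = 2.0,
                     post_pad_s: float = 5.0) -> list[tuple[float, float]]:
    """Inter-trial windows: everything outside [open - pre_pad, close + post_pad]."""
    windows = []
    t0 = 0.0
    for open_s, close_s, _ in rec.odor_events:
        lo = max(open_s - pre_pad_s, 0.0)
        if lo > t0:
            windows.append((t0, lo))
        t0 = close_s + post_pad_s
    if rec.duration_s > t0:
        windows.append((t0, rec.duration_s))
    return windows


def detect_inhalations(sniff_signal, sample_rate_hz: float,
                       min_separation_s: float = 0.08,
                       lowpass_hz: float = 15.0) -> np.ndarray:
    """Inhalation peak times: maxima of the low-passed signal above an
    adaptive (median + 0.2 SD) threshold, at least 80 ms apart."""
    x = np.asarray(sniff_signal, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("sniff signal must be finite")
    if x.std() == 0:
        warnings.warn("flat sniff signal: no inhalations detected")
        return np.array([])
    nyq = sample_rate_hz / 2.0
    if lowpass_hz < nyq:
        sos = _signal.butter(3, lowpass_hz / nyq, output="sos")
        x = _signal.sosfiltfilt(sos, x)
    height = np.median(x) + 0.2 * x.std()
    peaks, _ = _signal.find_peaks(
        x, height=height, distance=max(int(min_separation_s * sample_rate_hz), 1))
    return peaks / sample_rate_hz


def _first_inhalation_after(inhalations, t: float) -> float | None:
    inh = np.asarray(inhalations, dtype=float)
    after = inh[inh >= t]
    return float(after[0]) if after.size else None


def evoked_vm_awake(clipped: SpikeClippedVm, inhalations, events,
                    windows_s=(1.0, 2.0, 5.0), baseline_s: float = 2.0):
    """Awake evoked Vm over the given windows, averaged across trials.

    Per trial: baseline = mean Vm over [open - baseline_s, open); each
    response window starts at the first inhalation after valve opening.
    Returns ``(means, per_trial, baseline_sd)`` where ``means`` maps window
    length -> trial-averaged dVm, ``per_trial`` the per-trial values and
    ``baseline_sd`` the SD across trials of the baseline means (the
    "baseline fluctuation" used by the +-2 SD significance rule).
    """
    vm = clipped.vm_clipped
    fs = clipped.sample_rate_hz
    per_trial: dict[float, list[float]] = {w: [] for w in windows_s}
    baselines = []
    for open_s, _close_s, _ in events:
        t0 = _first_inhalation_after(inhalations, open_s)
        if t0 is None:
            warnings.warn(f"no inhalation after valve at {open_s:.2f} s; "
                          "trial skipped")
            continue
        b_lo = int(round((open_s - baseline_s) * fs))
        b_hi = int(round(open_s * fs))
        if b_lo < 0:
            warnings.warn("baseline window precedes recording start; skipped")
            continue
        baseline = float(vm[b_lo:b_hi].mean())
        baselines.append(baseline)
        i0 = int(round(t0 * fs))
        for w in windows_s:
            i1 = min(int(round((t0 + w) * fs)), vm.size)
            per_trial[w].append(float(vm[i0:i1].mean()) - baseline)
    means = {w: (float(np.mean(v)) if v else np.nan) for w, v in per_trial.items()}
    baseline_sd = float(np.std(baselines, ddof=1)) if len(baselines) > 1 else np.nan
    return means, per_trial, baseline_sd


def _cycle_bounds(peaks, lo_s, hi_s):
    """(start, end) pairs of consecutive peaks whose spacing is in [lo, hi)."""
    peaks = np.asarray(peaks, dtype=float)
    durations = np.diff(peaks)
    ok = (durations >= lo_s) & (durations < hi_s)
    return [(peaks[i], peaks[i + 1]) for i in np.flatnonzero(ok)]


def evoked_vm_anesthetized(clipped: SpikeClippedVm, expiration_peaks, event,
                           n_baseline_cycles: int = 5):
    """Cycle-aligned evoked Vm with baseline-waveform subtraction.

    The ``n_baseline_cycles`` respiration cycles preceding valve opening are
    resampled to a common length and averaged into a baseline waveform; that
    waveform is subtracted from the first complete cycle after valve opening
    and the evoked Vm is the mean of the residual.  Cycles longer than 3x
    the median cycle length are excluded as irregular.
    """
    vm = clipped.vm_clipped
    fs = clipped.sample_rate_hz
    open_s = event[0]
    peaks = np.asarray(expiration_peaks, dtype=float)
    if peaks.size < 4:
        raise ValueError("need at least 3 baseline respiration cycles")
    med = float(np.median(np.diff(peaks)))
    cycles = _cycle_bounds(peaks, 0.0, 3.0 * med)

    base = [c for c in cycles if c[1] <= open_s][-n_baseline_cycles:]
    if len(base) < 3:
        raise ValueError("need at least 3 baseline respiration cycles")
    post = [c for c in cycles if c[0] >= open_s]
    if not post:
        raise ValueError("no complete respiration cycle after valve opening")
    first_post = post[0]

    n_resamp = 256

    def _resample(c):
        i0, i1 = int(round(c[0] * fs)), int(round(c[1] * fs))
        seg = vm[i0:i1]
        src = np.linspace(0.0, 1.0, seg.size)
        dst = np.linspace(0.0, 1.0, n_resamp)
        return np.interp(dst, src, seg)

    baseline_wave = np.mean([_resample(c) for c in base], axis=0)
    residual = _resample(first_post) - baseline_wave
    return float(residual.mean())


def vm_significance(dvm: float, baseline_fluctuation_sd: float) -> str:
    """Hyperpolarizing if dVm < -2 SD, depolarizing if > +2 SD, else none."""
    if baseline_fluctuation_sd < 0:
        raise ValueError("SD must be >= 0")
    if dvm < -2.0 * baseline_fluctuation_sd:
        return "hyperpolarizing"
    if dvm > 2.0 * baseline_fluctuation_sd:
        return "depolarizing"
    return "none"


def fr_response(spike_times_s, inhalations, events, bin_s: float = 0.25,
                odor_dur_s: float = 1.0, baseline_s: float = 2.0):
    """Binned firing-rate response and paired t-test across trials.

    Per trial, FR is computed in ``bin_s`` bins aligned to the first
    inhalation after valve opening (odor period) and over the 2 s before
    valve opening (baseline); dFR = mean odor-bin FR - mean baseline FR,
    averaged over trials.  The paired t-test compares baseline vs odor FR
    across trials (p is None with < 2 usable trials).
    """
    spikes = np.asarray(spike_times_s, dtype=float)
    base_rates = []
    odor_rates = []
    for open_s, _close, _ in events:
        t0 = _first_inhalation_after(inhalations, open_s)
        if t0 is None:
            warnings.warn(f"no inhalation after valve at {open_s:.2f} s; "
                          "trial skipped")
            continue
        edges_b = np.arange(open_s - baseline_s, open_s + 1e-9, bin_s)
        in_b = spikes[(spikes >= open_s - baseline_s) & (spikes < open_s)]
        counts_b, _ = np.histogram(in_b, bins=edges_b)
        edges_o = np.arange(t0, t0 + odor_dur_s + 1e-9, bin_s)
        in_o = spikes[(spikes >= t0) & (spikes < t0 + odor_dur_s)]
        counts_o, _ = np.histogram(in_o, bins=edges_o)
        base_rates.append(counts_b.mean() / bin_s)
        odor_rates.append(counts_o.mean() / bin_s)
    if not base_rates:
        raise ValueError("no usable trials")
    base_rates = np.asarray(base_rates)
    odor_rates = np.asarray(odor_rates)
    dfr = float((odor_rates - base_rates).mean())
    if base_rates.size >= 2 and np.std(odor_rates - base_rates, ddof=1) > 0:
        _t, p = _stats.paired_t(odor_rates, base_rates)
    else:
        p = None
    return dfr, p


def theta_coupling(clipped: SpikeClippedVm, inhalations,
                   analysis_windows=None, cycle_bounds_s=(0.2, 0.32),
                   min_cycles: int = 5) -> ThetaCoupling:
    """Sniff-cycle modulation of baseline Vm.

    Qualifying sniff cycles (duration within ``cycle_bounds_s``, fully inside
    an analysis window) are resampled to phase [0, 2pi), averaged, and the
    cycle mean of each is removed so slow drifts do not masquerade as
    coupling.  Strength = (max - min) / 2 of the phase-averaged waveform;
    the preferred phase is the position of its maximum (phase 0 at the
    inhalation peak).
    """
    vm = clipped.vm_clipped
    fs = clipped.sample_rate_hz
    cycles = _cycle_bounds(np.asarray(inhalations, dtype=float),
                           cycle_bounds_s[0], cycle_bounds_s[1])
    if analysis_windows is not None:
        cycles = [c for c in cycles
                  if any(c[0] >= lo and c[1] <= hi for lo, hi in analysis_windows)]

    waves = []
    for c0, c1 in cycles:
        i0, i1 = int(round(c0 * fs)), int(round(c1 * fs))
        seg = vm[i0:i1]
        if seg.size < N_PHASE_BINS:
            continue
        src = np.linspace(0.0, 2.0 * np.pi, seg.size, endpoint=False)
        dst = np.linspace(0.0, 2.0 * np.pi, N_PHASE_BINS, endpoint=False)
        waves.append(np.interp(dst, src, seg - seg.mean()))
    low_conf = len(waves) < min_cycles
    if low_conf:
        warnings.warn(f"only {len(waves)} qualifying sniff cycles (< {min_cycles})")
    if not waves:
        return ThetaCoupling(strength_mv=0.0, phase_rad=0.0, n_cycles=0,
                             low_confidence=True)
    mean_wave = np.mean(waves, axis=0)
    strength = float((mean_wave.max() - mean_wave.min()) / 2.0)
    phase = float(np.linspace(0.0, 2.0 * np.pi, N_PHASE_BINS,
                              endpoint=False)[int(np.argmax(mean_wave))])
    if phase >= np.pi:
        phase -= 2.0 * np.pi
    return ThetaCoupling(strength_mv=strength, phase_rad=phase,
                         n_cycles=len(waves), low_confidence=low_conf)


def analyze_awake_recording(rec: VmRecording,
                            use_generator_inhalations: bool = False
                            ) -> EvokedResponse:
    """Full awake pipeline for one cell-odor recording."""
    clipped = detect_spikes_and_clip(rec)
    if use_generator_inhalations and rec.inhalation_times_s is not None:
        inh = rec.inhalation_times_s
    else:
        inh = detect_inhalations(rec.sniff_signal, rec.sample_rate_hz)
    means, _per_trial, base_sd = evoked_vm_awake(clipped, inh, rec.odor_events)
    dfr, p = fr_response(clipped.spike_times_s, inh, rec.odor_events)
    sig_vm = (vm_significance(means[1.0], base_sd)
              if np.isfinite(base_sd) else "none")
    return EvokedResponse(
        cell_id=rec.cell_id, odor=rec.odor_events[0][2] if rec.odor_events else "",
        dvm_1s_mv=means.get(1.0, np.nan), dvm_2s_mv=means.get(2.0, np.nan),
        dvm_5s_mv=means.get(5.0, np.nan), dfr_hz=dfr,
        significant_vm=sig_vm,
        significant_fr=bool(p is not None and p < 0.05), fr_p_value=p)
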