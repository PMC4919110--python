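"""Sniff-frequency novelty/adaptation analysis and go/no-go block accuracy.

Sniff frequencies are inverses of mean inter-sniff intervals: the baseline
uses intervals fully inside the 2 s before odor onset, the odor-period
frequency uses intervals beginning and ending within the odor window
(half-open windows; straddling intervals are excluded).
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import GoNoGoLog, SniffResponse, SniffSession
from . import stats as _stats


def _mean_isi_within(times: np.ndarray, lo: float, hi: float) -> float | None:
    """Mean inter-sniff interval over intervals fully inside [lo, hi)."""
    inside = times[(times >= lo) & (times < hi)]
    if inside.size < 2:
        return None
    return float(np.mean(np.diff(inside)))


def sniff_frequencies(session: SniffSession, presentation,
                      baseline_s: float = 2.0) -> SniffResponse | None:
    """Baseline and odor-period sniff frequency for one presentation.

    Returns None (with a warning) when either window lacks two inhalations.
    """
    odor, onset, offset, idx = presentation
    t = session.inhalation_times_s
    isi_base = _mean_isi_within(t, onset - baseline_s, onset)
    isi_odor = _mean_isi_within(t, onset, offset)
    if isi_base is None or isi_odor is None:
        warnings.warn(f"presentation {odor}#{idx}: too few inhalations, excluded")
        return None
    return SniffResponse(odor=odor, presentation_index=idx,
                         baseline_freq_hz=1.0 / isi_base,
                         odor_freq_hz=1.0 / isi_odor,
                         session_id=session.session_id)


def session_responses(session: SniffSession) -> list[SniffResponse]:
    out = []
    for pres in session.presentations:
        r = sniff_frequencies(session, pres)
        if r is not None:
            out.append(r)
    return out


def instantaneous_frequency_trace(session: SniffSession,
                                  window_ms: float = 500.0,
                                  dt_s: float = 0.01):
    """Moving-average instantaneous sniff frequency vs window leading edge.

    The instantaneous frequency 1/ISI is assigned over each inter-sniff
    interval and boxcar-averaged over the trailing ``window_ms`` window; the
    trace is sampled every ``dt_s`` and ends at the last inhalation.
    """
    t = session.inhalation_times_s
    if t.size < 2:
        raise ValueError("need at least 2 inhalations")
    win = window_ms / 1000.0
    edges = np.arange(t[0] + win, t[-1] + dt_s / 2.0, dt_s)
    if edges.size == 0:
        edges = np.array([t[-1]])
    isis = np.diff(t)
    inst = 1.0 / isis

    # integral of the piecewise-constant instantaneous-frequency function
    def _integral(upto: np.ndarray) -> np.ndarray:
        cum = np.concatenate([[0.0], np.cumsum(inst * isis)])
        idx = np.clip(np.searchsorted(t, upto, side="right") - 1, 0, isis.size - 1)
        partial = cum[idx] + inst[idx] * np.clip(upto - t[idx], 0.0, isis[idx])
        return partial

    vals = (_integral(edges) - _integral(edges - win)) / win
    return edges, vals


def adaptation_test(responses: list[SniffResponse]):
    """Novelty adaptation: 1st presentation vs mean of 2nd and 3rd.

    Pairs are formed per (session, odor); a pair is dropped when any of
    presentations 1-3 is missing.  Returns
    ``(mean_1st, mean_23, t, p, n_pairs)`` with a paired t-test (two-tailed)
    across pairs.
    """
    by_key: dict[tuple, dict[int, float]] = {}
    for r in responses:
        by_key.setdefault((r.session_id, r.odor), {})[r.presentation_index] = \
            r.response_hz
    firsts, laters = [], []
    for vals in by_key.values():
        if not all(k in vals for k in (1, 2, 3)):
            continue
        firsts.append(vals[1])
        laters.append((vals[2] + vals[3]) / 2.0)
    if len(firsts) < 2:
        raise ValueError("need at least 2 complete (1st, 2nd, 3rd) pairs")
    firsts = np.asarray(firsts)
    laters = np.asarray(laters)
    t, p = _stats.paired_t(firsts, laters)
    return float(firsts.mean()), float(laters.mean()), t, p, len(firsts)


def block_accuracy(log: GoNoGoLog) -> np.ndarray:
    """Percent correct per consecutive block (lick on S+ / no-lick on S-).

    A trailing partial block is dropped with a warning.
    """
    n_full = log.n_trials // log.block_size
    if log.n_trials % log.block_size:
        warnings.warn("trailing partial block dropped")
    correct = np.array([
        licked if cls == "S+" else not licked
        for cls, licked in zip(log.stimulus_class, log.licked)], dtype=float)
    correct = correct[:n_full * log.block_size]
    return 100.0 * correct.reshape(n_full, log.block_size).mean(axis=1)


def criterion_check(block_accuracies, criterion_pct: float = 75.0) -> bool:
    """Session passes iff any block's accuracy strictly exceeds the criterion."""
    acc = np.asarray(block_accuracies, dtype=float)
    if acc.size == 0:
        raise ValueError("need at least one block")
    return bool(acc.max() > criterion_pct)
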