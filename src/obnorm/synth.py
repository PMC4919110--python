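"""Synthetic olfactory-bulb datasets with known ground truth.

Every generator is fully determined by ``(profile, seed)``.  The imaging
generator emulates sparse GCaMP-like odor responses: per site a latent
responsive fraction is drawn around the profile mean, each responder is
assigned an amplitude, a duration and a k-of-n trial reliability, and its
transient is an instantaneous-rise/exponential-decay kernel whose decay is
set so the trace re-crosses the nominal detection threshold at the drawn
duration.  On non-crossing trials a responder still emits the same transient
scaled by ``subthreshold_frac`` — consistent graded activity below the
response criterion, which is what carries trial-to-trial pattern
correlations in the control condition.

The electrophysiology generator builds 20-kHz membrane potential as
rest + sniff-locked theta + Ornstein-Uhlenbeck noise + stereotyped spikes +
an odor-evoked two-level deflection aligned to the first inhalation after
valve opening, so the awake analysis windows recover the drawn 1-s and 5-s
means.  Sniff sessions are inhomogeneous Gamma-renewal point processes
(time-rescaled, so rate steps at odor onset/offset are exact).
"""

from __future__ import annotations

import numpy as np
from scipy import signal as _signal

from .datatypes import (
    GoNoGoLog,
    ImagingDataset,
    SniffSession,
    TrialFluorescence,
    VmRecording,
)
from .profiles import EphysProfile, GeneratorProfile, SniffProfile

__all__ = [
    "generate_imaging_site",
    "generate_imaging_sites",
    "generate_concentration_series",
    "generate_concentration_study",
    "generate_ephys_recording",
    "generate_ephys_panel",
    "generate_sniff_session",
    "generate_gonogo_session",
]


def _rng_from(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _truncated_normal(rng, mean, sd, low, size):
    """Normal draws resampled until >= low (vectorized rejection)."""
    out = rng.normal(mean, sd, size)
    bad = out < low
    # rejection loop terminates fast for any sane (mean, sd, low)
    for _ in range(200):
        n_bad = int(bad.sum())
        if n_bad == 0:
            return out
        out[bad] = rng.normal(mean, sd, n_bad)
        bad = out < low
    out[out < low] = low
    return out


# ---------------------------------------------------------------------------
# imaging
# ---------------------------------------------------------------------------

# sub-threshold plateaus are capped at this many noise SDs below threshold
# (higher plateaus start crossing the >=3-frame criterion through noise)
GHOST_CAP_SD = 0.7
GHOST_PLATEAU_S = 4.5
GHOST_DECAY_S = 0.5
WEAK_CELL_FRAC = 0.5


def _plateau_kernel(t_frames, onset, dur_s=GHOST_PLATEAU_S, tau=GHOST_DECAY_S):
    """Unit plateau from onset for dur_s seconds, then exponential decay."""
    dt = t_frames[None, :] - onset[:, None]
    return np.where(dt < 0.0, 0.0,
                    np.where(dt < dur_s, 1.0, np.exp(-(dt - dur_s) / tau)))


def _beta_rates(u, mean, conc_param):
    """Per-cell responder rates: Beta quantiles at shared uniforms ``u``.

    Mean is exactly ``mean``; ``conc_param`` controls the across-cell
    dispersion (odor-tuning heterogeneity).  Monotone in ``mean`` for fixed
    ``u``, which makes responder sets nested across a concentration series.
    """
    from scipy import special as _sp
    mean = min(max(mean, 1e-9), 1.0 - 1e-9)
    return _sp.betaincinv(mean * conc_param, (1.0 - mean) * conc_param, u)


def _site_core(profiles_by_conc, seed, site_id, odor_label):
    """Generate one imaging site for >= 1 concentrations of one odor set.

    All concentrations share the cell population, per-cell excitability and
    the site random effect; responder sets are nested across concentrations
    (a cell recruited at a low concentration stays recruited at higher ones).
    """
    concs = sorted(profiles_by_conc)
    base = profiles_by_conc[concs[0]]
    n_cells = base.cells_per_site
    for p in profiles_by_conc.values():
        if p.cells_per_site != n_cells:
            raise ValueError("cells_per_site must match across the series")
    rng = _rng_from(seed)

    n_odors = base.n_odors if len(concs) == 1 else 1
    odors = ([f"odor{i + 1:02d}" for i in range(n_odors)]
             if odor_label is None else [odor_label])
    n_trials = base.n_trials
    n_frames = int(round((base.pre_odor_s + base.odor_dur_s + base.post_odor_s)
                         * base.frame_rate_hz))
    t_frames = np.arange(n_frames) / base.frame_rate_hz

    site_z = rng.standard_normal()                      # shared site random effect
    rate_u = rng.random(n_cells)                        # cell excitability quantile
    recruit_u = rng.random((n_cells, len(odors)))       # nests responders across concs
    f0_cells = rng.normal(100.0, 10.0, n_cells).clip(min=30.0)
    # non-responders with consistent sub-criterion activity (per cell-odor)
    weak_cell = rng.random((n_cells, len(odors))) < WEAK_CELL_FRAC
    weak_level = rng.uniform(0.2, 0.7, (n_cells, len(odors)))

    trials: list[TrialFluorescence] = []
    stim_odors: list[str] = []
    stim_concs: list[float] = []
    gt_blocks = []
    amp_blocks = []

    for conc in concs:
        prof = profiles_by_conc[conc]
        f_site = float(np.clip(prof.frac_responsive + prof.latent_site_sd() * site_z,
                               0.0, 1.0))
        pool = min(1.0, f_site * n_trials / prof.mean_trials_active)
        thr = prof.nominal_threshold
        ghost_cap = GHOST_CAP_SD * prof.noise_sd
        rel = np.asarray(prof.reliability_probs)
        rates = _beta_rates(rate_u, pool, prof.tuning_shape)

        for io, odor in enumerate(odors):
            responder = recruit_u[:, io] < rates
            # per-responder response identity: amplitude, duration, onset, k
            amp = _truncated_normal(rng, prof.amp_mean, prof.amp_sd,
                                    prof.amp_min, n_cells)
            min_dur = 3.0 / prof.frame_rate_hz * 1.05
            dur = _truncated_normal(rng, prof.dur_mean_s, prof.dur_sd_s,
                                    min_dur, n_cells)
            onset = base.odor_onset_s + rng.uniform(
                0.0, min(prof.odor_dur_s, 1.0), n_cells)
            k_active = 1 + rng.choice(n_trials, size=n_cells, p=rel)
            # reliable responders respond more strongly (threshold effect);
            # the floor is re-applied so every responder stays detectable
            dk = k_active - prof.mean_trials_active
            amp = np.clip(amp * np.exp(prof.amp_reliability_coupling * dk),
                          prof.amp_min, prof.amp_max)
            # lengthen reliable cells' transients only: shortening unreliable
            # ones would push their single responses under the 3-frame rule
            dur = dur * np.exp(prof.dur_reliability_coupling * np.maximum(dk, 0.0))
            with np.errstate(divide="ignore"):
                tau = np.where(amp > thr * 1.05,
                               dur / np.log(np.maximum(amp / thr, 1.001)),
                               prof.decay_tau_s)
            ghost_amp = np.minimum(prof.subthreshold_frac * amp, ghost_cap)
            weak_amp = np.where(weak_cell[:, io] & ~responder,
                                weak_level[:, io] * ghost_cap, 0.0)

            # which trials each responder crosses threshold on
            order = np.argsort(rng.random((n_cells, n_trials)), axis=1)
            active = order < k_active[:, None]

            resp_kernel = (np.exp(-np.maximum(t_frames[None, :] - onset[:, None],
                                              0.0) / tau[:, None])
                           * (t_frames[None, :] >= onset[:, None]))
            flat_kernel = _plateau_kernel(t_frames, onset)

            gt = np.zeros((n_cells, n_trials), dtype=bool)
            amps = np.zeros((n_cells, n_trials))
            for it in range(n_trials):
                gain = rng.lognormal(-0.5 * prof.trial_amp_jitter**2,
                                     prof.trial_amp_jitter, n_cells)
                is_active = responder & active[:, it]
                is_ghost = responder & ~active[:, it]
                peak = np.where(is_active, amp * gain, 0.0)
                flat = gain * (np.where(is_ghost, ghost_amp, 0.0) + weak_amp)
                dff_true = (peak[:, None] * resp_kernel
                            + flat[:, None] * flat_kernel)
                noise = rng.normal(0.0, prof.noise_sd, (n_cells, n_frames))
                values = f0_cells[:, None] * (1.0 + dff_true + noise)
                trials.append(TrialFluorescence(
                    values=values, frame_rate_hz=prof.frame_rate_hz,
                    odor_onset_s=base.odor_onset_s,
                    odor_offset_s=base.odor_onset_s + prof.odor_dur_s,
                    odor_label=odor, concentration=conc, trial_index=it,
                    site_id=site_id, cell_class=prof.cell_class))
                gt[:, it] = is_active
                amps[:, it] = np.where(is_active, peak, 0.0)
            gt_blocks.append(gt)
            amp_blocks.append(amps)
            stim_odors.append(odor)
            stim_concs.append(conc)

    ground_truth = np.stack(gt_blocks, axis=1)     # cells x stimuli x trials
    true_amplitude = np.stack(amp_blocks, axis=1)
    return ImagingDataset(
        trials=trials,
        cell_ids=[f"{site_id}_c{i:03d}" for i in range(n_cells)],
        odor_labels=stim_odors,
        concentration_labels=stim_concs,
        ground_truth=ground_truth,
        true_amplitude=true_amplitude,
        site_id=site_id,
    )


def generate_imaging_site(profile: GeneratorProfile, seed,
                          site_id: str = "site00",
                          concentration: float = 1e-4) -> ImagingDataset:
    """One imaging site: ``n_odors`` stimuli x ``n_trials`` trials."""
    return _site_core({concentration: profile}, seed, site_id, odor_label=None)


def generate_imaging_sites(profile: GeneratorProfile, seed) -> list[ImagingDataset]:
    """All ``profile.n_sites`` sites, each from a spawned child seed."""
    seeds = np.random.SeedSequence(seed).spawn(profile.n_sites)
    return [generate_imaging_site(profile, s, site_id=f"site{i:02d}")
            for i, s in enumerate(seeds)]


def generate_concentration_series(profile_per_conc: dict[float, GeneratorProfile],
                                  seed, site_id: str = "site00",
                                  odor_label: str = "acetophenone") -> ImagingDataset:
    """One site measured at every concentration of a dilution series."""
    if len(profile_per_conc) < 1:
        raise ValueError("need at least one concentration")
    return _site_core(profile_per_conc, seed, site_id, odor_label=odor_label)


def generate_concentration_study(profile_per_conc, seed,
                                 odor_label: str = "acetophenone"
                                 ) -> list[ImagingDataset]:
    """A concentration series replicated over the profile's ``n_sites``."""
    n_sites = next(iter(profile_per_conc.values())).n_sites
    seeds = np.random.SeedSequence(seed).spawn(n_sites)
    return [generate_concentration_series(profile_per_conc, s,
                                          site_id=f"site{i:02d}",
                                          odor_label=odor_label)
            for i, s in enumerate(seeds)]


# ---------------------------------------------------------------------------
# electrophysiology
# ---------------------------------------------------------------------------

def _renewal_times(rng, rate_hz, t_end, shape):
    """Gamma-renewal event times at constant rate, starting near 0."""
    n_exp = int(rate_hz * t_end * 1.5 + 20)
    isis = rng.gamma(shape, 1.0 / (shape * rate_hz), n_exp)
    t = np.cumsum(isis) - isis[0] * rng.random()
    while t[-1] < t_end:
        extra = rng.gamma(shape, 1.0 / (shape * rate_hz), n_exp)
        t = np.concatenate([t, t[-1] + np.cumsum(extra)])
    return t[t < t_end]


def _ou_noise(rng, n, dt, tau, sd):
    a = np.exp(-dt / tau)
    white = rng.standard_normal(n)
    return _signal.lfilter([sd * np.sqrt(1.0 - a * a)], [1.0, -a], white)


_SPIKE_MS = np.array([0.0, 0.3, 0.6, 1.0, 1.6, 2.4, 4.0])
_SPIKE_SHAPE = np.array([0.0, 0.55, 1.0, 0.35, -0.12, -0.05, 0.0])


def _spike_kernel(sample_rate_hz, amp_mv):
    t = np.arange(0.0, _SPIKE_MS[-1], 1000.0 / sample_rate_hz)
    return amp_mv * np.interp(t, _SPIKE_MS, _SPIKE_SHAPE)


def generate_ephys_recording(profile: EphysProfile, n_trials: int, seed,
                             odor: str = "odor", cell_id: str = "cell00",
                             protocol: str = "awake") -> VmRecording:
    """One cell-odor whole-cell recording with ``n_trials`` odor trials."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = _rng_from(seed)
    fs = profile.sample_rate_hz
    dt = 1.0 / fs
    trial_len = profile.trial_len_s
    t_total = trial_len * n_trials
    n = int(round(t_total * fs))
    times = np.arange(n) * dt

    sniff_rate = profile.sniff_freq_hz if protocol == "awake" else 2.5
    inh = _renewal_times(rng, sniff_rate, t_total, profile.sniff_shape)
    # cycle phase: 0 at each inhalation peak, linear to 2*pi at the next
    phase = np.interp(times, inh, np.arange(inh.size) * 2.0 * np.pi)
    sniff_sig = np.cos(phase) + rng.normal(0.0, 0.05, n)

    # cell-level draws; positive quantities are lognormal so the population
    # mean/SD match the profile without truncation bias
    def _logn(mean, sd):
        if mean <= 0:
            return 0.0
        s2 = np.log(1.0 + (sd / mean) ** 2)
        return float(rng.lognormal(np.log(mean) - 0.5 * s2, np.sqrt(s2)))

    theta_amp = _logn(profile.theta_amp_mv, profile.theta_amp_sd_mv)
    # cells prefer different sniff phases (population spread); a fixed
    # preference would also bias inhalation-aligned window means
    theta_phase = rng.uniform(-np.pi, np.pi)
    base_fr = _logn(profile.baseline_fr_mean_hz, profile.baseline_fr_sd_hz)
    dvm1 = rng.normal(profile.dvm_mean_mv, profile.dvm_sd_mv)
    dvm5 = rng.normal(profile.dvm5_mean_mv, profile.dvm5_sd_mv)
    # odor firing rate = (b + mean dFR) x unit-mean lognormal gain: respects
    # the rate >= 0 floor while keeping the measured dFR mean exact
    base_plus = base_fr + profile.dfr_mean_hz
    if base_plus > 0.5:
        sx2 = np.log(1.0 + (profile.dfr_sd_hz / base_plus) ** 2)
        gain = rng.lognormal(-0.5 * sx2, np.sqrt(sx2))
        odor_rate = base_plus * gain
    else:
        odor_rate = max(base_fr + rng.normal(profile.dfr_mean_hz,
                                             profile.dfr_sd_hz), 0.0)
    # two-level deflection: level on the 1-s odor window, tail to 5 s chosen
    # so the 5-s mean equals the drawn value
    tail = (5.0 * dvm5 - dvm1) / 4.0

    vm = np.full(n, profile.vrest_mv)
    vm += theta_amp * np.cos(phase - theta_phase)
    vm += _ou_noise(rng, n, dt, 0.05, profile.vm_noise_sd_mv)

    odor_events = []
    rate = np.full(n, base_fr)
    for trial in range(n_trials):
        v_open = trial * trial_len + profile.valve_open_s
        v_close = v_open + profile.odor_dur_s
        odor_events.append((v_open, v_close, odor))
        after = inh[inh >= v_open]
        t0 = after[0] if after.size else v_open
        i0 = int(round(t0 * fs))
        i1 = min(int(round((t0 + 1.0) * fs)), n)
        i5 = min(int(round((t0 + 5.0) * fs)), n)
        has_vm_response = (profile.dvm_sd_mv > 0 or profile.dvm5_sd_mv > 0
                           or profile.dvm_mean_mv != 0 or profile.dvm5_mean_mv != 0)
        jit = rng.normal(0.0, 0.3) if has_vm_response else 0.0
        vm[i0:i1] += dvm1 + jit
        vm[i1:i5] += tail + jit
        rate[i0:i1] = odor_rate

    # Poisson spiking on the sample grid with a 2-ms refractory
    spikes = np.flatnonzero(rng.random(n) < rate * dt)
    if spikes.size:
        keep = np.concatenate([[True], np.diff(spikes) > 0.002 * fs])
        spikes = spikes[keep]
        kern = _spike_kernel(fs, profile.spike_amp_mv)
        padded = np.zeros(n + kern.size)
        for idx in spikes:
            padded[idx:idx + kern.size] += kern
        vm += padded[:n]

    return VmRecording(vm=vm, sniff_signal=sniff_sig, sample_rate_hz=fs,
                       odor_events=odor_events, protocol=protocol,
                       cell_id=cell_id, inhalation_times_s=inh)


def generate_ephys_panel(profile: EphysProfile, n_pairs: int, n_trials: int,
                         seed, protocol: str = "awake") -> list[VmRecording]:
    """``n_pairs`` independent cell-odor recordings (spawned child seeds)."""
    seeds = np.random.SeedSequence(seed).spawn(n_pairs)
    return [generate_ephys_recording(profile, n_trials, s,
                                     cell_id=f"cell{i:02d}", protocol=protocol)
            for i, s in enumerate(seeds)]


# ---------------------------------------------------------------------------
# sniffing and operant behavior
# ---------------------------------------------------------------------------

def generate_sniff_session(profile: SniffProfile, n_presentations: int, seed,
                           odor: str = "odor",
                           session_id: str = "s00") -> SniffSession:
    """Inhalation times for repeated presentations of one odor.

    The instantaneous sniff rate is the baseline plus, inside each odor
    window, a response drawn from the first-presentation distribution for
    presentation 1 and the 2nd/3rd distribution afterwards.  Events come
    from a Gamma-renewal process generated in rescaled (operational) time,
    so rate steps at the window edges are exact.
    """
    if n_presentations < 1:
        raise ValueError("n_presentations must be >= 1")
    rng = _rng_from(seed)
    lead_in = 5.0
    period = profile.odor_dur_s + profile.iti_s
    t_end = lead_in + n_presentations * period

    presentations = []
    knots_t = [0.0]
    knots_rate = []
    for k in range(n_presentations):
        onset = lead_in + k * period
        offset = onset + profile.odor_dur_s
        if k == 0:
            resp = rng.normal(profile.response_1st_mean_hz, profile.response_1st_sd_hz)
        else:
            resp = rng.normal(profile.response_23_mean_hz, profile.response_23_sd_hz)
        presentations.append((odor, onset, offset, k + 1))
        knots_t += [onset, offset]
        knots_rate += [profile.baseline_freq_hz,
                       max(profile.baseline_freq_hz + resp, 0.8)]
    knots_t.append(t_end)
    knots_rate.append(profile.baseline_freq_hz)

    # piecewise-constant rate -> piecewise-linear integrated rate Lambda(t)
    knots_t = np.asarray(knots_t)
    seg_rate = np.asarray(knots_rate)
    lam_knots = np.concatenate([[0.0], np.cumsum(seg_rate * np.diff(knots_t))])

    shape = profile.isi_shape
    n_exp = int(lam_knots[-1] * 1.5 + 30)
    ops = np.cumsum(rng.gamma(shape, 1.0 / shape, n_exp))
    ops = ops - ops[0] * rng.random()
    while ops[-1] < lam_knots[-1]:
        ops = np.concatenate([ops, ops[-1] + np.cumsum(rng.gamma(shape, 1.0 / shape, n_exp))])
    ops = ops[ops < lam_knots[-1]]
    times = np.interp(ops, lam_knots, knots_t)
    times = np.unique(times)

    return SniffSession(inhalation_times_s=times, presentations=presentations,
                        session_id=session_id)


def generate_gonogo_session(p_correct_per_block, trials_per_block: int = 20,
                            seed=0) -> GoNoGoLog:
    """Bernoulli go/no-go outcomes, S+/S- balanced within each block."""
    p_blocks = np.asarray(p_correct_per_block, dtype=float)
    if np.any((p_blocks < 0) | (p_blocks > 1)):
        raise ValueError("block probabilities must lie in [0, 1]")
    if trials_per_block % 2:
        raise ValueError("trials_per_block must be even for balanced S+/S-")
    rng = _rng_from(seed)
    classes: list[str] = []
    licked: list[bool] = []
    half = trials_per_block // 2
    for p in p_blocks:
        labels = np.array(["S+"] * half + ["S-"] * half)
        rng.shuffle(labels)
        correct = rng.random(trials_per_block) < p
        for lab, ok in zip(labels, correct):
            classes.append(str(lab))
            # correct means lick on S+ / withhold on S-
            licked.append(bool(ok if lab == "S+" else not ok))
    return GoNoGoLog(stimulus_class=classes, licked=licked,
                     block_size=trials_per_block)
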