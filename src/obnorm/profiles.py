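"""Named generator profiles describing each genotype/condition.

Every numeric default below that carries a citation-style comment is a
population statistic printed in the study being emulated; the remaining
values (noise level, kernel shape, dispersion parameters) are this package's
own design choices, documented in docs/methods.md.

Profiles are plain dataclasses; a flat ``key=value`` config file can override
any field via :func:`load_profile` / :func:`apply_overrides`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class GeneratorProfile:
    """Statistical structure of one imaging genotype/condition.

    ``frac_responsive`` is the trial-averaged responsive fraction the full
    pipeline should recover (mean across sites); ``frac_responsive_sd`` the
    TOTAL across-site SD of that measured fraction.  ``reliability_probs[k-1]``
    is the probability that a responder crosses threshold on exactly k of
    ``n_trials`` trials.  ``subthreshold_frac`` scales the transient a
    responder still emits on its non-crossing trials (consistent, graded,
    below-criterion activity); it is the knob that sets within-odor pattern
    correlations.  ``tuning_shape`` is the Beta concentration of
    per-cell responder rates (smaller = more heterogeneous odor tuning).
    """

    name: str
    n_sites: int
    cells_per_site: int
    frame_rate_hz: float = 2.53          # acquisition frame rate (imaging methods)
    pre_odor_s: float = 20.0
    odor_onset_s: float = 20.0
    odor_dur_s: float = 2.0              # 2-s odor pulse
    post_odor_s: float = 12.0
    n_trials: int = 4                    # 4 presentations per odorant
    n_odors: int = 13                    # 13-odorant panel
    frac_responsive: float = 0.145       # mean responsive fraction, control low conc.
    frac_responsive_sd: float = 0.112    # across-site SD of that fraction
    amp_mean: float = 0.175              # peak dF/F scale before reliability coupling
    amp_sd: float = 0.10
    amp_min: float = 0.14                # keep peaks clear of the 3.2 x SD criterion
    amp_max: float = 1.3                 # saturation of strong (reliable) responses
    dur_mean_s: float = 3.0              # most responses end within 8 s of onset
    dur_sd_s: float = 1.0
    reliability_probs: tuple = (0.56, 0.20, 0.10, 0.14)  # k-of-4 masses, control
    noise_sd: float = 0.03               # iid dF/F noise per frame
    decay_tau_s: float = 1.5             # fallback decay constant
    subthreshold_frac: float = 0.35
    amp_reliability_coupling: float = 0.4  # reliable responders are stronger
    dur_reliability_coupling: float = 0.2  # ... and their transients longer
    trial_amp_jitter: float = 0.10       # multiplicative per-trial gain SD
    tuning_shape: float = 0.9            # Beta concentration; ~46% odor-silent cells
    cell_class: str = "mitral"           # mitral (3.2 x SD) or pg (3.4 x SD)
    genotype: str = "control"

    def __post_init__(self) -> None:
        probs = np.asarray(self.reliability_probs, dtype=float)
        if probs.size != self.n_trials:
            raise ValueError("reliability_probs must have n_trials entries")
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0, atol=1e-6):
            raise ValueError("reliability_probs must be a probability vector summing to 1")
        for name in ("frac_responsive", "frac_responsive_sd", "subthreshold_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.frame_rate_hz <= 0 or self.odor_dur_s <= 0 or self.n_trials < 1:
            raise ValueError("frame_rate_hz, odor_dur_s must be > 0 and n_trials >= 1")

    @property
    def threshold_multiplier(self) -> float:
        return 3.4 if self.cell_class == "pg" else 3.2

    @property
    def nominal_threshold(self) -> float:
        """Detection threshold in dF/F units at the design noise level."""
        return self.threshold_multiplier * self.noise_sd

    @property
    def mean_trials_active(self) -> float:
        """E[k]: mean number of supra-threshold trials per responder."""
        k = np.arange(1, self.n_trials + 1)
        return float(np.sum(k * np.asarray(self.reliability_probs)))

    @property
    def responder_pool_rate(self) -> float:
        """Cell-level responder rate implied by the trial-averaged fraction."""
        return min(1.0, self.frac_responsive * self.n_trials / self.mean_trials_active)

    def sampling_sd(self) -> float:
        """Expected within-site sampling SD of the measured fraction.

        Var over cells of the per-cell trial-mean activity s * k / n_trials,
        divided by the number of cells: this is what finite cell sampling
        adds on top of the latent between-site spread.
        """
        k = np.arange(1, self.n_trials + 1)
        probs = np.asarray(self.reliability_probs)
        ek2 = float(np.sum(k**2 * probs))
        pool = self.responder_pool_rate
        var_cell = pool * ek2 / self.n_trials**2 - (pool * self.mean_trials_active / self.n_trials) ** 2
        return float(np.sqrt(max(var_cell, 0.0) / self.cells_per_site))

    def latent_site_sd(self) -> float:
        """Between-site SD of the latent fraction after removing sampling noise."""
        return float(np.sqrt(max(self.frac_responsive_sd**2 - self.sampling_sd() ** 2, 1e-6)))


@dataclass(frozen=True)
class EphysProfile:
    """Whole-cell recording statistics for one genotype (awake protocol)."""

    name: str
    sample_rate_hz: float = 20000.0      # digitization rate
    vrest_mv: float = -55.0
    baseline_fr_mean_hz: float = 5.8     # control baseline firing 5.8 +- 6.2 Hz
    baseline_fr_sd_hz: float = 6.2
    theta_amp_mv: float = 0.4            # theta modulation strength 0.4 +- 0.4 mV
    theta_amp_sd_mv: float = 0.4
    theta_phase_rad: float = float(np.pi / 2)
    sniff_freq_hz: float = 4.0
    sniff_shape: float = 16.0            # Gamma shape of inter-sniff intervals
    dvm_mean_mv: float = -1.8            # 1-s evoked Vm, control -1.8 +- 2.1 mV
    dvm_sd_mv: float = 2.1
    dvm5_mean_mv: float = -0.7           # 5-s evoked Vm, control -0.7 +- 0.5 mV
    dvm5_sd_mv: float = 0.5
    dfr_mean_hz: float = 2.2             # evoked firing-rate change +2.2 +- 13.3 Hz
    dfr_sd_hz: float = 13.3
    odor_dur_s: float = 1.0
    vm_noise_sd_mv: float = 0.3
    trial_len_s: float = 14.0
    valve_open_s: float = 8.0
    spike_amp_mv: float = 45.0
    genotype: str = "control"

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        for name in ("baseline_fr_sd_hz", "theta_amp_sd_mv", "dvm_sd_mv",
                     "dvm5_sd_mv", "dfr_sd_hz", "vm_noise_sd_mv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SniffProfile:
    """Sniff-frequency novelty response statistics for one condition."""

    name: str
    baseline_freq_hz: float = 4.0
    response_1st_mean_hz: float = 2.1    # novel-odor response 2.1 +- 1.6 Hz
    response_1st_sd_hz: float = 1.6
    response_23_mean_hz: float = 0.3     # 2nd/3rd presentation 0.3 +- 1.2 Hz
    response_23_sd_hz: float = 1.2
    odor_dur_s: float = 2.0
    iti_s: float = 10.0                  # inter-trial interval
    isi_shape: float = 8.0               # Gamma shape of inter-sniff intervals
    genotype: str = "control"

    def __post_init__(self) -> None:
        if self.baseline_freq_hz < 0 or self.odor_dur_s <= 0:
            raise ValueError("frequencies must be >= 0 and odor_dur_s > 0")


# --------------------------------------------------------------------------
# Named default profiles.  Concentration series are maps dilution -> profile.
# --------------------------------------------------------------------------

_CTRL_REL = (0.56, 0.20, 0.10, 0.14)      # control k-of-4 reliability masses
# Only the 4-of-4 mass (2.9%) is printed for the transgenic; k=1..3 rescale the
# control proportions to sum to 0.971.
_M71_REL = (0.632, 0.226, 0.113, 0.029)
# Trial-to-trial variability decreases with concentration; these vectors keep
# the responder-pool rate <= 1 at the printed high-concentration fractions.
_REL_MID = (0.30, 0.25, 0.20, 0.25)
_REL_HIGH = (0.03, 0.07, 0.15, 0.75)
_REL_PG_HIGH = (0.005, 0.015, 0.03, 0.95)
_REL_PG_LOW = (0.10, 0.15, 0.25, 0.50)

CTRL_MC_LOW = GeneratorProfile(
    name="CTRL-MC-LOW", n_sites=14, cells_per_site=35,
    frac_responsive=0.145, frac_responsive_sd=0.112,   # 14.5% +- 11.2%
    reliability_probs=_CTRL_REL, subthreshold_frac=0.35,
    genotype="control",
)

M71_MC_LOW = GeneratorProfile(
    name="M71-MC-LOW", n_sites=7, cells_per_site=28,
    frac_responsive=0.10, frac_responsive_sd=0.112,
    reliability_probs=_M71_REL, subthreshold_frac=0.0,
    amp_reliability_coupling=0.15, dur_reliability_coupling=0.05,
    amp_mean=0.16, dur_mean_s=4.0, dur_sd_s=1.5,       # smaller, longer responses
    genotype="m71",
)


def _series(base: GeneratorProfile, fracs, sds, rels, concs=(1e-4, 1e-3, 1e-2)):
    return {
        conc: replace(base, name=f"{base.name}@{conc:g}", frac_responsive=f,
                      frac_responsive_sd=s, reliability_probs=r)
        for conc, f, s, r in zip(concs, fracs, sds, rels)
    }


# Transgenic acetophenone series: 10.0% / 28.7% / 50.1% responsive mitral
# cells at 0.01 / 0.1 / 1% dilutions, across-site SDs 11.2 / 17.1 / 25.8%.
M71_ACET = _series(
    replace(M71_MC_LOW, name="M71-ACET", n_sites=10, cells_per_site=35),
    fracs=(0.10, 0.287, 0.501), sds=(0.112, 0.171, 0.258),
    rels=(_M71_REL, _REL_MID, _REL_HIGH),
)

# Control mitral series (both odorants behave alike: ~10 / ~15 / ~20%).
CTRL_ACET = _series(
    replace(CTRL_MC_LOW, name="CTRL-ACET", n_sites=10),
    fracs=(0.10, 0.15, 0.20), sds=(0.112, 0.12, 0.13),
    rels=(_CTRL_REL, _REL_MID, _REL_HIGH),
)
CTRL_EA = {c: replace(p, name=p.name.replace("ACET", "EA")) for c, p in CTRL_ACET.items()}

# Transgenic ethyl acetate series: ~1.5x at 10-fold, ~2x at 100-fold.
M71_EA = _series(
    replace(M71_MC_LOW, name="M71-EA", n_sites=10, cells_per_site=35),
    fracs=(0.10, 0.15, 0.20), sds=(0.112, 0.12, 0.13),
    rels=(_M71_REL, _REL_MID, _REL_HIGH),
)

# Periglomerular imaging (3.4 x SD criterion). Control: 10.9% at low
# acetophenone, 10.8% at 0.1%.  Transgenic: 48% / 85.1 +- 13% / 94 +- 8%.
CTRL_PG = _series(
    GeneratorProfile(name="CTRL-PG", n_sites=10, cells_per_site=40,
                     cell_class="pg", genotype="control",
                     frac_responsive=0.109, frac_responsive_sd=0.066,
                     reliability_probs=_CTRL_REL, subthreshold_frac=0.35),
    fracs=(0.109, 0.108, 0.182), sds=(0.066, 0.066, 0.093),
    rels=(_CTRL_REL, _REL_MID, _REL_HIGH),
)
M71_PG = _series(
    GeneratorProfile(name="M71-PG", n_sites=9, cells_per_site=40,
                     cell_class="pg", genotype="m71",
                     frac_responsive=0.48, frac_responsive_sd=0.15,
                     reliability_probs=_REL_PG_LOW, subthreshold_frac=0.0,
                     amp_reliability_coupling=0.2,
                     amp_mean=0.22, amp_sd=0.12, dur_mean_s=5.0),
    fracs=(0.48, 0.851, 0.94), sds=(0.15, 0.13, 0.08),
    rels=(_REL_PG_LOW, _REL_PG_HIGH, _REL_PG_HIGH),
)

CTRL_MTC_AWAKE = EphysProfile(
    name="CTRL-MTC-AWAKE", genotype="control",
    baseline_fr_mean_hz=5.8, baseline_fr_sd_hz=6.2,    # 5.8 +- 6.2 Hz
    theta_amp_mv=0.4, theta_amp_sd_mv=0.4,             # 0.4 +- 0.4 mV
    dvm_mean_mv=-1.8, dvm_sd_mv=2.1,                   # -1.8 +- 2.1 mV (1 s)
    dvm5_mean_mv=-0.7, dvm5_sd_mv=0.5,                 # -0.7 +- 0.5 mV (5 s)
    dfr_mean_hz=2.2, dfr_sd_hz=13.3,                   # +2.2 +- 13.3 Hz
)

M71_MTC_AWAKE = EphysProfile(
    name="M71-MTC-AWAKE", genotype="m71",
    baseline_fr_mean_hz=3.0, baseline_fr_sd_hz=1.0,    # 3.0 +- 1.0 Hz
    theta_amp_mv=0.2, theta_amp_sd_mv=0.1,             # 0.2 +- 0.1 mV
    dvm_mean_mv=-1.0, dvm_sd_mv=1.0,                   # 1-s value not printed
    dvm5_mean_mv=-2.2, dvm5_sd_mv=1.9,                 # -2.2 +- 1.9 mV (5 s)
    dfr_mean_hz=-0.5, dfr_sd_hz=2.7,                   # -0.5 +- 2.7 Hz (acet.)
)

CTRL_SNIFF = SniffProfile(
    name="CTRL-SNIFF", genotype="control",
    response_1st_mean_hz=2.1, response_1st_sd_hz=1.6,  # 2.1 +- 1.6 Hz
    response_23_mean_hz=0.3, response_23_sd_hz=1.2,    # 0.3 +- 1.2 Hz
)

M71_SNIFF = SniffProfile(
    name="M71-SNIFF", genotype="m71",
    response_1st_mean_hz=2.7, response_1st_sd_hz=1.4,  # non-acet odors, 2.7 +- 1.4 Hz
    response_23_mean_hz=0.4, response_23_sd_hz=1.2,
)

IMAGING_PROFILES: dict[str, GeneratorProfile] = {
    p.name: p for p in (CTRL_MC_LOW, M71_MC_LOW)
}
IMAGING_SERIES: dict[str, dict[float, GeneratorProfile]] = {
    "M71-ACET": M71_ACET, "CTRL-ACET": CTRL_ACET,
    "CTRL-EA": CTRL_EA, "M71-EA": M71_EA,
    "CTRL-PG": CTRL_PG, "M71-PG": M71_PG,
}
EPHYS_PROFILES: dict[str, EphysProfile] = {
    p.name: p for p in (CTRL_MTC_AWAKE, M71_MTC_AWAKE)
}
SNIFF_PROFILES: dict[str, SniffProfile] = {
    p.name: p for p in (CTRL_SNIFF, M71_SNIFF)
}


def available_profiles() -> dict[str, list[str]]:
    return {
        "imaging": sorted(IMAGING_PROFILES),
        "imaging_series": sorted(IMAGING_SERIES),
        "ephys": sorted(EPHYS_PROFILES),
        "sniff": sorted(SNIFF_PROFILES),
    }


def parse_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key=value`` config file (``#`` comments allowed)."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line (expected key=value): {raw!r}")
        key, val = line.split("=", 1)
        out[key.strip()] = val.strip()
    return out


def apply_overrides(profile, overrides: dict[str, str]):
    """Return a profile copy with string overrides coerced to the field types."""
    kwargs = {}
    fields = {f.name: f for f in dataclasses.fields(profile)}
    for key, val in overrides.items():
        if key not in fields:
            raise KeyError(f"unknown profile field: {key}")
        current = getattr(profile, key)
        if isinstance(current, tuple):
            kwargs[key] = tuple(float(x) for x in val.split(","))
        elif isinstance(current, bool):
            kwargs[key] = val.lower() in ("1", "true", "yes")
        elif isinstance(current, int):
            kwargs[key] = int(val)
        elif isinstance(current, float):
            kwargs[key] = float(val)
        else:
            kwargs[key] = val
    return replace(profile, **kwargs)


def load_profile(name: str, kind: str = "imaging", config: str | Path | None = None):
    """Look up a named profile, optionally overridden from a config file."""
    registry = {
        "imaging": IMAGING_PROFILES,
        "ephys": EPHYS_PROFILES,
        "sniff": SNIFF_PROFILES,
    }[kind]
    if name not in registry:
        raise KeyError(
            f"unknown {kind} profile {name!r}; available: {sorted(registry)}")
    profile = registry[name]
    if config is not None:
        profile = apply_overrides(profile, parse_config(config))
    return profile
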