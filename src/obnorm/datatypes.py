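"""In-memory containers exchanged between the generator and the analyses."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TrialFluorescence:
    """One imaging trial: raw ROI fluorescence, cells x frames, plus timing.

    ``values[i, j]`` is the raw fluorescence (arbitrary units) of cell i at
    frame j; frame j covers time ``[j, j+1) / frame_rate_hz`` from trial
    start.  The pre-odor period runs from 0 to ``odor_onset_s``.
    """

    values: np.ndarray
    frame_rate_hz: float
    odor_onset_s: float
    odor_offset_s: float
    odor_label: str
    concentration: float
    trial_index: int
    site_id: str = ""
    cell_class: str = "mitral"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x frames array")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass
class DffTrial:
    """dF/F0 for one trial with the per-cell baseline statistics.

    ``f0`` is the per-cell median fluorescence in seconds [2, 6) of the
    pre-odor period; ``baseline_sd`` the SD of dF/F over the whole pre-odor
    period (the trial's baseline fluctuation, which sets the response
    threshold).
    """

    dff: np.ndarray
    f0: np.ndarray
    baseline_sd: np.ndarray
    frame_rate_hz: float
    odor_onset_s: float
    odor_offset_s: float
    odor_label: str
    concentration: float
    trial_index: int
    site_id: str = ""
    cell_class: str = "mitral"

    @property
    def n_cells(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]


@dataclass
class ImagingDataset:
    """A set of imaging trials sharing one cell population, with ground truth.

    ``ground_truth`` maps (cell, odor, trial) -> whether the generator made
    the cell emit a supra-threshold transient on that trial (the per-trial
    truth; its trial average is the quantity fraction_responsive estimates),
    and ``true_amplitude`` the corresponding peak dF/F (0 where inactive).
    """

    trials: list[TrialFluorescence]
    cell_ids: list[str]
    odor_labels: list[str]
    concentration_labels: list[float]
    ground_truth: np.ndarray | None = None
    true_amplitude: np.ndarray | None = None
    site_id: str = ""

    def __post_init__(self) -> None:
        if self.trials:
            n = self.trials[0].n_cells
            fr = self.trials[0].frame_rate_hz
            for t in self.trials:
                if t.n_cells != n or t.frame_rate_hz != fr:
                    raise ValueError("all trials must share cell count and frame rate")


@dataclass
class VmRecording:
    """Continuous whole-cell Vm with a respiration channel and valve events.

    ``odor_events`` is a list of ``(valve_open_s, valve_close_s, odor_label)``
    sorted and non-overlapping.  ``protocol`` is ``"awake"`` or
    ``"anesthetized"``.
    """

    vm: np.ndarray
    sniff_signal: np.ndarray
    sample_rate_hz: float
    odor_events: list[tuple[float, float, str]]
    protocol: str = "awake"
    cell_id: str = ""
    inhalation_times_s: np.ndarray | None = None  # generator ground truth

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        ev = sorted(self.odor_events)
        for (o1, c1, _), (o2, _, _) in zip(ev, ev[1:]):
            if c1 > o2:
                raise ValueError("odor events must be non-overlapping")
        self.odor_events = ev

    @property
    def duration_s(self) -> float:
        return self.vm.size / self.sample_rate_hz

    def times(self) -> np.ndarray:
        return np.arange(self.vm.size) / self.sample_rate_hz


@dataclass
class SpikeClippedVm:
    """Vm with spike intervals replaced by linear interpolation."""

    vm_clipped: np.ndarray
    spike_times_s: np.ndarray
    sample_rate_hz: float


@dataclass
class SniffSession:
    """Inhalation-peak event times plus the odor presentation schedule.

    ``presentations`` is a list of
    ``(odor_label, onset_s, offset_s, presentation_index)`` where the index
    counts presentations of that odor within the session (1-based).
    """

    inhalation_times_s: np.ndarray
    presentations: list[tuple[str, float, float, int]]
    session_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.inhalation_times_s, dtype=float)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("inhalation times must be strictly increasing")
        self.inhalation_times_s = t


@dataclass
class GoNoGoLog:
    """Ordered go/no-go trials: stimulus class (S+ / S-) and lick outcome."""

    stimulus_class: list[str]
    licked: list[bool]
    block_size: int = 20

    def __post_init__(self) -> None:
        if len(self.stimulus_class) != len(self.licked):
            raise ValueError("stimulus_class and licked must have equal length")
        bad = set(self.stimulus_class) - {"S+", "S-"}
        if bad:
            raise ValueError(f"unknown stimulus classes: {bad}")

    @property
    def n_trials(self) -> int:
        return len(self.licked)


@dataclass
class ThetaCoupling:
    """Sniff-cycle modulation of baseline Vm: strength (mV) and phase (rad)."""

    strength_mv: float
    phase_rad: float
    n_cycles: int
    low_confidence: bool = False


@dataclass
class EvokedResponse:
    """Odor-evoked Vm / firing-rate summary for one cell-odor pair."""

    cell_id: str
    odor: str
    dvm_1s_mv: float
    dvm_2s_mv: float
    dvm_5s_mv: float
    dfr_hz: float
    significant_vm: str = "none"  # hyperpolarizing | depolarizing | none
    significant_fr: bool = False
    fr_p_value: float | None = None


@dataclass
class SniffResponse:
    """Sniff-frequency response to one odor presentation."""

    odor: str
    presentation_index: int
    baseline_freq_hz: float
    odor_freq_hz: float
    session_id: str = ""

    @property
    def response_hz(self) -> float:
        return self.odor_freq_hz - self.baseline_freq_hz


@dataclass
class SiteSummary:
    """Per (site, odor, concentration) responsive fraction."""

    site_id: str
    genotype: str
    odor: str
    concentration: float
    frac_responsive: float
    n_cells: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_responsive <= 1.0:
            raise ValueError("frac_responsive must lie in [0, 1]")


@dataclass
class ConcentrationSeriesResult:
    """Linear-change (LC) regression of responsive fraction on log10 dilution."""

    lc_test: float
    lc_reference: float
    delta_lc: float
    pearson_r_test: float
    points: "object" = field(default=None)  # pandas DataFrame (site, odor, conc, frac)
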