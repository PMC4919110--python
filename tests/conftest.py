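import warnings

import numpy as np
import pytest

from obnorm.datatypes import DffTrial, TrialFluorescence


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trial(values, frame_rate_hz=2.53, odor_onset_s=20.0,
               odor_offset_s=22.0, odor="odorA", conc=1e-4, trial=0,
               site="site00", cell_class="mitral"):
    return TrialFluorescence(values=np.asarray(values, dtype=float),
                             frame_rate_hz=frame_rate_hz,
                             odor_onset_s=odor_onset_s,
                             odor_offset_s=odor_offset_s,
                             odor_label=odor, concentration=conc,
                             trial_index=trial, site_id=site,
                             cell_class=cell_class)


def make_dff(dff, baseline_sd, frame_rate_hz=2.53, odor_onset_s=20.0,
             odor="odorA", conc=1e-4, trial=0, site="site00"):
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    sd = np.broadcast_to(np.asarray(baseline_sd, dtype=float),
                         (dff.shape[0],)).copy()
    return DffTrial(dff=dff, f0=np.full(dff.shape[0], 100.0), baseline_sd=sd,
                    frame_rate_hz=frame_rate_hz, odor_onset_s=odor_onset_s,
                    odor_offset_s=odor_onset_s + 2.0, odor_label=odor,
                    concentration=conc, trial_index=trial, site_id=site)
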