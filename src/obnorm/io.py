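"""Serialization: HDF5 array containers and TSV tables.

Imaging trials are stored as one dataset per trial (``trial000`` ...) with
timing attributes and a TSV-style manifest; Vm recordings as ``vm`` /
``sniff`` datasets plus an event table.  Tables travel as tab-separated
text with a header line.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import ImagingDataset, SiteSummary, TrialFluorescence, VmRecording


def save_imaging(dataset: ImagingDataset, path: str | Path) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["site_id"] = dataset.site_id
        h5.attrs["cell_ids"] = [c.encode() for c in dataset.cell_ids]
        for i, trial in enumerate(dataset.trials):
            d = h5.create_dataset(f"trial{i:03d}", data=trial.values)
            d.attrs["frame_rate_hz"] = trial.frame_rate_hz
            d.attrs["odor_onset_s"] = trial.odor_onset_s
            d.attrs["odor_offset_s"] = trial.odor_offset_s
            d.attrs["odor_label"] = trial.odor_label
            d.attrs["concentration"] = trial.concentration
            d.attrs["trial_index"] = trial.trial_index
            d.attrs["cell_class"] = trial.cell_class
        if dataset.ground_truth is not None:
            h5.create_dataset("ground_truth", data=dataset.ground_truth)
            h5.create_dataset("true_amplitude", data=dataset.true_amplitude)
            h5.attrs["stim_odors"] = [o.encode() for o in dataset.odor_labels]
            h5.attrs["stim_concs"] = dataset.concentration_labels


def load_imaging(path: str | Path) -> ImagingDataset:
    trials = []
    with h5py.File(path, "r") as h5:
        site_id = str(h5.attrs.get("site_id", ""))
        cell_ids = [c.decode() if isinstance(c, bytes) else str(c)
                    for c in h5.attrs.get("cell_ids", [])]
        names = sorted(k for k in h5 if k.startswith("trial"))
        for name in names:
            d = h5[name]
            trials.append(TrialFluorescence(
                values=d[()], frame_rate_hz=float(d.attrs["frame_rate_hz"]),
                odor_onset_s=float(d.attrs["odor_onset_s"]),
                odor_offset_s=float(d.attrs["odor_offset_s"]),
                odor_label=str(d.attrs["odor_label"]),
                concentration=float(d.attrs["concentration"]),
                trial_index=int(d.attrs["trial_index"]),
                site_id=site_id, cell_class=str(d.attrs.get("cell_class", "mitral"))))
        gt = h5["ground_truth"][()] if "ground_truth" in h5 else None
        amp = h5["true_amplitude"][()] if "true_amplitude" in h5 else None
        odors = [o.decode() if isinstance(o, bytes) else str(o)
                 for o in h5.attrs.get("stim_odors", [])]
        concs = list(h5.attrs.get("stim_concs", []))
    return ImagingDataset(trials=trials, cell_ids=cell_ids,
                          odor_labels=odors, concentration_labels=concs,
                          ground_truth=gt, true_amplitude=amp, site_id=site_id)


def save_vm(rec: VmRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("vm", data=rec.vm)
        h5.create_dataset("sniff", data=rec.sniff_signal)
        h5.attrs["sample_rate_hz"] = rec.sample_rate_hz
        h5.attrs["protocol"] = rec.protocol
        h5.attrs["cell_id"] = rec.cell_id
        ev = np.array([(o, c, lab.encode()) for o, c, lab in rec.odor_events],
                      dtype=[("open_s", "f8"), ("close_s", "f8"), ("odor", "S64")])
        h5.create_dataset("events", data=ev)
        if rec.inhalation_times_s is not None:
            h5.create_dataset("inhalations", data=rec.inhalation_times_s)


def load_vm(path: str | Path) -> VmRecording:
    with h5py.File(path, "r") as h5:
        events = [(float(e["open_s"]), float(e["close_s"]),
                   e["odor"].decode()) for e in h5["events"][()]]
        inh = h5["inhalations"][()] if "inhalations" in h5 else None
        return VmRecording(
            vm=h5["vm"][()], sniff_signal=h5["sniff"][()],
            sample_rate_hz=float(h5.attrs["sample_rate_hz"]),
            odor_events=events, protocol=str(h5.attrs["protocol"]),
            cell_id=str(h5.attrs["cell_id"]), inhalation_times_s=inh)


def summaries_to_frame(summaries: list[SiteSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "site_id": s.site_id, "genotype": s.genotype, "odor": s.odor,
        "concentration": s.concentration,
        "frac_responsive": s.frac_responsive, "n_cells": s.n_cells,
    } for s in summaries])


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
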