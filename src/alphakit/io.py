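"""Tidy-CSV and HDF5 export of stimuli, recordings and spectra."""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from .spectral import PowerSpectrum
from .stimgen import TrialSpec
from .synth_eeg import Montage, Recording, SubjectParams

__all__ = ["trials_to_csv", "spectrum_to_csv", "save_recording", "load_recording"]


def trials_to_csv(trials: list[TrialSpec], path) -> None:
    """Write FM/CMF timecourses as tidy CSV:
    trial, side, frame, time_s, freq_hz, luminance_cdm2."""
    frames = []
    for j, tr in enumerate(trials):
        for side, fm, cmf in (("left", tr.fm_left, tr.cmf_left),
                              ("right", tr.fm_right, tr.cmf_right)):
            frames.append(pd.DataFrame({
                "trial": j, "side": side, "frame": np.arange(len(fm)),
                "time_s": fm.t, "freq_hz": fm.f,
                "luminance_cdm2": cmf.luminance}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def spectrum_to_csv(ps: PowerSpectrum, path) -> None:
    """Write a power spectrum as tidy CSV: channel, freq_hz, power, scale."""
    n_ch, n_f = ps.values.shape
    pd.DataFrame({
        "channel": np.repeat(ps.channels, n_f),
        "freq_hz": np.tile(ps.freqs, n_ch),
        "power": ps.values.ravel(),
        "scale": ps.scale,
    }).to_csv(path, index=False)


def save_recording(rec: Recording, path) -> None:
    """Store a recording in HDF5 with a ground-truth parameter sidecar."""
    import h5py
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=rec.data, compression="gzip")
        fh.attrs["fs"] = rec.fs
        fh.attrs["segment_kind"] = rec.segment_kind
        fh.create_dataset("pos", data=rec.montage.pos)
        fh.attrs["labels"] = json.dumps(rec.montage.labels)
        fh.attrs["left_cluster"] = json.dumps(rec.montage.left_cluster)
        fh.attrs["right_cluster"] = json.dumps(rec.montage.right_cluster)
        fh.create_dataset("trial_onsets",
                          data=np.array([t.onset_sample for t in rec.trials]))
        if rec.subject is not None:
            fh.attrs["subject"] = json.dumps(asdict(rec.subject))


def load_recording(path) -> Recording:
    """Load a recording saved by :func:`save_recording` (trial specs are not
    round-tripped, only their onsets)."""
    import h5py
    with h5py.File(path, "r") as fh:
        montage = Montage(labels=json.loads(fh.attrs["labels"]),
                          pos=fh["pos"][()],
                          left_cluster=json.loads(fh.attrs["left_cluster"]),
                          right_cluster=json.loads(fh.attrs["right_cluster"]))
        subject = None
        if "subject" in fh.attrs:
            subject = SubjectParams(**json.loads(fh.attrs["subject"]))
        rec = Recording(data=fh["data"][()], fs=float(fh.attrs["fs"]),
                        montage=montage, trials=[], subject=subject,
                        segment_kind=str(fh.attrs["segment_kind"]))
    return rec
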