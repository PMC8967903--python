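"""HDF5 persistence for session bundles and trial matrices.

Arrays live as datasets; scalar metadata rides along as a JSON attribute
so files remain self-describing.  The stimulus table can also be exported
as CSV.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import GroundTruth, SessionBundle, TrialMatrix

__all__ = [
    "save_session",
    "load_session",
    "save_trials",
    "load_trials",
    "export_stim_table_csv",
]

_STIM_COLS = ["epoch_type", "start_frame", "end_frame", "direction", "temporal_frequency"]


def save_session(bundle: SessionBundle, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("dff", data=bundle.dff)
        f.create_dataset("speed", data=bundle.speed)
        f.create_dataset("pupil", data=bundle.pupil)
        if bundle.raw is not None:
            f.create_dataset("raw", data=bundle.raw)
        g = f.create_group("stim_table")
        t = bundle.stim_table
        g.create_dataset("epoch_type", data=t["epoch_type"].astype("S"))
        for col in _STIM_COLS[1:]:
            g.create_dataset(col, data=t[col].to_numpy(dtype=float))
        f.attrs["meta"] = json.dumps(
            {
                "frame_rate": bundle.frame_rate,
                "region": bundle.region,
                "layer": bundle.layer,
                "session_id": bundle.session_id,
            }
        )
        if bundle.truth is not None:
            gt = f.create_group("truth")
            gt.create_dataset("neuron_class", data=bundle.truth.neuron_class.astype("S"))
            for name in (
                "speed_gain",
                "bump_center",
                "bump_width",
                "pref_direction",
                "dir_kappa",
                "dir_amp",
                "stim_offset",
                "noise_sd_running",
                "noise_sd_stationary",
            ):
                gt.create_dataset(name, data=np.asarray(getattr(bundle.truth, name), dtype=float))
            gt.attrs["shared_gain_sd"] = bundle.truth.shared_gain_sd
            gt.attrs["seed"] = bundle.truth.seed


def load_session(path: str | Path) -> SessionBundle:
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        g = f["stim_table"]
        stim_table = pd.DataFrame(
            {
                "epoch_type": [s.decode() for s in g["epoch_type"][()]],
                **{col: g[col][()] for col in _STIM_COLS[1:]},
            }
        )
        stim_table["start_frame"] = stim_table["start_frame"].astype(int)
        stim_table["end_frame"] = stim_table["end_frame"].astype(int)
        truth = None
        if "truth" in f:
            gt = f["truth"]
            truth = GroundTruth(
                neuron_class=np.array([s.decode() for s in gt["neuron_class"][()]]),
                speed_gain=gt["speed_gain"][()],
                bump_center=gt["bump_center"][()],
                bump_width=gt["bump_width"][()],
                pref_direction=gt["pref_direction"][()],
                dir_kappa=gt["dir_kappa"][()],
                dir_amp=gt["dir_amp"][()],
                stim_offset=gt["stim_offset"][()],
                noise_sd_running=gt["noise_sd_running"][()],
                noise_sd_stationary=gt["noise_sd_stationary"][()],
                shared_gain_sd=float(gt.attrs["shared_gain_sd"]),
                seed=int(gt.attrs["seed"]),
            )
        return SessionBundle(
            dff=f["dff"][()],
            speed=f["speed"][()],
            pupil=f["pupil"][()],
            stim_table=stim_table,
            raw=f["raw"][()] if "raw" in f else None,
            truth=truth,
            **meta,
        )


def export_stim_table_csv(bundle: SessionBundle, path: str | Path) -> None:
    bundle.stim_table[_STIM_COLS].to_csv(path, index=False)


def save_trials(tm: TrialMatrix, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("responses", data=tm.responses)
        f.create_dataset("class_label", data=np.asarray(tm.class_label, dtype=float))
        f.create_dataset("state", data=np.asarray(tm.state).astype("S"))
        f.create_dataset("neuron_ids", data=np.asarray(tm.neuron_ids, dtype=int))
        f.attrs["meta"] = json.dumps(
            {
                "window_s": tm.window_s,
                "offset_frames": tm.offset_frames,
                "source_session": tm.source_session,
            }
        )


def load_trials(path: str | Path) -> TrialMatrix:
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        return TrialMatrix(
            responses=f["responses"][()],
            class_label=f["class_label"][()],
            state=np.array([s.decode() for s in f["state"][()]]),
            neuron_ids=f["neuron_ids"][()],
            **meta,
        )
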