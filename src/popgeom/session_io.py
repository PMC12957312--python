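"""Session container: one HDF5 file per session.

Layout: ``/spike_counts`` (M × N × T int64), ``/trial_table`` (the
delimited trial table as a UTF-8 CSV string: trial_id, task, stimulus,
decision, outcome, grip_t, stim_on_t, go_t, release_t, touch_t) and a
JSON metadata attribute (bin_ms, epoch, seed, format version).  Ground
truth from the simulator goes to a JSON sidecar next to the container.
"""

from __future__ import annotations

import io
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .simulate import GroundTruth, SessionData

__all__ = ["write_session", "read_session", "write_ground_truth",
           "read_ground_truth"]

FORMAT_VERSION = 1

_EVENT_COLS = {"grip": "grip_t", "stimulus_on": "stim_on_t", "go_cue": "go_t",
               "release": "release_t", "touch": "touch_t"}


def _trial_table(session: SessionData) -> pd.DataFrame:
    df = pd.DataFrame({
        "trial_id": np.arange(session.n_trials),
        "task": session.task_label,
        "stimulus": session.stimulus_label,
        "decision": session.decision_label,
        "outcome": session.outcome,
    })
    for ev, col in _EVENT_COLS.items():
        df[col] = session.event_times[ev]
    return df


def write_session(session: SessionData, path) -> None:
    """Write a session container (lossless round trip)."""
    path = Path(path)
    table = _trial_table(session).to_csv(index=False)
    meta = {
        "format_version": FORMAT_VERSION,
        "bin_ms": session.bin_ms,
        "n_trials": session.n_trials,
        "n_units": session.n_units,
        "n_bins": session.n_bins,
        "unit_ids": [f"u{i:03d}" for i in range(session.n_units)],
        **{k: v for k, v in session.meta.items()
           if isinstance(v, (int, float, str, list, bool))},
    }
    with h5py.File(path, "w") as f:
        f.create_dataset("spike_counts", data=session.spike_counts,
                         dtype=np.int64)
        f.create_dataset("trial_table", data=table)
        f.attrs["metadata"] = json.dumps(meta)


def read_session(path) -> SessionData:
    """Read a session container, validating the schema."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "spike_counts" not in f or "trial_table" not in f:
            raise ValueError(f"{path} is not a session container")
        counts = f["spike_counts"][()]
        table_csv = f["trial_table"][()]
        if isinstance(table_csv, bytes):
            table_csv = table_csv.decode("utf-8")
        meta = json.loads(f.attrs.get("metadata", "{}"))
    if "format_version" not in meta:
        raise ValueError(f"{path}: metadata lacks format_version")
    df = pd.read_csv(io.StringIO(table_csv))
    if len(df) != counts.shape[0]:
        raise ValueError(
            f"trial table has {len(df)} rows but spike tensor has "
            f"{counts.shape[0]} trials")
    return SessionData(
        spike_counts=counts,
        task_label=df["task"].to_numpy(dtype=str),
        stimulus_label=df["stimulus"].to_numpy(dtype=str),
        decision_label=df["decision"].to_numpy(dtype=str),
        outcome=df["outcome"].to_numpy(dtype=np.int64),
        event_times={ev: df[col].to_numpy(dtype=float)
                     for ev, col in _EVENT_COLS.items()},
        bin_ms=float(meta.get("bin_ms", 10.0)),
        meta=meta,
    )


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Serialize simulator ground truth to a JSON sidecar."""
    doc = {
        "realized_angle_deg": truth.realized_angle_deg,
        "realized_reuse": truth.realized_reuse,
        "decision_axes": {k: v.tolist() for k, v in truth.decision_axes.items()},
        "stimulus_axes": {k: v.tolist() for k, v in truth.stimulus_axes.items()},
        "loading_matrix": truth.loading_matrix.tolist(),
        "latent_time_courses": {k: v.tolist()
                                for k, v in truth.latent_time_courses.items()},
    }
    Path(path).write_text(json.dumps(doc))


def read_ground_truth(path) -> GroundTruth:
    doc = json.loads(Path(path).read_text())
    return GroundTruth(
        decision_axes={k: np.asarray(v) for k, v in doc["decision_axes"].items()},
        stimulus_axes={k: np.asarray(v) for k, v in doc["stimulus_axes"].items()},
        loading_matrix=np.asarray(doc["loading_matrix"]),
        realized_angle_deg=doc["realized_angle_deg"],
        realized_reuse=doc["realized_reuse"],
        latent_time_courses={k: np.asarray(v)
                             for k, v in doc["latent_time_courses"].items()},
    )
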