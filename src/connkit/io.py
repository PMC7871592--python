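"""HDF5 dataset layout, TOML scenario configs and CSV manifests.

Layout (one HDF5 group per subject)::

    /<subject>/lfp            channels x samples float array
    /<subject>/rate           scalar sampling rate (Hz)
    /<subject>/labels         channel region labels (utf-8)
    /<subject>/reference      reference label attribute
    /<subject>/spikes/<chan>  spike times (s) per spike channel
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .recording import MultiChannelRecording
from .synthetic import CouplingBlock, ScenarioSpec

__all__ = [
    "write_recording",
    "read_recording",
    "write_dataset",
    "read_dataset",
    "write_manifest",
    "load_scenario_toml",
]


def write_recording(grp: h5py.Group, rec: MultiChannelRecording, spikes: dict | None = None):
    grp.create_dataset("lfp", data=rec.data)
    grp.create_dataset("rate", data=float(rec.rate_hz))
    grp.create_dataset("labels", data=np.array(rec.labels, dtype=h5py.string_dtype()))
    grp.attrs["reference"] = rec.reference
    if spikes:
        sg = grp.create_group("spikes")
        for chan, times in spikes.items():
            sg.create_dataset(chan, data=np.asarray(times, dtype=float))


def read_recording(grp: h5py.Group):
    rec = MultiChannelRecording(
        data=grp["lfp"][()],
        rate_hz=float(grp["rate"][()]),
        labels=[s.decode() if isinstance(s, bytes) else s for s in grp["labels"][()]],
        reference=grp.attrs.get("reference", "ground"),
    )
    spikes = {}
    if "spikes" in grp:
        for chan in grp["spikes"]:
            spikes[chan] = grp["spikes"][chan][()]
    return rec, spikes


def write_dataset(path, recordings, subjects=None, spikes_per_subject=None):
    """Write a list of recordings, one HDF5 group per subject."""
    path = Path(path)
    subjects = subjects or [f"sub{i:03d}" for i in range(len(recordings))]
    with h5py.File(path, "w") as f:
        for name, rec in zip(subjects, recordings):
            sp = (spikes_per_subject or {}).get(name)
            write_recording(f.create_group(name), rec, sp)
    return subjects


def read_dataset(path):
    """Read a dataset written by :func:`write_dataset`."""
    out = {}
    with h5py.File(path, "r") as f:
        for name in f:
            out[name] = read_recording(f[name])
    return out


def write_manifest(path, subjects, groups, seeds):
    df = pd.DataFrame({"subject": subjects, "group": groups, "seed": seeds})
    df.to_csv(path, index=False)
    return df


def load_scenario_toml(path) -> ScenarioSpec:
    """Parse a TOML scenario config into a :class:`ScenarioSpec`.

    Expected shape::

        duration_s = 60.0
        rate_hz = 250.0
        regions = ["PFC", "dHC"]
        seed = 1
        [[blocks]]
        kind = "phase_lag"
        [blocks.params]
        f_hz = 8.0
        lag_deg = 90.0
        snr = 10.0
    """
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    blocks = [CouplingBlock(kind=b["kind"], params=b.get("params", {})) for b in cfg.get("blocks", [])]
    return ScenarioSpec(
        duration_s=float(cfg["duration_s"]),
        rate_hz=float(cfg["rate_hz"]),
        regions=cfg.get("regions", []),
        seed=int(cfg.get("seed", 0)),
        blocks=blocks,
    )
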