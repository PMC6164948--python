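"""Readers and writers: recordings (CSV, optional SNIRF/HDF5), designs,
layouts, unbalance reports, and run manifests.

CSV is the primary interchange format: one row per sample, one column per
channel (CH1..CH40), a `# fs=<Hz>` comment header, full float precision.
All writers are deterministic (stable column order, repr-exact floats).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .probe import ProbeLayout, read_layout, write_layout  # noqa: F401 (re-export)
from .synth import BlockDesign
from .unbalance import UnbalanceReport

__all__ = [
    "Recording",
    "read_recording",
    "write_recording",
    "read_design",
    "write_design",
    "read_layout",
    "write_layout",
    "write_report",
    "write_snirf",
    "read_snirf",
]


@dataclass
class Recording:
    """Channels x L matrix with sampling rate and channel ids."""

    data: np.ndarray
    fs: float
    channel_ids: list[int]
    metadata: dict


def write_recording(path, data: np.ndarray, fs: float, channel_ids, metadata: dict | None = None) -> None:
    data = np.asarray(data, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"# fs={fs!r}\n")
        for k, v in sorted((metadata or {}).items()):
            fh.write(f"# {k}={json.dumps(v)}\n")
        fh.write(",".join(f"CH{c}" for c in channel_ids) + "\n")
        for row in data.T:  # rows = samples
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def read_recording(path, layout: ProbeLayout | None = None) -> Recording:
    """Read a CSV recording; validates channel count against `layout` if given."""
    fs = None
    metadata: dict = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "fs":
                fs = float(val)
            else:
                try:
                    metadata[key.strip()] = json.loads(val)
                except json.JSONDecodeError:
                    metadata[key.strip()] = val
    if fs is None:
        raise ValueError(f"{path}: missing '# fs=' header")
    df = pd.read_csv(path, skiprows=header_lines, float_precision="round_trip")
    bad = df.columns[~df.columns.str.fullmatch(r"CH\d+")]
    if len(bad):
        raise ValueError(f"{path}: malformed channel columns {list(bad)}")
    non_numeric = df.apply(pd.to_numeric, errors="coerce")
    if non_numeric.isna().any().any():
        r, c = np.argwhere(non_numeric.isna().values)[0]
        raise ValueError(
            f"{path}: non-numeric cell at data row {r + 1}, column {df.columns[c]}"
        )
    channel_ids = [int(c[2:]) for c in df.columns]
    if layout is not None and channel_ids != layout.channel_ids:
        raise ValueError(f"{path}: channels do not match the supplied layout")
    return Recording(non_numeric.values.T.astype(float), fs, channel_ids, metadata)


def write_design(design: BlockDesign, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "fs": design.fs,
                "pre_rest_s": design.pre_rest_s,
                "task_s": design.task_s,
                "post_rest_s": design.post_rest_s,
                "n_blocks": design.n_blocks,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")


def read_design(path, strict: bool = False) -> BlockDesign:
    """JSON block design; missing optional fields take the 20/20/20 defaults."""
    with open(path) as fh:
        d = json.load(fh)
    known = {"fs", "pre_rest_s", "task_s", "post_rest_s", "n_blocks"}
    if strict:
        unknown = d.keys() - known
        if unknown:
            raise ValueError(f"design file {path}: unknown keys {sorted(unknown)}")
    return BlockDesign(**{k: d[k] for k in known & d.keys()})


def write_report(report: UnbalanceReport, channel_csv, optode_csv, summary_json=None,
                 identified=None) -> None:
    """Tidy CSVs: (channel, gamma_T, gamma_R, UD) and (optode, UI)."""
    with open(channel_csv, "w") as fh:
        fh.write("channel,gamma_T,gamma_R,UD\n")
        for ch in sorted(report.ud):
            g_t, g_r = report.gamma[ch]
            fh.write(f"{ch},{g_t!r},{g_r!r},{report.ud[ch]!r}\n")
    with open(optode_csv, "w") as fh:
        fh.write("optode,UI\n")
        for o in sorted(report.ui, key=lambda s: (s[0], int(s[1:]))):
            fh.write(f"{o},{report.ui[o]!r}\n")
    if summary_json is not None and identified is not None:
        with open(summary_json, "w") as fh:
            json.dump(
                {
                    "r_optode": identified.r_optode,
                    "channel": identified.channel,
                    "t_optode": identified.t_optode,
                    "contaminated": identified.contaminated,
                    "ui_max": identified.ui_max,
                },
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")


# -- optional SNIRF-style HDF5 export --------------------------------------


def write_snirf(path, data: np.ndarray, fs: float, channel_ids) -> None:
    """Minimal SNIRF-shaped HDF5 export (/nirs/data1) of an HbO matrix."""
    import h5py

    data = np.asarray(data, dtype=float)
    t = np.arange(data.shape[1]) / fs
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=np.bytes_("1.0"))
        g = f.create_group("nirs/data1")
        g.create_dataset("dataTimeSeries", data=data.T)
        g.create_dataset("time", data=t)
        g.create_dataset("channelIds", data=np.asarray(channel_ids, dtype=np.int64))


def read_snirf(path) -> Recording:
    import h5py

    with h5py.File(path, "r") as f:
        g = f["nirs/data1"]
        data = np.asarray(g["dataTimeSeries"]).T
        t = np.asarray(g["time"])
        ids = [int(i) for i in np.asarray(g["channelIds"])]
    fs = 1.0 / float(t[1] - t[0]) if t.size > 1 else 0.0
    return Recording(data, fs, ids, {})
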