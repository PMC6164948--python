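"""Optode grid and channel topology for nearest-neighbor fNIRS montages.

A continuous-wave fNIRS probe is a grid of transmitter (T, light source)
and receiver (R, detector) optodes; every horizontally or vertically
adjacent T-R pair forms a measurement channel.  The canonical montage used
throughout this package is a 5x5 alternating grid (13 T, 12 R optodes,
40 channels at 3 cm separation) covering the motor and sensory cortices.

Channels sharing an optode are called *neighbor channels*: each channel has
a T-side neighbor set (other channels of its T-optode) and an R-side set.
A motion artifact at one optode contaminates exactly the channels incident
to that optode, which is what the unbalance detector exploits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

__all__ = [
    "Optode",
    "Channel",
    "ProbeLayout",
    "build_layout",
    "default_layout",
    "read_layout",
    "write_layout",
]


@dataclass(frozen=True)
class Optode:
    id: str
    row: int  # 1-based grid row
    col: int  # 1-based grid column
    kind: str  # "T" or "R"


@dataclass(frozen=True)
class Channel:
    id: int
    optode_a: str
    optode_b: str


@dataclass
class ProbeLayout:
    """Optode grid with channel incidence and neighbor queries.

    Attributes
    ----------
    grid_rows, grid_cols : int
        Grid dimensions (optode positions).
    optodes : list of Optode
    channels : list of Channel
        Each channel joins one T- and one R-optode that are grid-adjacent.
    spacing_cm : float
        Optode separation; 3.0 cm for the canonical montage.
    """

    grid_rows: int
    grid_cols: int
    optodes: list[Optode]
    channels: list[Channel]
    spacing_cm: float = 3.0
    _opt_by_id: dict[str, Optode] = field(init=False, repr=False)
    _chan_by_id: dict[int, Channel] = field(init=False, repr=False)
    _incidence: dict[str, set[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._opt_by_id = {o.id: o for o in self.optodes}
        self._chan_by_id = {c.id: c for c in self.channels}
        self._incidence = {o.id: set() for o in self.optodes}
        for c in self.channels:
            for oid in (c.optode_a, c.optode_b):
                if oid not in self._opt_by_id:
                    raise ValueError(f"channel CH{c.id} references unknown optode {oid!r}")
                self._incidence[oid].add(c.id)

    # -- queries ----------------------------------------------------------

    @property
    def channel_ids(self) -> list[int]:
        return [c.id for c in self.channels]

    @property
    def t_optodes(self) -> list[str]:
        return [o.id for o in self.optodes if o.kind == "T"]

    @property
    def r_optodes(self) -> list[str]:
        return [o.id for o in self.optodes if o.kind == "R"]

    def optode(self, optode_id: str) -> Optode:
        try:
            return self._opt_by_id[optode_id]
        except KeyError:
            raise KeyError(f"unknown optode {optode_id!r}") from None

    def neighbor_channels(self, optode_id: str, exclude: int | None = None) -> set[int]:
        """Channels incident to `optode_id`, optionally minus one channel.

        These are the "neighbor channels" of the montage: all channels
        measured through the given optode.
        """
        if optode_id not in self._incidence:
            raise KeyError(f"unknown optode {optode_id!r}")
        chans = set(self._incidence[optode_id])
        if exclude is not None:
            chans.discard(exclude)
        return chans

    def optodes_of_channel(self, channel_id: int) -> tuple[str, str]:
        """Return the (T-optode, R-optode) pair measuring this channel."""
        try:
            ch = self._chan_by_id[channel_id]
        except KeyError:
            raise KeyError(f"unknown channel {channel_id!r}") from None
        a, b = self._opt_by_id[ch.optode_a], self._opt_by_id[ch.optode_b]
        if a.kind == "T":
            return a.id, b.id
        return b.id, a.id

    def validate(self) -> None:
        """Check the structural invariants of a T/R nearest-neighbor montage."""
        for ch in self.channels:
            kinds = {self._opt_by_id[ch.optode_a].kind, self._opt_by_id[ch.optode_b].kind}
            if kinds != {"T", "R"}:
                raise ValueError(f"CH{ch.id} does not join one T- and one R-optode")
        degree_sum = sum(len(v) for v in self._incidence.values())
        if degree_sum != 2 * len(self.channels):
            raise ValueError("incidence degrees do not sum to twice the channel count")


def build_layout(rows: int, cols: int, spacing_cm: float = 3.0) -> ProbeLayout:
    """Build the canonical alternating T/R grid layout.

    Optodes are placed row-major with T at (1,1) and alternating kind, so a
    position (r, c) holds a T-optode iff (r + c) is even.  T-optodes are
    numbered T1, T2, ... row-major over T positions, R-optodes likewise.
    Channels are numbered row-major, alternating between each row's
    horizontal links (left to right) and the following inter-row gap's
    vertical links (left to right).

    For the 5x5 grid this yields the standard 40-channel montage in which,
    e.g., optode R2 measures channels 3, 4 and 8, and CH20 joins T7 and R6.
    """
    if rows < 2 or cols < 2:
        raise ValueError("grid must be at least 2x2")
    optodes: list[Optode] = []
    pos_to_id: dict[tuple[int, int], str] = {}
    n_t = n_r = 0
    for r in range(1, rows + 1):
        for c in range(1, cols + 1):
            if (r + c) % 2 == 0:
                n_t += 1
                oid = f"T{n_t}"
                kind = "T"
            else:
                n_r += 1
                oid = f"R{n_r}"
                kind = "R"
            optodes.append(Optode(oid, r, c, kind))
            pos_to_id[(r, c)] = oid
    channels: list[Channel] = []
    cid = 0
    for r in range(1, rows + 1):
        for c in range(1, cols):  # horizontal links of row r
            cid += 1
            channels.append(Channel(cid, pos_to_id[(r, c)], pos_to_id[(r, c + 1)]))
        if r < rows:  # vertical links of the gap between rows r and r+1
            for c in range(1, cols + 1):
                cid += 1
                channels.append(Channel(cid, pos_to_id[(r, c)], pos_to_id[(r + 1, c)]))
    layout = ProbeLayout(rows, cols, optodes, channels, spacing_cm)
    layout.validate()
    return layout


def default_layout() -> ProbeLayout:
    """The packaged 5x5 / 40-channel montage (read from the bundled file)."""
    with resources.files("fnirs_macorr.data").joinpath("layout_5x5.json").open() as fh:
        return _layout_from_dict(json.load(fh))


def _layout_from_dict(d: dict) -> ProbeLayout:
    optodes = [Optode(o["id"], o["row"], o["col"], o["kind"]) for o in d["optodes"]]
    channels = [Channel(int(c["id"]), c["optode_a"], c["optode_b"]) for c in d["channels"]]
    layout = ProbeLayout(
        int(d["grid_rows"]), int(d["grid_cols"]), optodes, channels,
        float(d.get("spacing_cm", 3.0)),
    )
    layout.validate()
    return layout


def _layout_to_dict(layout: ProbeLayout) -> dict:
    return {
        "grid_rows": layout.grid_rows,
        "grid_cols": layout.grid_cols,
        "spacing_cm": layout.spacing_cm,
        "optodes": [
            {"id": o.id, "row": o.row, "col": o.col, "kind": o.kind} for o in layout.optodes
        ],
        "channels": [
            {"id": c.id, "optode_a": c.optode_a, "optode_b": c.optode_b}
            for c in layout.channels
        ],
    }


def read_layout(path, strict: bool = False) -> ProbeLayout:
    """Read a layout from a JSON file; see `write_layout` for the schema."""
    with open(path) as fh:
        d = json.load(fh)
    required = {"grid_rows", "grid_cols", "optodes", "channels"}
    missing = required - d.keys()
    if missing:
        raise ValueError(f"layout file {path}: missing keys {sorted(missing)}")
    if strict:
        unknown = d.keys() - (required | {"spacing_cm"})
        if unknown:
            raise ValueError(f"layout file {path}: unknown keys {sorted(unknown)}")
    return _layout_from_dict(d)


def write_layout(layout: ProbeLayout, path) -> None:
    with open(path, "w") as fh:
        json.dump(_layout_to_dict(layout), fh, indent=1, sort_keys=True)
        fh.write("\n")
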