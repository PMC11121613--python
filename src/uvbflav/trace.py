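"""Container and I/O for time-resolved chlorophyll fluorescence transients."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FluorTrace:
    """One fast fluorescence induction transient.

    time_s is strictly increasing; fluorescence is in instrument
    arbitrary units.  Fast-kinetics instruments sample log-densely from
    ~10 µs to ~1 s.
    """

    sample_id: str
    group: str
    time_s: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.fluorescence.shape:
            raise ValueError("time and fluorescence must be 1-D and equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(self.time_s <= 0):
            raise ValueError("time values must be positive (log sampling)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "fluorescence": self.fluorescence,
                "sample_id": self.sample_id,
                "group": self.group,
            }
        )


def traces_to_frame(traces: list[FluorTrace]) -> pd.DataFrame:
    if not traces:
        raise ValueError("no traces to serialize")
    return pd.concat([t.to_frame() for t in traces], ignore_index=True)


def write_traces(traces: list[FluorTrace], path) -> None:
    traces_to_frame(traces).to_csv(path, sep="\t", index=False)


def frame_to_traces(frame: pd.DataFrame) -> list[FluorTrace]:
    required = {"time_s", "fluorescence", "sample_id", "group"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"trace table missing columns: {sorted(missing)}")
    out = []
    for sid, sub in frame.groupby("sample_id", sort=False):
        out.append(
            FluorTrace(
                sample_id=str(sid),
                group=str(sub["group"].iloc[0]),
                time_s=sub["time_s"].to_numpy(),
                fluorescence=sub["fluorescence"].to_numpy(),
            )
        )
    return out


def read_traces(path) -> list[FluorTrace]:
    return frame_to_traces(pd.read_csv(path, sep="\t"))
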