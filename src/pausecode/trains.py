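"""Spike-train container and plain-text I/O.

Spike times are carried in milliseconds at double precision.  A population of
Purkinje-neuron (PN) trains is represented as a plain list of
:class:`SpikeTrain`; CSV round-tripping uses the two-column layout
``unit_id,time_ms`` with one spike per row, sorted by unit then time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["SpikeTrain", "read_trains_csv", "write_trains_csv"]


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times of one unit.

    Parameters
    ----------
    unit_id : str or int
        Identifier of the unit.
    times : ndarray
        Strictly increasing spike times, ms, all within ``[0, duration]``.
    duration : float
        Total length of the recording/simulation window, ms.
    """

    unit_id: object
    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if t.size and (np.any(np.diff(t) <= 0.0)):
            raise ValueError("spike times must be strictly increasing")
        if t.size and (t[0] < 0.0 or t[-1] > self.duration):
            raise ValueError("spike times must lie within [0, duration]")
        if self.duration <= 0.0:
            raise ValueError("duration must be positive")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def isis(self) -> np.ndarray:
        """Inter-spike intervals, ms (length ``n_spikes - 1``)."""
        return np.diff(self.times)

    @property
    def rate_hz(self) -> float:
        """Mean firing rate over the full duration, Hz."""
        return 1000.0 * self.n_spikes / self.duration

    def with_times(self, times: np.ndarray) -> "SpikeTrain":
        return replace(self, times=np.asarray(times, dtype=float))


def write_trains_csv(trains: list[SpikeTrain], path) -> None:
    """Write a population of trains as ``unit_id,time_ms`` rows."""
    frames = [
        pd.DataFrame({"unit_id": tr.unit_id, "time_ms": tr.times})
        for tr in trains
    ]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["unit_id", "time_ms"]
    )
    df.to_csv(path, index=False)


def read_trains_csv(path, duration: float | None = None) -> list[SpikeTrain]:
    """Read a population written by :func:`write_trains_csv`.

    ``duration`` defaults to the last spike time across the file, rounded up
    to the next millisecond.
    """
    df = pd.read_csv(path)
    if not {"unit_id", "time_ms"} <= set(df.columns):
        raise ValueError("expected columns unit_id,time_ms")
    if duration is None:
        duration = float(np.ceil(df["time_ms"].max())) if len(df) else 1.0
    out = []
    for uid, grp in df.groupby("unit_id", sort=True):
        out.append(SpikeTrain(uid, np.sort(grp["time_ms"].to_numpy()), duration))
    return out
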