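"""Core in-memory containers for extracellular recording sessions.

A :class:`SpikeSession` bundles the sorted spike timestamps of every single
unit recorded in one session with the event timestamps (tactile-stimulus
onsets or treadmill footfalls) the analysis aligns to.  A :class:`Psth` is a
peri-event time histogram: spike counts relative to an event, binned on a
fixed grid and *summed over trials* (divide by ``n_trials`` for the familiar
trial-averaged view).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpikeSession", "Psth", "bin_relative_times"]


@dataclass
class SpikeSession:
    """Spike timestamps per neuron plus aligned event timestamps.

    Parameters
    ----------
    spikes
        Mapping ``neuron_id -> sorted array of spike times`` in seconds.
    events
        Table with columns ``label`` (stimulation site or paw) and
        ``time_s``; sorted by time.
    duration
        Total recording duration in seconds.
    """

    spikes: dict[str, np.ndarray]
    events: pd.DataFrame
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        clean = {}
        for nid, t in self.spikes.items():
            t = np.asarray(t, dtype=float)
            if t.size and (np.any(np.diff(t) < 0)):
                raise ValueError(f"spike times for {nid!r} are not sorted")
            if t.size and (t[0] < 0 or t[-1] > self.duration):
                raise ValueError(
                    f"spike times for {nid!r} outside [0, duration={self.duration}]"
                )
            clean[str(nid)] = t
        self.spikes = clean
        ev = pd.DataFrame(self.events, columns=["label", "time_s"]).copy()
        ev["time_s"] = ev["time_s"].astype(float)
        if not ev["time_s"].is_monotonic_increasing:
            ev = ev.sort_values("time_s", kind="stable").reset_index(drop=True)
        if len(ev) and (ev["time_s"].iloc[0] < 0 or ev["time_s"].iloc[-1] > self.duration):
            raise ValueError("event times outside [0, duration]")
        self.events = ev.reset_index(drop=True)

    @property
    def neuron_ids(self) -> list[str]:
        return list(self.spikes)

    def event_times(self, label: str | None = None) -> np.ndarray:
        """Event timestamps (s), optionally restricted to one label."""
        ev = self.events
        if label is not None:
            ev = ev[ev["label"] == label]
        return ev["time_s"].to_numpy()

    def save(self, directory: str | Path) -> None:
        """Write the session as two delimited-text files.

        ``spikes.csv`` has columns ``neuron_id,time_s`` (one row per spike);
        ``events.csv`` has ``label,time_s``; ``session.json`` records the
        duration.
        """
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        rows = [
            (nid, t) for nid, ts in self.spikes.items() for t in ts
        ]
        pd.DataFrame(rows, columns=["neuron_id", "time_s"]).to_csv(
            d / "spikes.csv", index=False
        )
        self.events.to_csv(d / "events.csv", index=False)
        meta = {"duration": self.duration, "neuron_ids": self.neuron_ids}
        (d / "session.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "SpikeSession":
        d = Path(directory)
        meta = json.loads((d / "session.json").read_text())
        sp = pd.read_csv(d / "spikes.csv")
        ev = pd.read_csv(d / "events.csv")
        spikes = {str(nid): np.array([], dtype=float) for nid in meta["neuron_ids"]}
        for nid, grp in sp.groupby("neuron_id"):
            spikes[str(nid)] = np.sort(grp["time_s"].to_numpy(dtype=float))
        return cls(spikes=spikes, events=ev, duration=float(meta["duration"]))


@dataclass(frozen=True)
class Psth:
    """Peri-event time histogram (counts summed over trials).

    ``bin_edges`` are in ms relative to the event; bins are left-closed,
    right-open, and time zero (the event) falls in the first post-event bin.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts)
        if len(counts) != len(edges) - 1:
            raise ValueError("len(counts) must equal len(bin_edges) - 1")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts.astype(int))

    @property
    def binsize(self) -> float:
        """Bin width in ms (uniform grid)."""
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def bin_slice(self, lo_ms: float, hi_ms: float) -> slice:
        """Index slice of bins whose [left, right) interval lies in [lo, hi).

        The PSTH must fully cover the requested window.
        """
        if self.bin_edges[0] > lo_ms + 1e-9 or self.bin_edges[-1] < hi_ms - 1e-9:
            raise ValueError(f"window [{lo_ms}, {hi_ms}) ms not covered by PSTH")
        left = self.bin_edges[:-1]
        right = self.bin_edges[1:]
        sel = np.flatnonzero((left >= lo_ms - 1e-9) & (right <= hi_ms + 1e-9))
        if sel.size == 0:
            raise ValueError(f"window [{lo_ms}, {hi_ms}) ms not covered by PSTH")
        return slice(int(sel[0]), int(sel[-1]) + 1)

    def to_frame(self) -> pd.DataFrame:
        """Export as a table (bin_left_ms, count)."""
        return pd.DataFrame(
            {"bin_left_ms": self.bin_edges[:-1], "count": self.counts}
        )


def bin_relative_times(
    spike_times: np.ndarray,
    event_times: np.ndarray,
    window_ms: tuple[float, float],
    binsize_ms: float,
) -> Psth:
    """Align spikes to events and bin the relative times.

    The bin index of a spike at relative time ``t`` (ms) is
    ``floor((t - left) / binsize)``: bins are left-closed right-open, so a
    spike exactly at the event time lands in the first post-event bin
    ``[0, binsize)``.
    """
    lo, hi = float(window_ms[0]), float(window_ms[1])
    if hi <= lo:
        raise ValueError("window must satisfy left < right")
    span = hi - lo
    n_bins = span / binsize_ms
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("binsize must divide the window length")
    n_bins = int(round(n_bins))
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0:
        raise ValueError("no events to align to")
    spike_times = np.asarray(spike_times, dtype=float)
    counts = np.zeros(n_bins, dtype=int)
    lo_s, hi_s = lo / 1000.0, hi / 1000.0
    for ev in event_times:
        a = np.searchsorted(spike_times, ev + lo_s, side="left")
        b = np.searchsorted(spike_times, ev + hi_s, side="left")
        rel_ms = (spike_times[a:b] - ev) * 1000.0
        idx = np.floor((rel_ms - lo) / binsize_ms).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        np.add.at(counts, idx, 1)
    edges = lo + binsize_ms * np.arange(n_bins + 1)
    return Psth(bin_edges=edges, counts=counts, n_trials=len(event_times))
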