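"""Stimulus-locked PSTH analysis for anesthetized tactile mapping.

Each skin site on the forelimb is tapped 100 times at 0.5 Hz and a PSTH is
built per neuron in a window extending 100 ms before and after the stimulus
at 1 ms binsize.  A response is significant if

(a) some post-stimulus bin exceeds a threshold of the mean background
    activity (evaluated from 100 to 5 ms before the stimulus) plus three
    standard deviations,
(b) at least three post-stimulus bins exceed that threshold, and
(c) an unpaired t-test of the per-trial spike rate between the first and
    last suprathreshold bin against the per-trial background rate gives
    p < 0.001.

Response magnitude is the background-subtracted average number of spikes
per stimulus in the 5–50 ms post-stimulus window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .session import Psth, SpikeSession, bin_relative_times

__all__ = [
    "ResponseResult",
    "build_psth",
    "background_stats",
    "detect_response",
    "response_magnitude",
    "percent_responding",
    "quadrant_magnitudes",
    "ArrayLayout",
    "SENSORY_WINDOW_MS",
    "SENSORY_BINSIZE_MS",
    "BACKGROUND_WINDOW_MS",
    "MAGNITUDE_WINDOW_MS",
]

SENSORY_WINDOW_MS = (-100.0, 100.0)
SENSORY_BINSIZE_MS = 1.0
BACKGROUND_WINDOW_MS = (-100.0, -5.0)
MAGNITUDE_WINDOW_MS = (5.0, 50.0)
N_SD = 3.0
MIN_SUPRA_BINS = 3
T_TEST_ALPHA = 0.001


@dataclass(frozen=True)
class ResponseResult:
    """Verdict of the three-criterion classifier for one neuron × site."""

    significant: bool
    onset_bin: int | None
    offset_bin: int | None
    magnitude: float            # background-subtracted spikes/stimulus
    p_value: float
    threshold: float            # spikes/bin on the trial-summed PSTH
    background_mean: float      # spikes/bin
    background_sd: float

    def __post_init__(self) -> None:
        if self.significant and (self.onset_bin is None or self.offset_bin is None):
            raise ValueError("significant result requires onset/offset bins")
        if (
            self.onset_bin is not None
            and self.offset_bin is not None
            and self.onset_bin > self.offset_bin
        ):
            raise ValueError("onset_bin must be <= offset_bin")
        if not np.isfinite(self.magnitude):
            raise ValueError("magnitude must be finite")


def build_psth(
    session: SpikeSession,
    neuron_id: str,
    location: str,
    window_ms: tuple[float, float] = SENSORY_WINDOW_MS,
    binsize_ms: float = SENSORY_BINSIZE_MS,
) -> Psth:
    """Stimulus-locked PSTH for one neuron and stimulation site."""
    events = session.event_times(location)
    if events.size == 0:
        raise ValueError(f"no events with label {location!r} in session")
    return bin_relative_times(session.spikes[neuron_id], events, window_ms, binsize_ms)


def background_stats(psth: Psth,
                     window_ms: tuple[float, float] = BACKGROUND_WINDOW_MS
                     ) -> tuple[float, float]:
    """Mean and SD of the trial-summed counts over the background bins.

    The SD is the population SD across the background-window bins (a single
    per-neuron background statistic), evaluated from 100 to 5 ms before the
    stimulus: 95 bins at 1 ms.
    """
    sl = psth.bin_slice(*window_ms)
    bg = psth.counts[sl].astype(float)
    return float(bg.mean()), float(bg.std(ddof=0))


def _per_trial_rates(session: SpikeSession, neuron_id: str, location: str,
                     lo_ms: float, hi_ms: float) -> np.ndarray:
    """Per-trial spike rates (spikes/ms) in a peri-stimulus window."""
    t = session.spikes[neuron_id]
    events = session.event_times(location)
    lo_s, hi_s = lo_ms / 1000.0, hi_ms / 1000.0
    counts = np.array(
        [
            np.searchsorted(t, ev + hi_s, side="left")
            - np.searchsorted(t, ev + lo_s, side="left")
            for ev in events
        ],
        dtype=float,
    )
    return counts / (hi_ms - lo_ms)


def detect_response(
    session: SpikeSession,
    neuron_id: str,
    location: str,
    psth: Psth | None = None,
) -> ResponseResult:
    """Apply the three-criterion significance classifier to one neuron.

    Criterion (b) counts *any* three suprathreshold post-stimulus bins (no
    consecutiveness requirement, unlike the awake detector).  If both
    per-trial rate samples of criterion (c) have zero variance, the t-test
    is undefined and an exact-equality fallback governs: significant only
    if the response rate strictly exceeds background in every trial.
    """
    if psth is None:
        psth = build_psth(session, neuron_id, location)
    bg_mean, bg_sd = background_stats(psth)
    threshold = bg_mean + N_SD * bg_sd

    post = psth.bin_slice(0.0, psth.bin_edges[-1])
    post_counts = psth.counts[post]
    supra = np.flatnonzero(post_counts > threshold) + post.start

    magnitude = response_magnitude(psth, bg_mean)

    if supra.size < MIN_SUPRA_BINS:
        return ResponseResult(
            significant=False, onset_bin=None, offset_bin=None,
            magnitude=magnitude, p_value=1.0, threshold=threshold,
            background_mean=bg_mean, background_sd=bg_sd,
        )
    onset, offset = int(supra[0]), int(supra[-1])
    onset_ms = float(psth.bin_edges[onset])
    offset_ms = float(psth.bin_edges[offset + 1])
    resp_rates = _per_trial_rates(session, neuron_id, location, onset_ms, offset_ms)
    bg_rates = _per_trial_rates(session, neuron_id, location, *BACKGROUND_WINDOW_MS)

    if resp_rates.std(ddof=0) == 0.0 and bg_rates.std(ddof=0) == 0.0:
        strictly_greater = bool(np.all(resp_rates > bg_rates.mean())) and (
            resp_rates.mean() != bg_rates.mean()
        )
        significant, p = strictly_greater, 0.0 if strictly_greater else 1.0
    else:
        t, p = sps.ttest_ind(resp_rates, bg_rates)
        significant = bool(p < T_TEST_ALPHA) and resp_rates.mean() > bg_rates.mean()

    if not significant:
        onset = offset = None  # type: ignore[assignment]
    return ResponseResult(
        significant=significant,
        onset_bin=onset,
        offset_bin=offset,
        magnitude=magnitude,
        p_value=float(p),
        threshold=threshold,
        background_mean=bg_mean,
        background_sd=bg_sd,
    )


def response_magnitude(psth: Psth, background_mean: float,
                       window_ms: tuple[float, float] = MAGNITUDE_WINDOW_MS
                       ) -> float:
    """Background-subtracted spikes per stimulus in the 5–50 ms window.

    ``(Σ counts in [5, 50) ms − n_bins·background_mean) / n_trials``; may be
    negative for neurons quieter after the stimulus than before.
    """
    sl = psth.bin_slice(*window_ms)
    n_bins = sl.stop - sl.start
    total = float(psth.counts[sl].sum())
    return (total - n_bins * background_mean) / psth.n_trials


def percent_responding(results: pd.DataFrame,
                       contralateral_locations: list[str] | None = None) -> float:
    """Proportion of recorded neurons responding to the contralateral forelimb.

    ``results`` is tidy with columns ``neuron_id, location, significant``; a
    neuron *responds* if it is significant for at least one of the (by
    default, all listed) contralateral stimulation sites.
    """
    df = results
    if contralateral_locations is not None:
        df = df[df["location"].isin(contralateral_locations)]
    if df.empty:
        raise ValueError("no neurons / locations to evaluate")
    per_neuron = df.groupby("neuron_id")["significant"].any()
    return float(per_neuron.mean())


@dataclass(frozen=True)
class ArrayLayout:
    """4×4 microwire array geometry and its 2×2 quadrants.

    Rows run rostral→caudal, columns medial→lateral.  Q2 is the
    medial-rostral quadrant (rows 0–1, cols 0–1); Q1 rostral-lateral,
    Q3 caudal-medial, Q4 caudal-lateral.
    """

    n_rows: int = 4
    n_cols: int = 4

    def quadrant(self, wire: int) -> str:
        if not (0 <= wire < self.n_rows * self.n_cols):
            raise ValueError(f"wire {wire} not on the {self.n_rows}x{self.n_cols} array")
        row, col = divmod(wire, self.n_cols)
        rostral = row < self.n_rows // 2
        medial = col < self.n_cols // 2
        if rostral and medial:
            return "Q2"
        if rostral:
            return "Q1"
        if medial:
            return "Q3"
        return "Q4"


def quadrant_magnitudes(magnitudes: pd.DataFrame,
                        layout: ArrayLayout | None = None) -> pd.Series:
    """Mean response magnitude per array quadrant.

    ``magnitudes`` has columns ``wire`` (0–15) and ``magnitude`` (one row
    per neuron).  Wires with no neurons contribute nothing; a quadrant with
    no neurons at all is NaN (missing), never zero.
    """
    if layout is None:
        layout = ArrayLayout()
    df = magnitudes.copy()
    df["quadrant"] = [layout.quadrant(int(w)) for w in df["wire"]]
    means = df.groupby("quadrant")["magnitude"].mean()
    return means.reindex(["Q1", "Q2", "Q3", "Q4"])
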