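"""Footfall-locked PSTH analysis for awake treadmill recordings.

PSTHs are built around forepaw footfalls in a ±250 ms window at 10 ms
binsize, smoothed with a length-five zero-phase sliding-window filter, and
compared to a threshold set at the one-sided 99% confidence bound above the
neuron's mean firing rate computed over the entire recording.  A response is
significant when at least three consecutive smoothed bins exceed the
threshold; the peak is the highest suprathreshold bin and the response rate
is computed from the *unsmoothed* PSTH over the suprathreshold run
containing the peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import Psth, SpikeSession, bin_relative_times

__all__ = [
    "LocomotorResponse",
    "build_footfall_psth",
    "smooth_zero_phase",
    "detect_locomotor_response",
    "peak_latency_distribution",
    "LOCOMOTOR_WINDOW_MS",
    "LOCOMOTOR_BINSIZE_MS",
    "Z_CI99",
]

LOCOMOTOR_WINDOW_MS = (-250.0, 250.0)
LOCOMOTOR_BINSIZE_MS = 10.0
FILTER_LENGTH = 5
MIN_RUN = 3
#: upper limit of a 99% confidence interval: normal quantile at 0.995
Z_CI99 = 2.5758293035489004


@dataclass(frozen=True)
class LocomotorResponse:
    significant: bool
    peak_latency_ms: float | None   # bin center of the peak bin
    extent: tuple[int, int] | None  # first/last bin of the suprathreshold run
    response_rate_hz: float | None  # from unsmoothed counts over the extent
    background_rate_hz: float
    threshold: float                # trial-summed spikes/bin


def build_footfall_psth(
    session: SpikeSession,
    neuron_id: str,
    paw: str | None = None,
    window_ms: tuple[float, float] = LOCOMOTOR_WINDOW_MS,
    binsize_ms: float = LOCOMOTOR_BINSIZE_MS,
) -> Psth:
    """Footfall-locked PSTH (50 bins of 10 ms by default)."""
    events = session.event_times(paw)
    if events.size == 0:
        raise ValueError("no footfalls to align to")
    return bin_relative_times(session.spikes[neuron_id], events, window_ms, binsize_ms)


def smooth_zero_phase(values: np.ndarray, length: int = FILTER_LENGTH) -> np.ndarray:
    """Forward-backward length-``length`` moving average (zero net phase).

    Edges are replicate-padded before each pass, which preserves unit DC
    gain at the boundaries; output length equals input length, and a
    symmetric input stays exactly symmetric.
    """
    x = np.asarray(values, dtype=float)
    if x.size < length:
        raise ValueError(f"need at least {length} bins to smooth")
    if length % 2 != 1:
        raise ValueError("filter length must be odd")
    half = length // 2
    kernel = np.full(length, 1.0 / length)

    def ma(v: np.ndarray) -> np.ndarray:
        padded = np.concatenate([np.full(half, v[0]), v, np.full(half, v[-1])])
        return np.convolve(padded, kernel, mode="valid")

    fwd = ma(x)
    return ma(fwd[::-1])[::-1]


def detect_locomotor_response(
    psth: Psth,
    background_rate_hz: float,
    use_smoothed: bool = True,
) -> LocomotorResponse:
    """Threshold the (smoothed) footfall PSTH against the 99% Poisson bound.

    The expected trial-summed count per bin under the whole-recording rate
    ``r`` is ``m = r · binsize · n_footfalls``; the threshold is
    ``m + z·√m`` with z = 2.5758, the 99% CI upper quantile.  On the
    trial-averaged PSTH this is ``μ + z·√(μ/n)``: doubling the footfall
    count shrinks the averaged-scale half-width by √2.  The peak is the maximal
    suprathreshold smoothed bin (earliest on ties); the extent is the
    maximal run of consecutive suprathreshold bins containing the peak;
    significance requires a run of at least three.  The response rate is
    computed from the unsmoothed counts over the extent.
    """
    if background_rate_hz < 0:
        raise ValueError("background rate must be >= 0")
    n = psth.n_trials
    bin_s = psth.binsize / 1000.0
    m = background_rate_hz * bin_s * n
    threshold = m + Z_CI99 * np.sqrt(m)

    raw = psth.counts.astype(float)
    values = smooth_zero_phase(raw) if use_smoothed else raw
    above = values > threshold
    if not above.any():
        return LocomotorResponse(
            significant=False, peak_latency_ms=None, extent=None,
            response_rate_hz=None, background_rate_hz=background_rate_hz,
            threshold=float(threshold),
        )
    supra = np.flatnonzero(above)
    peak = int(supra[np.argmax(values[supra])])  # argmax takes the earliest tie
    lo = peak
    while lo - 1 >= 0 and above[lo - 1]:
        lo -= 1
    hi = peak
    while hi + 1 < len(above) and above[hi + 1]:
        hi += 1
    run = hi - lo + 1
    significant = run >= MIN_RUN
    extent_s = run * bin_s
    response_rate = float(raw[lo : hi + 1].sum() / (n * extent_s))
    return LocomotorResponse(
        significant=significant,
        peak_latency_ms=float(psth.bin_centers[peak]),
        extent=(lo, hi),
        response_rate_hz=response_rate,
        background_rate_hz=background_rate_hz,
        threshold=float(threshold),
    )


def background_rate(session: SpikeSession, neuron_id: str) -> float:
    """Firing rate over the entire recording duration (Hz)."""
    return len(session.spikes[neuron_id]) / session.duration


def peak_latency_distribution(responses) -> np.ndarray:
    """Peak latencies (ms) of the significant neurons only."""
    return np.array(
        [r.peak_latency_ms for r in responses if r.significant], dtype=float
    )
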