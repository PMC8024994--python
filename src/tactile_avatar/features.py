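"""Signal-level feature extraction from touch and slide traces.

Two physical readouts anchor the analysis: the initial slope of the touch
transient is proportional to durometer hardness, and the dominant sliding
frequency equals sliding velocity divided by surface pattern pitch (so the
pitch is velocity x the inter-peak time interval). The network consumes a
400-sample touch window (400 ms at 1000 samples/s) and a 500-bin magnitude
spectrum of the sliding signal covering 1-500 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks

if TYPE_CHECKING:
    from .simulator import Recording, SimulationConfig, TactileMaterial

__all__ = [
    "EstimationError",
    "FeatureVector",
    "detect_onset",
    "estimate_touch_slope",
    "estimate_pitch",
    "slide_spectrum",
    "touch_window",
    "preprocess_recording",
    "features_for_corpus",
    "feature_table",
]

TOUCH_WINDOW_SAMPLES = 400
SPECTRUM_BINS = 500  # integer frequencies 1..500 Hz
_MIN_SPECTRUM_SAMPLES = 1000  # one 1 s window resolves the 1 Hz bin


class EstimationError(ValueError):
    """A signal-level estimate could not be formed (no onset / too few peaks)."""


@dataclass(frozen=True)
class FeatureVector:
    """Network input pair: 400-sample touch window + 500-bin slide spectrum."""

    touch_window: np.ndarray
    slide_spectrum: np.ndarray

    def __post_init__(self) -> None:
        if self.touch_window.shape != (TOUCH_WINDOW_SAMPLES,):
            raise ValueError("touch_window must have exactly 400 samples")
        if self.slide_spectrum.shape != (SPECTRUM_BINS,):
            raise ValueError("slide_spectrum must have exactly 500 bins")


def detect_onset(
    trace: np.ndarray, noise_mult: float = 5.0, min_run: int = 5
) -> int:
    """First index where the trace exceeds a noise-floor multiple for
    ``min_run`` consecutive samples.

    The noise floor is the standard deviation of the leading 50 samples;
    the threshold never drops below 2% of the trace maximum so that
    noiseless traces still yield a well-defined onset.
    """
    trace = np.asarray(trace, dtype=float)
    peak = float(trace.max(initial=0.0))
    if peak <= 0:
        raise EstimationError("flat trace: no contact onset detected")
    floor = float(np.std(trace[: min(50, len(trace))]))
    thr = max(noise_mult * floor, 0.02 * peak)
    above = trace > thr
    if min_run > 1:
        kernel = np.ones(min_run, dtype=int)
        runs = np.convolve(above.astype(int), kernel, mode="valid") == min_run
        idx = np.flatnonzero(runs)
    else:
        idx = np.flatnonzero(above)
    if idx.size == 0:
        raise EstimationError("flat trace: no contact onset detected")
    return int(idx[0])


def estimate_touch_slope(touch_trace: np.ndarray, sample_rate: float) -> float:
    """Least-squares slope (V/s) of the initial rise, onset to first peak."""
    trace = np.asarray(touch_trace, dtype=float)
    onset = detect_onset(trace)
    # first approach to the maximum, not the global argmax: on noisy
    # plateaus the argmax wanders arbitrarily far past the rise
    peak = int(np.argmax(trace >= 0.95 * trace.max()))
    if peak <= onset:
        raise EstimationError("no rising segment after onset")
    seg = trace[onset : peak + 1]
    t = np.arange(seg.size) / sample_rate
    slope, _ = np.polyfit(t, seg, 1)
    return float(slope)


def estimate_pitch(
    slide_trace: np.ndarray,
    velocity_cm_s: float,
    sample_rate: float,
    prominence_mult: float = 1.0,
) -> float:
    """Surface pattern pitch (um) = velocity x median inter-peak interval.

    Peaks are detected with prominence ``prominence_mult`` x the trace
    standard deviation and a minimum separation of 60% of the dominant
    spectral period (overtones of a patterned surface otherwise inject
    sub-period peaks); at 4 cm/s an inter-peak interval of 0.01 s maps to
    a 400 um pitch.
    """
    trace = np.asarray(slide_trace, dtype=float)
    mag = np.abs(np.fft.rfft(trace - trace.mean()))
    distance = None
    if mag.size > 1 and mag[1:].max() > 0:
        f_dom = np.argmax(mag[1:]) + 1  # cycles over the whole trace
        distance = max(1, int(0.6 * trace.size / f_dom))
    peaks, _ = find_peaks(
        trace, prominence=prominence_mult * float(np.std(trace)), distance=distance
    )
    if peaks.size < 2:
        raise EstimationError("fewer than 2 peaks detected in sliding trace")
    interval_s = float(np.median(np.diff(peaks))) / sample_rate
    return velocity_cm_s * 1e4 * interval_s  # cm/s -> um/s


def slide_spectrum(slide_trace: np.ndarray, sample_rate: float = 1000.0) -> np.ndarray:
    """Magnitude spectrum of the sliding trace on integer frequencies 1-500 Hz.

    The trace is demeaned (DC excluded), Fourier-transformed over the full
    sliding window, linearly interpolated onto the 1..500 Hz grid, and
    max-normalized per recording.
    """
    trace = np.asarray(slide_trace, dtype=float)
    if trace.size < _MIN_SPECTRUM_SAMPLES:
        raise ValueError(
            f"sliding trace shorter than one {_MIN_SPECTRUM_SAMPLES}-sample window"
        )
    mag = np.abs(np.fft.rfft(trace - trace.mean()))
    freqs = np.fft.rfftfreq(trace.size, d=1.0 / sample_rate)
    grid = np.arange(1, SPECTRUM_BINS + 1, dtype=float)
    spec = np.interp(grid, freqs, mag)
    top = spec.max()
    # floor guards against amplifying pure round-off on (near-)DC traces
    if top > 1e-9 * trace.size * (np.abs(trace).max() + 1.0):
        spec = spec / top
    else:
        spec = np.zeros_like(spec)
    return spec


def touch_window(touch_trace: np.ndarray) -> np.ndarray:
    """The 400-sample window starting at contact onset (400 ms at 1000/s)."""
    trace = np.asarray(touch_trace, dtype=float)
    onset = detect_onset(trace)
    if onset + TOUCH_WINDOW_SAMPLES > trace.size:
        raise ValueError(
            f"only {trace.size - onset} samples after onset; need {TOUCH_WINDOW_SAMPLES}"
        )
    return trace[onset : onset + TOUCH_WINDOW_SAMPLES]


def preprocess_recording(recording: "Recording") -> FeatureVector:
    """Network preprocessing of one recording (aggregated across cells)."""
    return FeatureVector(
        touch_window=touch_window(recording.aggregated_touch),
        slide_spectrum=slide_spectrum(recording.aggregated_slide, recording.sample_rate),
    )


def features_for_corpus(
    library: Sequence["TactileMaterial"], config: "SimulationConfig"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stream a simulated corpus straight to network inputs.

    Returns ``(touch, slide, material_ids)`` with shapes ``(N, 400)``,
    ``(N, 500)``, ``(N,)`` where ``N = n_materials x n_trials_per_material``.
    Raw per-cell traces are never materialised, which keeps full-scale
    corpora (thousands of 30-cell recordings) in tens of megabytes.
    """
    from .simulator import iter_corpus

    n = len(library) * config.n_trials_per_material
    touch = np.empty((n, TOUCH_WINDOW_SAMPLES))
    slide = np.empty((n, SPECTRUM_BINS))
    ids = np.empty(n, dtype=int)
    for i, rec in enumerate(iter_corpus(library, config)):
        fv = preprocess_recording(rec)
        touch[i] = fv.touch_window
        slide[i] = fv.slide_spectrum
        ids[i] = rec.material_id
    return touch, slide, ids


def feature_table(recordings: Iterable["Recording"]):
    """Per-trial scalar features as a DataFrame: slope and pitch estimate."""
    import pandas as pd

    rows = []
    trial_counter: dict[int, int] = {}
    for rec in recordings:
        trial = trial_counter.get(rec.material_id, 0)
        trial_counter[rec.material_id] = trial + 1
        try:
            slope = estimate_touch_slope(rec.aggregated_touch, rec.sample_rate)
        except EstimationError:
            slope = np.nan
        try:
            pitch = estimate_pitch(
                rec.aggregated_slide, rec.sliding_velocity_cm_s, rec.sample_rate
            )
        except EstimationError:
            pitch = np.nan
        rows.append(
            {
                "material_id": rec.material_id,
                "trial": trial,
                "slope_v_per_s": slope,
                "pitch_estimate_um": pitch,
            }
        )
    return pd.DataFrame(rows)
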