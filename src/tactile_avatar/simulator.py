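"""Synthetic piezoelectric touch/slide recordings for a ranked texture library.

The generator emulates a multiarray piezoelectric fingertip sensor stroked
over fabric-like materials: a *touch* transient whose initial slope grows
with durometer hardness, and a *slide* oscillation whose fundamental
frequency is sliding velocity divided by the surface pattern pitch.
Materials are ordered by a ground-truth smooth/soft -> rough rank; broadband
texture noise grows with rank while neighbouring mid-rank materials are
deliberately similar (smaller parameter gaps) so that they are harder to
tell apart — the same structure that makes humans hesitate over mid-ranked
fabrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "TactileMaterial",
    "SimulationConfig",
    "Recording",
    "hardness_bin",
    "side_middle_masks",
    "build_material_library",
    "simulate_touch",
    "simulate_slide",
    "iter_corpus",
    "record_corpus",
    "material_manifest",
]

#: durometer upper edges for bins 1..5 (20-40, 41-50, 51-60, 61-70, 71-90)
_BIN_EDGES = (40.0, 50.0, 60.0, 70.0)


def hardness_bin(durometer: float) -> int:
    """Map a durometer reading (20-90) to its 5-level hardness bin."""
    if not 20.0 <= durometer <= 90.0:
        raise ValueError(f"durometer {durometer} outside the 20-90 scale")
    return int(np.searchsorted(_BIN_EDGES, durometer, side="left")) + 1


def side_middle_masks(n_materials: int) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (side, middle) masks over ranks 1..M.

    For the 42-material study the middle band is ranks 11-30 and the side
    band ranks 1-10 and 31-42; other library sizes scale the band edges
    proportionally.
    """
    m = n_materials
    lo = int(round(10 * m / 42))
    hi = int(round(30 * m / 42))
    ranks = np.arange(1, m + 1)
    middle = (ranks > lo) & (ranks <= hi)
    return ~middle, middle


@dataclass(frozen=True)
class TactileMaterial:
    """One texture sample with its ground-truth physical parameters."""

    material_id: int
    true_rank: int  # 1 = smoothest/softest
    durometer_hardness: float  # 20-90, dimensionless
    pattern_pitch_um: float  # spatial period of the surface texture
    harmonic_amplitudes: tuple[float, ...]  # fundamental + overtones, relative
    roughness_level: float  # broadband texture amplitude, relative
    piezo_gain: float  # V/N coupling of this material/sensor pairing
    texture_seed: int  # seeds the frozen broadband texture sequence

    @property
    def hardness_bin(self) -> int:
        return hardness_bin(self.durometer_hardness)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for corpus generation.

    Defaults mirror the measurement protocol: 42 materials, 100 trials per
    material, 1.2 N contact force, 4 cm/s sliding velocity, 1000 samples/s,
    30 active sensing cells.
    """

    n_materials: int = 42
    n_trials_per_material: int = 100
    contact_force_n: float = 1.2
    sliding_velocity_cm_s: float = 4.0
    noise_level: float = 0.05  # measurement noise, relative to signal peak
    seed: int = 0
    sample_rate: float = 1000.0
    n_cells: int = 30
    touch_duration_s: float = 0.6
    touch_onset_s: float = 0.1
    touch_decay_tau_s: float = 0.08
    slide_duration_s: float = 2.0
    cell_gain_jitter: float = 0.02
    # affine slope-vs-hardness map: slope = gain * force * (a + b * durometer)
    slope_intercept: float = 2.0  # a, V/s per (N * gain)
    slope_per_durometer: float = 0.2  # b, V/s per durometer unit
    touch_peak_v_per_n: float = 1.0  # transient peak amplitude scale
    slide_amp_v: float = 0.3  # slide oscillation amplitude scale

    def __post_init__(self) -> None:
        if self.n_materials < 1:
            raise ValueError("n_materials must be positive")
        if self.n_trials_per_material < 1:
            raise ValueError("n_trials_per_material must be positive")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")


@dataclass
class Recording:
    """Touch and slide voltage traces for one contact event.

    Per-cell traces are stored as ``(n_cells, n_samples)`` arrays; the
    aggregated traces are their arithmetic means.
    """

    material_id: int
    touch_traces: np.ndarray
    slide_traces: np.ndarray
    contact_force_n: float
    sliding_velocity_cm_s: float
    sample_rate: float

    @property
    def aggregated_touch(self) -> np.ndarray:
        return self.touch_traces.mean(axis=0)

    @property
    def aggregated_slide(self) -> np.ndarray:
        return self.slide_traces.mean(axis=0)


def _warped_positions(n: int) -> np.ndarray:
    """Rank positions in [0, 1] with compressed gaps for middle ranks.

    Middle-band ranks receive 40% of the side-band inter-neighbour gap, so
    mid-ranked materials sit closer together in parameter space.
    """
    if n == 1:
        return np.array([0.5])
    _, middle = side_middle_masks(n)
    gaps = np.where(middle[1:] | middle[:-1], 0.4, 1.0)
    pos = np.concatenate([[0.0], np.cumsum(gaps)])
    return pos / pos[-1]


def build_material_library(
    n_materials: int = 42, seed: int = 0
) -> list[TactileMaterial]:
    """Build a ranked texture library of ``n_materials`` samples.

    Pattern pitch grows with rank (rough fabrics have coarser patterns,
    e.g. a 400 um fine weave near the smooth end versus a 4 mm check near
    the rough end) over roughly 1.5e2-8e3 um; broadband roughness grows
    linearly with rank. Durometer hardness spans 20-90 but is assigned by a
    seeded shuffle, independent of rank: a smooth fabric can be hard.
    """
    if n_materials < 1:
        raise ValueError("n_materials must be positive")
    rng = np.random.default_rng(seed)
    u = _warped_positions(n_materials)
    pitches = 150.0 * (8000.0 / 150.0) ** u
    durometers = np.linspace(20.0, 90.0, max(n_materials, 2))[:n_materials]
    rng.shuffle(durometers)
    ratios = rng.uniform(0.3, 0.6, size=n_materials)
    gains = np.exp(rng.normal(0.0, 0.05, size=n_materials))
    texture_seeds = rng.integers(0, 2**31 - 1, size=n_materials)
    library = []
    for i in range(n_materials):
        rank = i + 1
        rough = 0.02 + 0.28 * (rank - 1) / max(n_materials - 1, 1)
        amps = tuple((ratios[i] ** k) for k in range(4))
        library.append(
            TactileMaterial(
                material_id=rank,
                true_rank=rank,
                durometer_hardness=float(durometers[i]),
                pattern_pitch_um=float(pitches[i]),
                harmonic_amplitudes=amps,
                roughness_level=float(rough),
                piezo_gain=float(gains[i]),
                texture_seed=int(texture_seeds[i]),
            )
        )
    return library


def touch_slope_v_per_s(
    material: TactileMaterial, force_n: float, config: SimulationConfig
) -> float:
    """Initial touch-transient slope: gain x force x affine(durometer)."""
    g = config.slope_intercept + config.slope_per_durometer * material.durometer_hardness
    return material.piezo_gain * force_n * g


def simulate_touch(
    material: TactileMaterial,
    force_n: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate one aggregated touch transient (volts).

    The trace is silent until contact onset, rises linearly at a slope
    proportional to durometer hardness, peaks, then decays exponentially
    (piezoelectric derivative response). Additive white measurement noise
    at ``config.noise_level`` (relative to the peak) is drawn from ``rng``.
    """
    if force_n < 0:
        raise ValueError("contact force must be >= 0")
    n = int(round(config.touch_duration_s * config.sample_rate))
    t = np.arange(n) / config.sample_rate
    trace = np.zeros(n)
    peak = material.piezo_gain * config.touch_peak_v_per_n * force_n
    if force_n > 0:
        slope = touch_slope_v_per_s(material, force_n, config)
        t0 = config.touch_onset_s
        t_rise = peak / slope
        rising = (t >= t0) & (t < t0 + t_rise)
        trace[rising] = slope * (t[rising] - t0)
        decaying = t >= t0 + t_rise
        trace[decaying] = peak * np.exp(
            -(t[decaying] - t0 - t_rise) / config.touch_decay_tau_s
        )
    if config.noise_level > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        ref = peak if force_n > 0 else config.touch_peak_v_per_n
        trace = trace + rng.normal(0.0, config.noise_level * ref, size=n)
    return trace


def _texture_broadband(material: TactileMaterial, n: int) -> np.ndarray:
    # frozen per-material texture: identical in every trial, by design
    trng = np.random.default_rng(material.texture_seed)
    return trng.standard_normal(n)


def simulate_slide(
    material: TactileMaterial,
    velocity_cm_s: float,
    duration_s: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate one aggregated sliding trace (volts).

    Fundamental frequency = velocity / pattern pitch, with geometrically
    decaying overtones and a frozen broadband texture component scaled by
    the material's roughness level. Measurement noise from ``rng``.
    """
    if velocity_cm_s <= 0:
        raise ValueError("sliding velocity must be > 0")
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    n = int(round(duration_s * config.sample_rate))
    t = np.arange(n) / config.sample_rate
    f0 = velocity_cm_s * 1e4 / material.pattern_pitch_um  # cm/s -> um/s
    amp = config.slide_amp_v * material.piezo_gain
    trace = np.zeros(n)
    for k, a in enumerate(material.harmonic_amplitudes, start=1):
        trace += amp * a * np.sin(2 * np.pi * k * f0 * t)
    trace += amp * material.roughness_level * _texture_broadband(material, n)
    if config.noise_level > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        trace = trace + rng.normal(0.0, config.noise_level * amp, size=n)
    return trace


def _cell_gains(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    # fixed sensor-array heterogeneity: one gain factor per cell per corpus
    return 1.0 + config.cell_gain_jitter * rng.standard_normal(config.n_cells)


def iter_corpus(
    library: Sequence[TactileMaterial], config: SimulationConfig
) -> Iterator[Recording]:
    """Stream ``n_trials_per_material`` recordings per material.

    Trial-to-trial variation is driven solely by the measurement-noise
    stream seeded from ``config.seed``; a fixed seed reproduces the corpus
    bit for bit. Recordings are yielded material-major, trial-minor.
    """
    if len(library) == 0:
        raise ValueError("material library is empty")
    rng = np.random.default_rng(config.seed)
    gains = _cell_gains(config, rng)
    nt = int(round(config.touch_duration_s * config.sample_rate))
    ns = int(round(config.slide_duration_s * config.sample_rate))
    noiseless = replace(config, noise_level=0.0)
    for material in library:
        touch_clean = simulate_touch(material, config.contact_force_n, noiseless)
        slide_clean = simulate_slide(
            material,
            config.sliding_velocity_cm_s,
            config.slide_duration_s,
            noiseless,
        )
        touch_ref = material.piezo_gain * config.touch_peak_v_per_n * config.contact_force_n
        slide_ref = config.slide_amp_v * material.piezo_gain
        for _ in range(config.n_trials_per_material):
            touch = gains[:, None] * touch_clean[None, :]
            slide = gains[:, None] * slide_clean[None, :]
            if config.noise_level > 0:
                touch = touch + rng.normal(
                    0.0, config.noise_level * touch_ref, size=(config.n_cells, nt)
                )
                slide = slide + rng.normal(
                    0.0, config.noise_level * slide_ref, size=(config.n_cells, ns)
                )
            yield Recording(
                material_id=material.material_id,
                touch_traces=touch,
                slide_traces=slide,
                contact_force_n=config.contact_force_n,
                sliding_velocity_cm_s=config.sliding_velocity_cm_s,
                sample_rate=config.sample_rate,
            )


def record_corpus(
    library: Sequence[TactileMaterial], config: SimulationConfig
) -> list[Recording]:
    """Materialise the full corpus as a list (see :func:`iter_corpus`).

    At full study scale (42 x 100 trials x 30 cells) the raw traces run to
    gigabytes; prefer streaming via :func:`iter_corpus` or going straight
    to features with :func:`tactile_avatar.features.features_for_corpus`.
    """
    return list(iter_corpus(library, config))


def material_manifest(library: Sequence[TactileMaterial]):
    """Material library as a pandas DataFrame (one row per material)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "material_id": [m.material_id for m in library],
            "true_rank": [m.true_rank for m in library],
            "durometer_hardness": [m.durometer_hardness for m in library],
            "hardness_bin": [m.hardness_bin for m in library],
            "pattern_pitch_um": [m.pattern_pitch_um for m in library],
            "roughness_level": [m.roughness_level for m in library],
        }
    )
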