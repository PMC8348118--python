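"""Multitrack forward model: tracks, b-bit DMD patterns, shots and timing.

One *shot* displays a compound pattern — one subpattern per vertical track
of the DMD — and integrates for Δt seconds, yielding one spectrum per track
(``nτ × nc`` photon counts).  Signed measurement patterns (Bernoulli rows,
Haar wavelets) cannot be shown directly on a DMD whose pixels live on the
b-bit grid {0, 1/(2^b−1), …, 1}; they are affinely mapped into that range
and the shift is cancelled afterwards using a constant half-scale *offset
pattern*:

    ζ = (2^(b−1)−1)/(2^b−1) · (p/‖p‖∞ + 1)            (realization)
    pᵀx = (2^b−1)‖p‖∞ / ((2^(b−1)−1)Δt) · (G − G_offset)   (correction)

For pattern families whose normalized entries lie in {−1, 0, +1} (Bernoulli,
Haar, delta, offset) the b-bit snap is exact, so the noiseless
realize→measure→correct roundtrip reproduces pᵀx to float roundoff.

Measurement noise is Poisson shot noise plus dark current:
``G ~ Pois(ζᵀXΔt + αΔt)`` independently per (track, channel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datacube import Scene, SceneMatrix, matrix_to_cube

__all__ = [
    "TrackLayout",
    "Subpattern",
    "CompoundPattern",
    "NoiseModel",
    "ShotRecord",
    "TimingModel",
    "split_tracks",
    "realize_subpattern",
    "make_offset_compound",
    "simulate_shot",
    "extract_measurements",
    "full_sampling_acquire",
    "acquisition_time",
]


@dataclass(frozen=True)
class TrackLayout:
    """Division of an ``nh × nw`` scene (and the DMD) into nτ vertical strips."""

    nh: int
    nw: int
    n_tracks: int

    def __post_init__(self) -> None:
        if self.n_tracks < 1:
            raise ValueError("need at least one track")
        if self.nw % self.n_tracks != 0:
            raise ValueError(
                f"scene width {self.nw} not divisible into {self.n_tracks} tracks"
            )

    @property
    def track_width(self) -> int:
        return self.nw // self.n_tracks

    @property
    def pixels_per_track(self) -> int:
        return self.nh * self.track_width

    def track_of_column(self, col: int) -> int:
        return col // self.track_width

    def pixel_range(self, i: int) -> tuple[int, int]:
        """Unrolled-index range [start, stop) of track i.

        With column-major unrolling (p = row + nh·col) each vertical strip
        is a contiguous block of the scene matrix.
        """
        if not 0 <= i < self.n_tracks:
            raise IndexError(f"track {i} out of range")
        blk = self.pixels_per_track
        return i * blk, (i + 1) * blk


def split_tracks(m: SceneMatrix, layout: TrackLayout) -> list[np.ndarray]:
    """Split X into the per-track submatrices X^(1)…X^(nτ) (views)."""
    if (m.nh, m.nw) != (layout.nh, layout.nw):
        raise ValueError("scene matrix dims do not match track layout")
    return [m.X[slice(*layout.pixel_range(i))] for i in range(layout.n_tracks)]


@dataclass
class Subpattern:
    """b-bit DMD pixel values on one track, plus the pattern they encode.

    ``scale`` is the ℓ∞ norm of the continuous pattern the subpattern
    realizes; it is needed to undo the affine DMD mapping at extraction.
    Offset and delta subpatterns carry no signed source pattern and store
    ``scale=None``.
    """

    zeta: np.ndarray
    b: int
    scale: float | None = None
    is_offset: bool = False

    def __post_init__(self) -> None:
        self.zeta = np.asarray(self.zeta, dtype=float)
        grid = np.round(self.zeta * (2**self.b - 1))
        if not np.allclose(grid / (2**self.b - 1), self.zeta, rtol=0, atol=1e-12):
            raise ValueError("subpattern entries must lie on the b-bit grid")
        if self.zeta.min() < 0 or self.zeta.max() > 1:
            raise ValueError("subpattern entries must lie in [0, 1]")


@dataclass
class CompoundPattern:
    """One subpattern per track, displayed together in a single shot."""

    subpatterns: list[Subpattern]
    label: object = None

    def __post_init__(self) -> None:
        lens = {sp.zeta.size for sp in self.subpatterns}
        bits = {sp.b for sp in self.subpatterns}
        if len(lens) > 1 or len(bits) > 1:
            raise ValueError("subpatterns must share length and bit depth")

    @property
    def b(self) -> int:
        return self.subpatterns[0].b

    @property
    def n_tracks(self) -> int:
        return len(self.subpatterns)


@dataclass
class NoiseModel:
    """Poisson shot noise + dark current, or exact noiseless counts.

    ``alpha`` is the dark current in photons pixel⁻¹ s⁻¹, added as αΔt to
    every (track, channel) Poisson mean.  Each shot draws from its own
    substream keyed by the caller-supplied shot key, so acquisition order
    does not change the simulated data.
    """

    poisson_enabled: bool = False
    alpha: float = 0.0
    offset_shot_repeats: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("dark current must be >= 0")
        if self.offset_shot_repeats is None:
            self.offset_shot_repeats = 10 if self.poisson_enabled else 1
        if self.offset_shot_repeats < 1:
            raise ValueError("need at least one offset shot")

    def rng_for(self, shot_key: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(shot_key)])


@dataclass
class ShotRecord:
    """Raw detector output of one shot: nτ × nc photon counts."""

    G: np.ndarray
    dt: float
    label: object = None
    is_offset: bool = False
    pattern: CompoundPattern | None = None


NOISELESS = NoiseModel(poisson_enabled=False)


def realize_subpattern(p: np.ndarray, b: int) -> Subpattern:
    """Map a signed continuous pattern onto the b-bit DMD grid."""
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("pattern entries must be finite")
    pinf = float(np.max(np.abs(p)))
    if pinf == 0.0:
        raise ValueError("cannot realize an all-zero pattern")
    if b < 2:
        raise ValueError("bit depth must be >= 2")
    c = (2 ** (b - 1) - 1) / (2**b - 1)
    zeta = c * (p / pinf + 1.0)
    # snap to the b-bit grid, rounding half away from zero (entries are >= 0
    # so this is floor(x + 1/2) on the scaled grid)
    levels = np.floor(zeta * (2**b - 1) + 0.5)
    zeta = levels / (2**b - 1)
    return Subpattern(zeta=zeta, b=b, scale=pinf)


def make_offset_compound(layout: TrackLayout, b: int) -> CompoundPattern:
    """The constant half-scale compound pattern used for offset correction."""
    if b < 2:
        raise ValueError("bit depth must be >= 2 (b=1 offset is identically zero)")
    c = (2 ** (b - 1) - 1) / (2**b - 1)
    subs = [
        Subpattern(zeta=np.full(layout.pixels_per_track, c), b=b, is_offset=True)
        for _ in range(layout.n_tracks)
    ]
    return CompoundPattern(subpatterns=subs, label="offset")


def _record_shot(m: SceneMatrix, layout: TrackLayout, cp: CompoundPattern,
                 dt: float, noise: NoiseModel, shot_key: int) -> ShotRecord:
    """Forward model shared by all acquisition paths (no bit-depth policy)."""
    if dt <= 0:
        raise ValueError("integration time must be positive")
    tracks = split_tracks(m, layout)
    if cp.n_tracks != layout.n_tracks:
        raise ValueError("compound pattern track count does not match layout")
    if cp.subpatterns[0].zeta.size != layout.pixels_per_track:
        raise ValueError("subpattern length does not match track size")
    G = np.stack([sp.zeta @ Xi for sp, Xi in zip(cp.subpatterns, tracks)]) * dt
    if noise.poisson_enabled:
        rng = noise.rng_for(shot_key)
        G = rng.poisson(G + noise.alpha * dt).astype(float)
    elif noise.alpha:
        G = G + noise.alpha * dt
    return ShotRecord(G=G, dt=dt, label=cp.label,
                      is_offset=all(sp.is_offset for sp in cp.subpatterns),
                      pattern=cp)


def simulate_shot(m: SceneMatrix, layout: TrackLayout, cp: CompoundPattern,
                  dt: float, noise: NoiseModel = NOISELESS,
                  shot_key: int = 0) -> ShotRecord:
    """Simulate one DMD shot: ``G[i, ℓ] = ζ^(i)ᵀ X^(i)_{·,ℓ} Δt`` (+ noise)."""
    if cp.b < 2:
        raise ValueError("bit depth must be >= 2")
    return _record_shot(m, layout, cp, dt, noise, shot_key)


def extract_measurements(shots: list[ShotRecord],
                         offsets: list[ShotRecord]) -> np.ndarray:
    """Undo the DMD affine mapping: corrected projections pᵀX per shot/track.

    Returns an array of shape ``(n_shots, nτ, nc)`` whose entry
    ``[k, i, ℓ]`` estimates the signed projection of channel ℓ of track i
    onto the pattern realized in shot k.  The offset record is the
    entrywise mean over all supplied offset shots.
    """
    if not offsets:
        raise ValueError("at least one offset shot is required")
    dts = {s.dt for s in shots} | {s.dt for s in offsets}
    if len(dts) > 1:
        raise ValueError("all shots must share the same integration time")
    dt = dts.pop()
    G_offset = np.mean([s.G for s in offsets], axis=0)
    out = np.empty((len(shots), *G_offset.shape))
    for k, shot in enumerate(shots):
        if shot.pattern is None:
            raise ValueError("shot record carries no pattern; cannot correct")
        b = shot.pattern.b
        factor = (2**b - 1) / ((2 ** (b - 1) - 1) * dt)
        for i, sp in enumerate(shot.pattern.subpatterns):
            if sp.is_offset or sp.scale is None:
                out[k, i] = np.nan  # idle track: no signed pattern to invert
            else:
                out[k, i] = factor * sp.scale * (shot.G[i] - G_offset[i])
    return out


def full_sampling_acquire(m: SceneMatrix, layout: TrackLayout, dt: float,
                          noise: NoiseModel = NOISELESS
                          ) -> tuple[Scene, pd.DataFrame]:
    """Multitrack point-scan: one pixel per track per shot, np/nτ shots.

    1-bit delta patterns select a single within-track pixel; all tracks scan
    in parallel.  The estimate is simply counts/Δt — no reconstruction step.
    """
    n_shots = layout.pixels_per_track
    Xhat = np.empty_like(m.X)
    log = []
    for s in range(n_shots):
        subs = [Subpattern(zeta=_delta(layout.pixels_per_track, s), b=1)
                for _ in range(layout.n_tracks)]
        cp = CompoundPattern(subpatterns=subs, label=("delta", s))
        rec = _record_shot(m, layout, cp, dt, noise, shot_key=s)
        for i in range(layout.n_tracks):
            start, _ = layout.pixel_range(i)
            Xhat[start + s] = np.maximum(rec.G[i] / dt - noise.alpha, 0.0)
        log.append({"shot": s, "label": f"delta:{s}", "is_offset": False})
    scene = matrix_to_cube(SceneMatrix(X=Xhat, nh=m.nh, nw=m.nw))
    return scene, pd.DataFrame(log)


def _delta(n: int, k: int) -> np.ndarray:
    z = np.zeros(n)
    z[k] = 1.0
    return z


@dataclass
class TimingModel:
    """Acquisition/total time accounting.

    Defaults follow a desk DMD+spectrometer setup: 0.1 s integration per
    shot, 255 frames/s for 8-bit grayscale patterns (10 638 frames/s for
    1-bit binary patterns, used by full sampling).  ``reconstruction_time``
    is a measured input, not something the model predicts.
    """

    dt: float = 0.1
    pattern_switch_rate: float = 255.0
    pattern_load_time: float = 0.0
    predict_time: float = 0.0
    reconstruction_time: float = 0.0

    BINARY_SWITCH_RATE = 10638.0
    GRAYSCALE_SWITCH_RATE = 255.0

    def __post_init__(self) -> None:
        if min(self.dt, self.pattern_switch_rate) < 0 or min(
            self.pattern_load_time, self.predict_time, self.reconstruction_time
        ) < 0:
            raise ValueError("timing components must be >= 0")


def acquisition_time(t: TimingModel, n_shots: int, n_patterns: int) -> dict:
    """Total-time breakdown: integration + pattern handling + reconstruction."""
    if n_shots < 0 or n_patterns < 0:
        raise ValueError("shot/pattern counts must be >= 0")
    integration = n_shots * t.dt
    pattern = n_patterns / t.pattern_switch_rate + t.pattern_load_time + t.predict_time
    total = integration + pattern + t.reconstruction_time
    return {
        "integration_time": integration,
        "pattern_time": pattern,
        "reconstruction_time": t.reconstruction_time,
        "total_time": total,
    }
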