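"""Multitrack adaptive basis scan with wavelet prediction (ABS-WP).

The algorithm progressively measures the 2D Haar coefficients of every
spectral slice, guided by predictions from coarser scales, and acquires up
to nτ coefficients per shot by combining one Haar subpattern per track into
a compound DMD pattern:

1. measure *all* level-J approximation coefficients (in parallel batches,
   one coefficient per track per shot);
2. for j = J … 1: reconstruct the scale-j approximation image from
   everything measured so far, bin the channels to grayscale, bicubic
   ×2-per-axis oversample, and one-level Haar transform the result — the
   three detail subbands are the predicted scale-j coefficients;
3. route the predicted indices to per-track sub-queues sorted by descending
   predicted magnitude, keep the top p_j percent of each queue, zero the
   rest, and measure the retained ones with compound patterns (exhausted
   queues idle on the constant offset subpattern);
4. finish with an inverse Haar transform of the coefficient store per
   channel.

With every p_j = 100 and no noise this is a complete orthonormal transform
measured coefficient-by-coefficient, so reconstruction is exact to float
roundoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from skimage.transform import resize

from .acquisition import (CompoundPattern, NOISELESS, NoiseModel, ShotRecord,
                          Subpattern, TimingModel, TrackLayout,
                          acquisition_time, extract_measurements,
                          make_offset_compound, realize_subpattern,
                          simulate_shot)
from .datacube import Scene, SceneMatrix, matrix_to_cube, unroll_slice
from .haar import (CoefficientStore, WaveletIndex, approx_indices,
                   detail_indices, haar_pattern, supporting_track,
                   ORIENT_ORDER)

__all__ = ["SamplingSchedule", "SubQueues", "AdaptiveResult",
           "measure_coefficient_batch", "predict_details", "build_subqueues",
           "form_compound_patterns", "abswp_multitrack"]


@dataclass
class SamplingSchedule:
    """Decomposition level J and per-scale sampling percentages p_J … p_1.

    ``percentages[0]`` applies to the coarsest detail scale (j = J),
    ``percentages[-1]`` to the finest (j = 1).  The compound-pattern
    construction requires every Haar support (up to 2ᴶ pixels wide) to fit
    inside a track: 2ᴶ must divide the track width.
    """

    J: int
    percentages: tuple[float, ...]

    def __post_init__(self) -> None:
        self.percentages = tuple(float(p) for p in self.percentages)
        if self.J < 1:
            raise ValueError("decomposition level must be >= 1")
        if len(self.percentages) != self.J:
            raise ValueError(f"need {self.J} percentages (p_J … p_1)")
        if any(not 0 <= p <= 100 for p in self.percentages):
            raise ValueError("percentages must lie in [0, 100]")

    def percentage_for(self, j: int) -> float:
        return self.percentages[self.J - j]

    def validate_for(self, layout: TrackLayout) -> None:
        blk = 2**self.J
        if blk > layout.track_width or layout.track_width % blk:
            raise ValueError(
                f"2^J = {blk} does not fit/divide the track width "
                f"{layout.track_width}; lower J or use fewer tracks"
            )
        if layout.nh % blk:
            raise ValueError(f"scene height {layout.nh} not divisible by 2^J = {blk}")


@dataclass
class SubQueues:
    """Per-track ordered lists of retained wavelet indices at one scale."""

    scale: int
    queues: list[list[WaveletIndex]]

    @property
    def max_length(self) -> int:
        return max((len(q) for q in self.queues), default=0)


@dataclass
class AdaptiveResult:
    scene: Scene
    store: CoefficientStore
    shot_log: pd.DataFrame
    n_shots: int
    sampling_ratio: float
    timing: dict = field(default_factory=dict)


def _subpattern_for(idx: WaveletIndex, layout: TrackLayout, b: int) -> Subpattern:
    """Realize the track-local slice of a Haar pattern as a b-bit subpattern."""
    track = supporting_track(idx, layout)
    full = haar_pattern(idx, layout.nh, layout.nw)
    tw = layout.track_width
    local = full[:, track * tw:(track + 1) * tw]
    sp = realize_subpattern(unroll_slice(local), b)
    return sp


def measure_coefficient_batch(m_scene: SceneMatrix, layout: TrackLayout,
                              batch: list[WaveletIndex],
                              offsets: list[ShotRecord], b: int = 8,
                              dt: float = 0.1, noise: NoiseModel = NOISELESS,
                              shot_key: int = 0
                              ) -> tuple[dict[WaveletIndex, np.ndarray], ShotRecord]:
    """Measure up to nτ wavelet coefficients (all channels) in one shot.

    The batch indices must have pairwise distinct supporting tracks; tracks
    without an index idle on the offset subpattern and their detector rows
    are discarded.
    """
    by_track: dict[int, WaveletIndex] = {}
    for idx in batch:
        t = supporting_track(idx, layout)
        if t in by_track:
            raise ValueError(f"two indices share supporting track {t}")
        by_track[t] = idx
    offset_cp = make_offset_compound(layout, b)
    subs = []
    for i in range(layout.n_tracks):
        if i in by_track:
            subs.append(_subpattern_for(by_track[i], layout, b))
        else:
            subs.append(offset_cp.subpatterns[i])
    cp = CompoundPattern(subpatterns=subs, label=tuple(batch))
    rec = simulate_shot(m_scene, layout, cp, dt, noise, shot_key=shot_key)
    corrected = extract_measurements([rec], offsets)[0]  # (nτ, nc)
    out = {idx: corrected[t] for t, idx in by_track.items()}
    return out, rec


def predict_details(store: CoefficientStore, j: int) -> dict[str, np.ndarray]:
    """Predict the magnitudes of the scale-j detail coefficients.

    Inverse-transforms the measured/zeroed coefficients coarser than j into
    the scale-j approximation image, averages the channels to grayscale,
    bicubic-oversamples ×2 per axis (×4 in pixel count) and applies a
    one-level 2D Haar transform; the detail subbands land exactly on the
    scale-j coefficient grid.
    """
    if not 1 <= j <= store.J:
        raise ValueError(f"scale {j} out of range")
    for jj in range(store.J, j, -1):
        for o in ("h", "v", "d"):
            if (store.status[(o, jj)] == 0).any():
                raise ValueError(f"coefficients at scale {jj} still pending")
    if (store.status[("a", store.J)] == 0).any():
        raise ValueError("approximation coefficients still pending")

    gray = np.mean([store.approx_image(j, ell) for ell in range(store.nc)], axis=0)
    up = resize(gray, (gray.shape[0] * 2, gray.shape[1] * 2), order=3,
                mode="edge", anti_aliasing=False)
    _, (cH, cV, cD) = pywt.dwt2(up, "haar", mode="periodization")
    return {"h": cH, "v": cV, "d": cD}


def build_subqueues(predictions: dict[str, np.ndarray],
                    schedule: SamplingSchedule, layout: TrackLayout, j: int,
                    store: CoefficientStore | None = None) -> SubQueues:
    """Route scale-j detail indices to per-track queues and retain top p_j.

    Queues are sorted by descending predicted magnitude (ties broken by
    orientation H, V, D then raster position); the top ceil(p_j% · queue
    length) survive, the rest are marked zeroed in the store.
    """
    p = schedule.percentage_for(j)
    entries: dict[int, list[tuple]] = {i: [] for i in range(layout.n_tracks)}
    for idx in detail_indices(layout.nh, layout.nw, j):
        mag = abs(float(predictions[idx.orientation][idx.row, idx.col]))
        t = supporting_track(idx, layout)
        entries[t].append((-mag, ORIENT_ORDER[idx.orientation], idx.row, idx.col, idx))
    queues: list[list[WaveletIndex]] = []
    for i in range(layout.n_tracks):
        entries[i].sort()
        keep = math.ceil(p / 100.0 * len(entries[i]))
        retained = [e[-1] for e in entries[i][:keep]]
        queues.append(retained)
        if store is not None:
            for e in entries[i][keep:]:
                store.set_zeroed(e[-1])
    return SubQueues(scale=j, queues=queues)


def form_compound_patterns(queues: SubQueues, layout: TrackLayout, b: int = 8
                           ) -> list[tuple[CompoundPattern, list[WaveletIndex | None]]]:
    """Combine the r-th entry of every sub-queue into the r-th compound pattern.

    Exhausted queues contribute the constant offset subpattern; the
    detector rows of those idle tracks carry no coefficient and are
    discarded downstream.
    """
    offset_cp = make_offset_compound(layout, b)
    out = []
    for r in range(queues.max_length):
        subs, active = [], []
        for i in range(layout.n_tracks):
            if r < len(queues.queues[i]):
                idx = queues.queues[i][r]
                subs.append(_subpattern_for(idx, layout, b))
                active.append(idx)
            else:
                subs.append(offset_cp.subpatterns[i])
                active.append(None)
        out.append((CompoundPattern(subpatterns=subs, label=("detail", queues.scale, r)),
                    active))
    return out


def abswp_multitrack(m_scene: SceneMatrix, layout: TrackLayout,
                     schedule: SamplingSchedule, b: int = 8, dt: float = 0.1,
                     noise: NoiseModel = NOISELESS,
                     timing: TimingModel | None = None) -> AdaptiveResult:
    """Run the full multitrack ABS-WP acquisition + reconstruction."""
    schedule.validate_for(layout)
    if (m_scene.nh, m_scene.nw) != (layout.nh, layout.nw):
        raise ValueError("scene dims do not match layout")
    nh, nw, nc = layout.nh, layout.nw, m_scene.nc
    J = schedule.J
    store = CoefficientStore(nh, nw, nc, J)
    log: list[dict] = []

    # offset shots (averaged; reused for every subsequent extraction)
    offset_cp = make_offset_compound(layout, b)
    offsets = []
    for r in range(noise.offset_shot_repeats):
        rec = simulate_shot(m_scene, layout, offset_cp, dt, noise,
                            shot_key=1_000_000 + r)
        offsets.append(rec)
        log.append({"shot": len(log), "label": "offset", "scale": None,
                    "is_offset": True})

    # Step 1: all approximation coefficients, round-robin one per track
    per_track: list[list[WaveletIndex]] = [[] for _ in range(layout.n_tracks)]
    for idx in approx_indices(nh, nw, J):
        per_track[supporting_track(idx, layout)].append(idx)
    n_batches = max(len(q) for q in per_track)
    for t in range(n_batches):
        batch = [q[t] for q in per_track if t < len(q)]
        values, _ = measure_coefficient_batch(
            m_scene, layout, batch, offsets, b, dt, noise,
            shot_key=2_000_000 + t)
        for idx, vec in values.items():
            store.set_measured(idx, vec)
        log.append({"shot": len(log), "label": f"approx:{t}", "scale": J,
                    "is_offset": False})

    # prediction + acquisition cycles, coarse to fine
    for j in range(J, 0, -1):
        predictions = predict_details(store, j)
        queues = build_subqueues(predictions, schedule, layout, j, store)
        for r, (cp, active) in enumerate(form_compound_patterns(queues, layout, b)):
            rec = simulate_shot(m_scene, layout, cp, dt, noise,
                                shot_key=3_000_000 + j * 100_000 + r)
            corrected = extract_measurements([rec], offsets)[0]
            for i, idx in enumerate(active):
                if idx is not None:
                    store.set_measured(idx, corrected[i])
            log.append({"shot": len(log), "label": f"detail:{j}:{r}", "scale": j,
                        "is_offset": False})

    cube = np.clip(store.reconstruct(), 0.0, None)
    scene = Scene(values=cube)
    shot_log = pd.DataFrame(log)
    n_shots = len(shot_log)
    counts = store.counts()
    ratio = counts["measured"] / (nh * nw)
    timing = timing or TimingModel(dt=dt)
    breakdown = acquisition_time(timing, n_shots=n_shots, n_patterns=n_shots)
    return AdaptiveResult(scene=scene, store=store, shot_log=shot_log,
                          n_shots=n_shots, sampling_ratio=ratio,
                          timing=breakdown)
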