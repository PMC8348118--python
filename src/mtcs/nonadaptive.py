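"""Multitrack non-adaptive compressed sensing: Bernoulli plans + TV recovery.

Each track i gets its own measurement matrix Φ^(i) with i.i.d. entries
±1/m^(i) (equal probability); shot k displays row k of every track's matrix
simultaneously as one compound pattern.  The global sensing operator is the
block-diagonal stack of the Φ^(i), and reconstruction solves a 2D
anisotropic-TV minimization per spectral channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .acquisition import (CompoundPattern, NoiseModel, NOISELESS, ShotRecord,
                          TrackLayout, extract_measurements,
                          make_offset_compound, realize_subpattern,
                          simulate_shot)
from .datacube import Scene, SceneMatrix, matrix_to_cube
from .tv import TVInfo, TVOptions, TVSolver

__all__ = ["BernoulliPlan", "TVOptions", "make_plan", "assemble_block_diagonal",
           "acquire_nonadaptive", "reconstruct_tv"]


@dataclass
class BernoulliPlan:
    """A seeded per-track Bernoulli measurement plan.

    Matrices are regenerated on demand from (seed, track index), so plans
    serialize as a few integers rather than dense arrays.  All tracks share
    the same number of rows m.
    """

    layout: TrackLayout
    m: int
    seed: int

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("need at least one measurement per track")
        if self.m > self.layout.pixels_per_track:
            raise ValueError("cannot take more measurements than pixels per track")

    @property
    def r_sampling(self) -> float:
        return self.m / self.layout.pixels_per_track

    def phi(self, i: int) -> np.ndarray:
        """Materialize Φ^(i), shape (m, np/nτ), entries ±1/m equiprobable."""
        if not 0 <= i < self.layout.n_tracks:
            raise IndexError(f"track {i} out of range")
        rng = np.random.default_rng([self.seed, i])
        signs = rng.integers(0, 2, size=(self.m, self.layout.pixels_per_track)) * 2 - 1
        return signs / self.m

    def total_shots(self, offset_repeats: int = 1) -> int:
        """Measurement shots plus offset shots."""
        return self.m + offset_repeats


def make_plan(layout: TrackLayout, r_sampling: float | None = None,
              seed: int = 0, m: int | None = None) -> BernoulliPlan:
    """Build a plan from a sampling ratio, or directly from m rows per track."""
    if (r_sampling is None) == (m is None):
        raise ValueError("specify exactly one of r_sampling and m")
    if m is None:
        if not 0 < r_sampling <= 1:
            raise ValueError("sampling ratio must be in (0, 1]")
        m = round(r_sampling * layout.pixels_per_track)
        if m < 1:
            raise ValueError("sampling ratio yields fewer than one measurement")
    return BernoulliPlan(layout=layout, m=m, seed=seed)


def assemble_block_diagonal(plan: BernoulliPlan) -> sp.csr_matrix:
    """The global sensing matrix Φ = diag(Φ^(1), …, Φ^(nτ))."""
    return sp.block_diag(
        [plan.phi(i) for i in range(plan.layout.n_tracks)], format="csr"
    )


def acquire_nonadaptive(m_scene: SceneMatrix, plan: BernoulliPlan, b: int = 8,
                        dt: float = 0.1, noise: NoiseModel = NOISELESS
                        ) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate the full non-adaptive acquisition.

    Returns ``Y`` of shape ``(nτ, m, nc)`` — the corrected projections
    Φ^(i)X^(i) per track — and the shot log.
    """
    layout = plan.layout
    if (m_scene.nh, m_scene.nw) != (layout.nh, layout.nw):
        raise ValueError("scene dims do not match plan layout")
    phis = [plan.phi(i) for i in range(layout.n_tracks)]

    log = []
    offset_cp = make_offset_compound(layout, b)
    offsets = []
    for r in range(noise.offset_shot_repeats):
        rec = simulate_shot(m_scene, layout, offset_cp, dt, noise,
                            shot_key=1_000_000 + r)
        offsets.append(rec)
        log.append({"shot": len(log), "label": "offset", "is_offset": True})

    shots: list[ShotRecord] = []
    for k in range(plan.m):
        subs = [realize_subpattern(phis[i][k], b) for i in range(layout.n_tracks)]
        cp = CompoundPattern(subpatterns=subs, label=("bernoulli", k))
        shots.append(simulate_shot(m_scene, layout, cp, dt, noise, shot_key=k))
        log.append({"shot": len(log), "label": f"bernoulli:{k}", "is_offset": False})

    corrected = extract_measurements(shots, offsets)  # (m, nτ, nc)
    Y = np.swapaxes(corrected, 0, 1)  # (nτ, m, nc)
    return Y, pd.DataFrame(log)


def reconstruct_tv(Y: np.ndarray, plan: BernoulliPlan,
                   opts: TVOptions | None = None,
                   solver: TVSolver | None = None
                   ) -> tuple[Scene, list[TVInfo]]:
    """Per-channel anisotropic-TV reconstruction from block-CS measurements.

    ``Y`` has shape ``(nτ, m, nc)`` as returned by
    :func:`acquire_nonadaptive`.  Channels are reconstructed independently
    against the block-diagonal operator; non-convergence is flagged on the
    per-channel info objects, not raised.  A prebuilt :class:`TVSolver`
    (for this plan) may be supplied to reuse its factorizations across
    repeated reconstructions.
    """
    layout = plan.layout
    Y = np.asarray(Y, dtype=float)
    if Y.shape[:2] != (layout.n_tracks, plan.m):
        raise ValueError(
            f"Y has shape {Y.shape}, expected ({layout.n_tracks}, {plan.m}, nc)"
        )
    if solver is None:
        solver = TVSolver(assemble_block_diagonal(plan), layout.nh, layout.nw,
                          opts or TVOptions())
    # track-major stacking of measurement rows matches the block order of Φ
    Ystack = Y.reshape(layout.n_tracks * plan.m, Y.shape[2])
    Xhat, infos = solver.solve_multi(Ystack)
    # reconstructed intensities are physical photon rates
    scene = matrix_to_cube(SceneMatrix(X=np.clip(Xhat, 0.0, None),
                                       nh=layout.nh, nw=layout.nw))
    return scene, infos
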