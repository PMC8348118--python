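"""Orthonormal 2D Haar patterns, wavelet indexing and the coefficient store.

A level-j Haar basis function, viewed as an ``nh × nw`` pattern, is
supported on one ``2ʲ × 2ʲ`` dyadic block and has entries ±2⁻ʲ
(approximation at level J: +2⁻ᴶ).  The sign convention matches the
separable Haar DWT with periodization as computed by PyWavelets, which
serves as the independent oracle and as the inverse-transform engine:

* ``'h'`` (horizontal detail): +2⁻ʲ on the top half rows of the block,
  −2⁻ʲ on the bottom half;
* ``'v'`` (vertical detail): +2⁻ʲ on the left half columns, −2⁻ʲ right;
* ``'d'`` (diagonal detail): sign + on top-left/bottom-right quadrants;
* ``'a'`` (approximation): +2⁻ᴶ everywhere on the block.

Because each support is a single dyadic block, a pattern is wholly
contained in one vertical track whenever the track width is a multiple of
the support size — the property that lets one subpattern per track sample
one coefficient per track in a single shot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .acquisition import TrackLayout

__all__ = ["WaveletIndex", "CoefficientStore", "haar_pattern",
           "supporting_track", "approx_indices", "detail_indices"]

ORIENTATIONS = ("a", "h", "v", "d")
# deterministic tie-break order for equal predicted magnitudes
ORIENT_ORDER = {"h": 0, "v": 1, "d": 2}

PENDING, MEASURED, ZEROED = 0, 1, 2


@dataclass(frozen=True, order=True)
class WaveletIndex:
    """One 2D Haar basis function: scale, orientation and dyadic position."""

    level: int
    orientation: str
    row: int
    col: int

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.level < 1:
            raise ValueError("level must be >= 1")
        if self.row < 0 or self.col < 0:
            raise ValueError("grid position must be non-negative")

    @property
    def support(self) -> int:
        """Side length of the (square) support in pixels."""
        return 2**self.level


def _check_dims(nh: int, nw: int, level: int) -> None:
    blk = 2**level
    if nh % blk or nw % blk:
        raise ValueError(
            f"dims ({nh}, {nw}) not divisible by 2^{level}; Haar level invalid"
        )


def haar_pattern(idx: WaveletIndex, nh: int, nw: int) -> np.ndarray:
    """The full ``nh × nw`` orthonormal Haar pattern for one index."""
    _check_dims(nh, nw, idx.level)
    blk = idx.support
    if not (0 <= idx.row < nh // blk and 0 <= idx.col < nw // blk):
        raise ValueError(f"index {idx} out of range for dims ({nh}, {nw})")
    amp = 2.0 ** (-idx.level)
    tile = np.full((blk, blk), amp)
    half = blk // 2
    if idx.orientation == "h":
        tile[half:, :] *= -1
    elif idx.orientation == "v":
        tile[:, half:] *= -1
    elif idx.orientation == "d":
        tile[half:, :half] *= -1
        tile[:half, half:] *= -1
    pattern = np.zeros((nh, nw))
    pattern[idx.row * blk:(idx.row + 1) * blk, idx.col * blk:(idx.col + 1) * blk] = tile
    return pattern


def supporting_track(idx: WaveletIndex, layout: TrackLayout) -> int:
    """The unique track wholly containing the pattern's support."""
    blk = idx.support
    col0 = idx.col * blk
    t0 = layout.track_of_column(col0)
    t1 = layout.track_of_column(col0 + blk - 1)
    if t0 != t1:
        raise ValueError(
            f"support of {idx} straddles tracks {t0} and {t1}; "
            f"requires track width divisible by 2^{idx.level}"
        )
    return t0


def approx_indices(nh: int, nw: int, J: int) -> list[WaveletIndex]:
    """All level-J approximation indices in raster order."""
    _check_dims(nh, nw, J)
    blk = 2**J
    return [WaveletIndex(J, "a", r, c)
            for r in range(nh // blk) for c in range(nw // blk)]


def detail_indices(nh: int, nw: int, j: int) -> list[WaveletIndex]:
    """All level-j detail indices (orientations H, V, D) in raster order."""
    _check_dims(nh, nw, j)
    blk = 2**j
    return [WaveletIndex(j, o, r, c)
            for o in ("h", "v", "d")
            for r in range(nh // blk) for c in range(nw // blk)]


class CoefficientStore:
    """Per-channel Haar coefficients with measured/zeroed/pending status.

    Values are kept in PyWavelets' ``wavedec2`` layout (approximation at
    level J plus three detail subbands per level); status is shared across
    channels because a single shot measures one coefficient for every
    channel at once.
    """

    def __init__(self, nh: int, nw: int, nc: int, J: int):
        _check_dims(nh, nw, J)
        self.nh, self.nw, self.nc, self.J = nh, nw, nc, J
        self.values: dict[tuple[str, int], np.ndarray] = {}
        self.status: dict[tuple[str, int], np.ndarray] = {}
        hJ, wJ = nh >> J, nw >> J
        self.values[("a", J)] = np.zeros((nc, hJ, wJ))
        self.status[("a", J)] = np.full((hJ, wJ), PENDING, dtype=np.int8)
        for j in range(J, 0, -1):
            hj, wj = nh >> j, nw >> j
            for o in ("h", "v", "d"):
                self.values[(o, j)] = np.zeros((nc, hj, wj))
                self.status[(o, j)] = np.full((hj, wj), PENDING, dtype=np.int8)

    def _key(self, idx: WaveletIndex) -> tuple[str, int]:
        key = (idx.orientation, idx.level)
        if key not in self.values:
            raise KeyError(f"{idx} not representable at decomposition level {self.J}")
        return key

    def set_measured(self, idx: WaveletIndex, per_channel: np.ndarray) -> None:
        key = self._key(idx)
        per_channel = np.asarray(per_channel, dtype=float)
        if per_channel.shape != (self.nc,):
            raise ValueError(f"expected {self.nc} channel values")
        self.values[key][:, idx.row, idx.col] = per_channel
        self.status[key][idx.row, idx.col] = MEASURED

    def set_zeroed(self, idx: WaveletIndex) -> None:
        key = self._key(idx)
        self.values[key][:, idx.row, idx.col] = 0.0
        self.status[key][idx.row, idx.col] = ZEROED

    def status_of(self, idx: WaveletIndex) -> int:
        key = self._key(idx)
        return int(self.status[key][idx.row, idx.col])

    def counts(self) -> dict[str, int]:
        measured = sum(int((s == MEASURED).sum()) for s in self.status.values())
        zeroed = sum(int((s == ZEROED).sum()) for s in self.status.values())
        pending = sum(int((s == PENDING).sum()) for s in self.status.values())
        return {"measured": measured, "zeroed": zeroed, "pending": pending}

    def _coeff_list(self, ell: int, down_to: int = 1) -> list:
        """PyWavelets coefficient list [cA_J, (H,V,D)_J, …, (H,V,D)_down_to]."""
        out: list = [self.values[("a", self.J)][ell]]
        for j in range(self.J, down_to - 1, -1):
            out.append(tuple(self.values[(o, j)][ell] for o in ("h", "v", "d")))
        return out

    def approx_image(self, j: int, ell: int) -> np.ndarray:
        """Scale-j approximation image from coefficients coarser than j."""
        if not 0 <= j <= self.J:
            raise ValueError(f"scale {j} out of range")
        if j == self.J:
            return self.values[("a", self.J)][ell].copy()
        coeffs = self._coeff_list(ell, down_to=j + 1)
        return pywt.waverec2(coeffs, "haar", mode="periodization")

    def reconstruct(self) -> np.ndarray:
        """Inverse 2D Haar transform per channel; shape (nh, nw, nc)."""
        pend = self.counts()["pending"]
        if pend:
            raise ValueError(f"{pend} coefficients still pending; cannot reconstruct")
        out = np.empty((self.nh, self.nw, self.nc))
        for ell in range(self.nc):
            out[:, :, ell] = pywt.waverec2(self._coeff_list(ell), "haar",
                                           mode="periodization")
        return out
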