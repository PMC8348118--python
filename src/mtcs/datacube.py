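"""Hyperspectral datacube containers, I/O and synthetic scene generation.

A hyperspectral scene is a non-negative 3D array of shape ``(nh, nw, nc)``
— two spatial axes (height, width) and one spectral axis — with values in
photons s⁻¹ voxel⁻¹.  For the linear-algebra of the acquisition model the
cube is unrolled into the ``np × nc`` matrix ``X`` whose column ``ℓ`` is the
spatial slice at channel ``ℓ`` raveled column-major (row index fastest:
``p = row + nh·col``).  That unrolling order is a package-wide convention;
every module relies on it.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile

__all__ = [
    "Scene",
    "SceneMatrix",
    "SceneSpec",
    "cube_to_matrix",
    "matrix_to_cube",
    "generate_scene",
    "read_cube",
    "write_cube",
]


@dataclass
class Scene:
    """A hyperspectral datacube with optional wavelength axis.

    Parameters
    ----------
    values
        Array of shape ``(nh, nw, nc)``, non-negative intensities in
        photons s⁻¹ voxel⁻¹.
    wavelengths
        Optional per-channel axis labels (nm or cm⁻¹), strictly monotone,
        length ``nc``.  Metadata only; no algorithm depends on it.
    """

    values: np.ndarray
    wavelengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"scene must be 3D (nh, nw, nc), got shape {self.values.shape}")
        if min(self.values.shape) < 1:
            raise ValueError("all scene dimensions must be >= 1")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("scene values must be finite and non-negative")
        if self.wavelengths is not None:
            self.wavelengths = np.asarray(self.wavelengths, dtype=float)
            if self.wavelengths.shape != (self.nc,):
                raise ValueError("wavelengths must have length nc")
            d = np.diff(self.wavelengths)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError("wavelengths must be strictly monotone")

    @property
    def nh(self) -> int:
        return self.values.shape[0]

    @property
    def nw(self) -> int:
        return self.values.shape[1]

    @property
    def nc(self) -> int:
        return self.values.shape[2]

    @property
    def n_pixels(self) -> int:
        return self.nh * self.nw


@dataclass
class SceneMatrix:
    """The unrolled ``np × nc`` scene matrix X plus its original spatial dims."""

    X: np.ndarray
    nh: int
    nw: int

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2D")
        if self.X.shape[0] != self.nh * self.nw:
            raise ValueError(
                f"X has {self.X.shape[0]} rows, expected nh*nw = {self.nh * self.nw}"
            )

    @property
    def nc(self) -> int:
        return self.X.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.X.shape[0]


def cube_to_matrix(scene: Scene) -> SceneMatrix:
    """Unroll a cube into the scene matrix X (column-major within slices).

    ``X[p, ℓ]`` is the scene value at pixel ``p = row + nh·col`` and
    channel ``ℓ``.
    """
    # Fortran-order ravel of (nh, nw, nc) gives index h + nh*w + nh*nw*c,
    # i.e. each channel's slice unrolled column-major, channels as columns.
    X = scene.values.reshape((scene.n_pixels, scene.nc), order="F")
    return SceneMatrix(X=X.copy(), nh=scene.nh, nw=scene.nw)


def matrix_to_cube(m: SceneMatrix, wavelengths: np.ndarray | None = None) -> Scene:
    """Inverse of :func:`cube_to_matrix`."""
    cube = m.X.reshape((m.nh, m.nw, m.nc), order="F")
    return Scene(values=cube.copy(), wavelengths=wavelengths)


def unroll_slice(img: np.ndarray) -> np.ndarray:
    """Ravel one spatial slice with the package's column-major convention."""
    return np.asarray(img).reshape(-1, order="F")


def roll_slice(vec: np.ndarray, nh: int, nw: int) -> np.ndarray:
    """Inverse of :func:`unroll_slice`."""
    return np.asarray(vec).reshape((nh, nw), order="F")


# ---------------------------------------------------------------------------
# synthetic scenes
# ---------------------------------------------------------------------------


@dataclass
class SceneSpec:
    """Recipe for a synthetic hyperspectral scene.

    ``kind='mosaic'`` emulates macroscopic reflectance scenes: a partition of
    the image into piecewise-constant rectangular regions, each carrying a
    smooth spectrum (Gaussian peaks on a broad baseline).  Such scenes have
    low total variation per spectral slice, the regime in which TV-based
    sparse recovery works.  ``kind='blobs'`` emulates cell-like Raman scenes:
    sparse elliptical supports on a dim background, each blob carrying
    narrowband spectral peaks.
    """

    kind: str = "mosaic"
    nh: int = 64
    nw: int = 64
    nc: int = 8
    n_regions: int = 4
    intensity_scale: float = 5e4
    seed: int = 0
    peak_width_range: tuple[float, float] = (0.03, 0.12)  # fraction of the spectral axis
    n_peaks_range: tuple[int, int] = (1, 3)
    background_level: float = 0.01  # blobs only: fraction of scale

    def __post_init__(self) -> None:
        if min(self.nh, self.nw, self.nc) < 1:
            raise ValueError("scene dimensions must be positive")
        if self.n_regions < 1:
            raise ValueError("need at least one region/blob")
        if self.intensity_scale <= 0:
            raise ValueError("intensity scale must be positive")


def _random_spectrum(rng: np.random.Generator, nc: int, spec: SceneSpec, narrow: bool) -> np.ndarray:
    """Gaussian peaks on a smooth baseline, normalized to max 1."""
    axis = np.linspace(0.0, 1.0, nc)
    lo, hi = spec.peak_width_range
    if narrow:
        lo, hi = lo / 2, max(lo, hi / 3)
    n_peaks = int(rng.integers(spec.n_peaks_range[0], spec.n_peaks_range[1] + 1))
    s = 0.15 + 0.25 * rng.random() * (0.5 + 0.5 * np.cos(2 * np.pi * (axis - rng.random())))
    if narrow:
        s = np.full(nc, 0.02 + 0.05 * rng.random())
    for _ in range(n_peaks):
        center = rng.random()
        width = lo + (hi - lo) * rng.random()
        amp = 0.4 + 0.6 * rng.random()
        s = s + amp * np.exp(-0.5 * ((axis - center) / max(width, 1e-6)) ** 2)
    return s / s.max()


def _bsp_regions(rng: np.random.Generator, nh: int, nw: int, n_regions: int) -> np.ndarray:
    """Partition the image into rectangles by recursive random splits."""
    label = np.zeros((nh, nw), dtype=int)
    rects = [(0, nh, 0, nw)]
    while len(rects) < n_regions:
        # split the largest rectangle that can still be split
        order = np.argsort([-(r1 - r0) * (c1 - c0) for r0, r1, c0, c1 in rects])
        for idx in order:
            r0, r1, c0, c1 = rects[idx]
            can_h = (r1 - r0) >= 2
            can_v = (c1 - c0) >= 2
            if not (can_h or can_v):
                continue
            horizontal = can_h and (not can_v or rng.random() < 0.5)
            if horizontal:
                cut = int(rng.integers(r0 + 1, r1))
                new = [(r0, cut, c0, c1), (cut, r1, c0, c1)]
            else:
                cut = int(rng.integers(c0 + 1, c1))
                new = [(r0, r1, c0, cut), (r0, r1, cut, c1)]
            rects.pop(idx)
            rects.extend(new)
            break
        else:  # nothing splittable: fewer regions than requested
            break
    for i, (r0, r1, c0, c1) in enumerate(rects):
        label[r0:r1, c0:c1] = i
    return label


def generate_scene(spec: SceneSpec) -> Scene:
    """Generate a deterministic synthetic scene from a :class:`SceneSpec`."""
    rng = np.random.default_rng(spec.seed)
    nh, nw, nc = spec.nh, spec.nw, spec.nc
    cube = np.zeros((nh, nw, nc))

    if spec.kind == "mosaic":
        label = _bsp_regions(rng, nh, nw, spec.n_regions)
        n_found = label.max() + 1
        # distinct overall brightness per region keeps spatial contrast
        levels = 0.25 + 0.75 * rng.random(n_found)
        for i in range(n_found):
            s = levels[i] * _random_spectrum(rng, nc, spec, narrow=False)
            cube[label == i, :] = s
    elif spec.kind == "blobs":
        cube += spec.background_level
        rr, cc = np.meshgrid(np.arange(nh), np.arange(nw), indexing="ij")
        for _ in range(spec.n_regions):
            cy = rng.uniform(0.15, 0.85) * nh
            cx = rng.uniform(0.15, 0.85) * nw
            ay = rng.uniform(0.05, 0.2) * nh
            ax = rng.uniform(0.05, 0.2) * nw
            theta = rng.uniform(0, np.pi)
            dy, dx = rr - cy, cc - cx
            u = dy * np.cos(theta) + dx * np.sin(theta)
            v = -dy * np.sin(theta) + dx * np.cos(theta)
            mask = (u / ay) ** 2 + (v / ax) ** 2 <= 1.0
            s = _random_spectrum(rng, nc, spec, narrow=True)
            cube[mask, :] += (0.4 + 0.6 * rng.random()) * s
    else:
        raise ValueError(f"unknown scene kind {spec.kind!r}")

    cube *= spec.intensity_scale / cube.max()
    # guarantee the requested scale exactly despite float rounding
    cube[np.unravel_index(np.argmax(cube), cube.shape)] = spec.intensity_scale
    return Scene(values=cube)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {4: np.float32, 5: np.float64}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def _check_nonneg(cube: np.ndarray, clamp_negative: bool) -> np.ndarray:
    if np.any(cube < 0):
        if clamp_negative:
            cube = np.clip(cube, 0.0, None)
        else:
            raise ValueError(
                "file contains negative intensities; pass clamp_negative=True to clip to zero"
            )
    return cube


def write_cube(scene: Scene, path: str | Path, format: str, *,
               interleave: str = "bsq", dtype: str = "float64") -> None:
    """Write a scene to disk.

    Formats: ``'envi'`` (header ``<path>.hdr`` + raw binary), ``'tiff'``
    (multi-page, one page per channel), ``'hdf5'``/``'npz'`` (datasets
    ``cube`` and ``wavelengths``).
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "envi":
        _write_envi(scene, path, interleave=interleave, dtype=np.dtype(dtype))
    elif fmt == "tiff":
        meta = {"wavelengths": None if scene.wavelengths is None else scene.wavelengths.tolist()}
        pages = np.moveaxis(scene.values.astype(dtype), 2, 0)
        tifffile.imwrite(path, pages, description=json.dumps(meta))
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("cube", data=scene.values.astype(dtype))
            if scene.wavelengths is not None:
                f.create_dataset("wavelengths", data=scene.wavelengths)
    elif fmt == "npz":
        payload = {"cube": scene.values.astype(dtype)}
        if scene.wavelengths is not None:
            payload["wavelengths"] = scene.wavelengths
        np.savez(path, **payload)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_cube(path: str | Path, format: str, *, clamp_negative: bool = False) -> Scene:
    """Read a scene written by :func:`write_cube` (or compatible files)."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "envi":
        cube, wl = _read_envi(path)
    elif fmt == "tiff":
        with tifffile.TiffFile(path) as tf:
            pages = tf.asarray()
            wl = None
            desc = tf.pages[0].description
            if desc:
                try:
                    meta = json.loads(desc)
                    if meta.get("wavelengths") is not None:
                        wl = np.asarray(meta["wavelengths"], dtype=float)
                except (json.JSONDecodeError, AttributeError, TypeError):
                    pass
        if pages.ndim == 2:
            pages = pages[None]
        cube = np.moveaxis(pages, 0, 2)
    elif fmt == "hdf5":
        with h5py.File(path, "r") as f:
            cube = f["cube"][...]
            wl = f["wavelengths"][...] if "wavelengths" in f else None
    elif fmt == "npz":
        with np.load(path) as z:
            cube = z["cube"]
            wl = z["wavelengths"] if "wavelengths" in z.files else None
    else:
        raise ValueError(f"unknown format {format!r}")
    cube = _check_nonneg(np.asarray(cube, dtype=float), clamp_negative)
    return Scene(values=cube, wavelengths=wl)


def _write_envi(scene: Scene, path: Path, *, interleave: str, dtype: np.dtype) -> None:
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unknown interleave {interleave!r}")
    cube = scene.values.astype(dtype)
    # ENVI axis orders: bsq = (bands, lines, samples); bil = (lines, bands,
    # samples); bip = (lines, samples, bands)
    if interleave == "bsq":
        arr = np.moveaxis(cube, 2, 0)
    elif interleave == "bil":
        arr = np.moveaxis(cube, 2, 1)
    else:
        arr = cube
    arr.tofile(path)
    lines = [
        "ENVI",
        f"samples = {scene.nw}",
        f"lines = {scene.nh}",
        f"bands = {scene.nc}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_ENVI_CODES[np.dtype(dtype)]}",
        f"interleave = {interleave}",
        "byte order = 0",
    ]
    if scene.wavelengths is not None:
        wl = ", ".join(f"{w:.6f}" for w in scene.wavelengths)
        lines.append("wavelength = {%s}" % wl)
    Path(str(path) + ".hdr").write_text("\n".join(lines) + "\n")


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    # join brace-delimited multi-line values first
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def _read_envi(path: Path) -> tuple[np.ndarray, np.ndarray | None]:
    hdr_path = Path(str(path) + ".hdr")
    if not hdr_path.exists():
        hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise FileNotFoundError(f"no ENVI header found for {path}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        nw = int(fields["samples"])
        nh = int(fields["lines"])
        nc = int(fields["bands"])
        code = int(fields["data type"])
        interleave = fields.get("interleave", "bsq").lower()
    except KeyError as e:
        raise ValueError(f"malformed ENVI header: missing {e}") from None
    if code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {code}")
    if int(fields.get("byte order", "0")) != 0:
        raise ValueError("big-endian ENVI files are not supported")
    raw = np.fromfile(path, dtype=_ENVI_DTYPES[code])
    if raw.size != nh * nw * nc:
        raise ValueError(
            f"ENVI payload has {raw.size} values, header promises {nh * nw * nc}"
        )
    if interleave == "bsq":
        cube = np.moveaxis(raw.reshape(nc, nh, nw), 0, 2)
    elif interleave == "bil":
        cube = np.moveaxis(raw.reshape(nh, nc, nw), 1, 2)
    elif interleave == "bip":
        cube = raw.reshape(nh, nw, nc)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    wl = None
    if "wavelength" in fields:
        inner = fields["wavelength"].strip().lstrip("{").rstrip("}")
        if inner.strip():
            wl = np.array([float(t) for t in inner.split(",")])
    return cube.copy(), wl
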