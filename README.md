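# mtcs — multitrack compressed-sensing hyperspectral imaging

`mtcs` simulates a hyperspectral camera that splits its field of view into
vertical *tracks* on a digital micromirror device and records one spectrum
per track per shot, and implements the reconstruction methods that make
such an instrument fast:

- a photon-accurate **forward model**: b-bit pattern realization on the
  modulator, constant-offset correction, Poisson shot noise and dark
  current, and an affine acquisition-time model;
- **multitrack full sampling** (one pixel per track per shot — the exact
  but slow baseline);
- **non-adaptive block compressed sensing**: per-track Bernoulli
  measurement matrices and per-channel anisotropic total-variation
  reconstruction (hand-written ADMM solver with equality and penalized
  modes, positivity, and cached factorizations across channels);
- **adaptive basis scan with wavelet prediction**: orthonormal 2D Haar
  coefficients measured one-per-track-per-shot, coarse-to-fine, with
  finer scales predicted from coarser ones and only the top fraction of
  each track's predicted coefficients actually measured;
- **study runners**: four-way method comparison and noise-robustness
  sweeps over illumination, dark current and integration time, plus a
  `mtcs` command-line interface and cube I/O (ENVI, TIFF, HDF5, NPZ).

The model and defaults are documented in [docs/methods.md](docs/methods.md).

## Worked example

Compare the four methods on a synthetic 32×32×4 piecewise-constant scene
(two tracks, Poisson noise, dark current 100 counts/s):

```python
from mtcs import NoiseModel, SamplingSchedule, SceneSpec, run_comparison

spec = SceneSpec(kind="mosaic", nh=32, nw=32, nc=4, n_regions=4,
                 intensity_scale=5e4, seed=7)
noise = NoiseModel(poisson_enabled=True, alpha=100.0, seed=1)
schedule = SamplingSchedule(J=2, percentages=(80.0, 25.0))
table, results = run_comparison(spec, n_tracks=2, dt=0.1, noise=noise,
                                r_sampling=0.2, schedule=schedule, seed=0)
print(table.to_string(index=False))
```

Output:

```
         method   psnr_db  relative_error  n_shots  total_time_s error
           full 40.096533        0.016722      512     51.248129  None
single_adaptive 18.274610        0.206241      420     43.647059  None
    nonadaptive 39.954040        0.016998      112     11.639216  None
       adaptive 21.858137        0.136521      215     22.343137  None
```

Things to notice, all consequences of the model:

- full sampling needs one shot per pixel per track (1024/2 = 512);
- non-adaptive CS reaches essentially the same PSNR from 112 shots
  (20% sampling + 10 offset shots) — a ~4.6× faster acquisition;
- the multitrack adaptive scan uses about half the shots of its
  single-track version (215 vs 420): the parallelization factor is the
  number of tracks, up to sub-queue rounding;
- at this photon level the adaptive scan is noisier than TV-regularized
  non-adaptive CS: each Haar coefficient is measured once, unregularized.
  Its advantage grows with illumination (see the sweep runner).

The same study is available from the shell:

```sh
mtcs compare --config compare.yaml out.csv
```

with `compare.yaml` holding the scene/noise/schedule keys, and sweeps via
`mtcs sweep`. `mtcs simulate`, `mtcs acquire` and `mtcs reconstruct`
expose the generation → acquisition → reconstruction pipeline on files.

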