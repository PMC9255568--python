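# tvdmreg

Rigid (translation + rotation) registration of 2-D grayscale images driven
by the **total variation of the difference map** (TVDM) — a dissimilarity
metric built for images whose noise, contrast and background vary too much
for sum-of-squared-difference or phase-correlation methods to cope with.
The motivating use case is transmission X-ray microscopy energy series
(TXM-XANES), where tens to hundreds of frames taken at different energies
must be mutually aligned to sub-pixel precision before per-pixel spectra
can be extracted, and where frame-to-frame intensity scales, backgrounds
and noise levels all drift.

## The metric

For a target image $I_t$ and a source image $I_s$ under a candidate rigid
transform $T$, the cost is

$$C(T) \;=\; \big\lVert \nabla\, d_m \big\rVert_1, \qquad
d_m = \mathrm{gf}(I_s \circ T, \sigma) - \mathrm{gf}(I_t, \sigma),$$

the anisotropic total variation (L1 norm of the forward-difference
gradient) of the difference map between the Gaussian-smoothed pair
($\sigma = 1$ px by default), accumulated over the valid overlap and
normalized by the number of valid gradient stencils.  Subtracting the
images turns shared structure into a flat background; taking the gradient
annihilates that background — so the cost is *exactly* invariant to
constant intensity offsets and insensitive to smooth background drifts,
while residual edges from misalignment are penalized at full weight.

The transform is found by alternating two searches until stable:

* **translation** — a coarse-to-fine brute-force scan over integer shifts
  on an image pyramid (5 levels, per-level range 8 by default, an overall
  reach of ±64 px), refined to sub-pixel precision by a parabolic fit of
  the cost at the integer optimum;
* **rotation** — a global 1-D search over the angle with differential
  evolution (population 100, crossover 0.7, mutation dithered in
  [0.5, 1)), within user-supplied bounds (±10° around a rough prior
  estimate by default).

A closed form anchors the design: the displacement field of a rigid
transform has total variation $2A(1-\cos\alpha+|\sin\alpha|)$ over an
area $A$, independent of the translation — which is why TV of the
*displacement field* cannot drive rigid registration and the TV of the
*difference map* is used instead.  The package also registers ordered
image series with a chunked-anchor strategy (chunk members → local
anchors → global anchor, transforms composed analytically) and ships a
synthetic-data module that regenerates the benchmark conditions —
phantoms, additive Gaussian noise with non-zero mean, constant offsets,
and sinusoidally modulated noise backgrounds — so every accuracy claim is
testable without any download.

## Worked example

`examples/register_noisy_pair.py` builds a 256×256 phantom pair displaced
by t = (13.5, 21.3) px and rotated 53.9° about the center, adds
independent Gaussian noise N(0.4, 0.4) to each frame — noise whose
magnitude exceeds most of the signal — and runs the registration:

```
truth:     angle =  53.900 deg   t = ( 13.50,  21.30) px
recovered: angle =  53.824 deg   t = ( 13.43,  21.26) px
errors:    0.076 deg, (0.07, 0.04) px
converged in 2 alternation(s); cost fell 0.0954 -> 0.0793
```

The recovered transform is within a tenth of a pixel and a tenth of a
degree of the truth.  The cost falls from its identity-transform value to
the aligned noise floor; the residual difference map is pure noise with
no edge structure.  The other examples demonstrate the metric's exact
offset invariance and robustness to sinusoidal noise bands
(`background_robustness.py`), the metric itself on a toy pair
(`metric_basics.py`), and series alignment with drift tracking across a
crack-like feature (`align_image_series.py`).

A thin command-line layer wraps the same library calls:

```bash
tvdmreg synth --experiment 1 --mu 0.4 --sigma 0.4 --seed 1 --out pair/
tvdmreg register pair/pair.tif pair/pair.tif --out result/
tvdmreg stack series.h5 --anchor 50 --chunk-size 7 --out aligned/
```

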