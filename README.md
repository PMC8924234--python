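# numspec

Numerosity — the number of items in a view — reads out surprisingly
early in the visual system: early visual cortex responds monotonically
to it regardless of item size and spacing, even though V1 neurons code
local contrast at specific orientations and spatial frequencies. This
package implements the image statistic that reconciles the two facts:
the **aggregate Fourier power in the first spatial-frequency harmonic**
of a dot display, which at fixed contrast tracks numerosity as ≈ n^0.47
with little effect of item size, spacing, or shape. It also implements
the accompanying fMRI modelling chain — monotonic (log/linear GLM) and
tuned (logarithmic-Gaussian pRF) response models with split-half
cross-validation, eccentricity-profile fitting with bootstrap, and the
model-comparison statistics — exercised on synthetic stimuli and
simulated voxel cohorts with known ground truth.

It is written for researchers in visual neuroscience and numerical
cognition who want to compute this statistic for their own displays,
test non-numerical feature accounts (area, perimeter, density, convex
hull, RMS contrast, Laplacian-of-Gaussian filter responses), or fit
monotonic/tuned response models to cyclic numerosity fMRI designs.

## The statistic

For a display image I, normalized to 0 on the background and 1 in the
items:

    PSD(k)  = Σ |F(u,v)|   over annuli  k−0.5 < √(u²+v²) ≤ k+0.5 ,  k = 1…N/2
    f₁      = lowest k above the PSD peak with PSD(k) < 0.25·max PSD
              at a local maximum of the PSD's first or second derivative
    power   = Σ_{k ≤ f₁} PSD(k) / (N²·√2)

so one full-contrast circle has power ≈ 1 at any resolution, and an
n-item display has power ≈ n^0.47. Monotonic voxel models convolve a
scaled feature time course with a canonical two-gamma HRF and fit
baseline and β by GLM; tuned models grid-search amplitude
exp(−(ln x − ln μ)²/2σ²) over μ ∈ [1.05, 6.95], σ ∈ [0.05, 2].

## Worked example

```python
import numpy as np
from numspec.stimuli import make_configuration_display, render
from numspec.spectral import aggregate_power

rng = np.random.default_rng(0)
for n in (1, 3, 7):
    spec = make_configuration_display("constant_size", n, rng=rng)
    ap = aggregate_power(render(spec), with_second_harmonic=True)
    print(f"n={n}: power={ap.normalized:.3f}  f1={ap.f1_limit} cycles/image"
          f"  2nd harmonic={ap.second_harmonic_normalized:.3f}")
```

prints

```
n=1: power=0.976  f1=15 cycles/image  2nd harmonic=0.510
n=3: power=1.554  f1=16 cycles/image  2nd harmonic=0.784
n=7: power=2.271  f1=15 cycles/image  2nd harmonic=1.201
```

— power grows sublinearly with numerosity (≈ n^0.47: 1, 1.7, 2.5)
although every item is the same size, the first-harmonic limit stays
set by the item size, and the second harmonic carries about half the
power of the first.

The numbered scripts under `analysis/` run the full simulation suite
(display galleries, power-vs-numerosity and the power-law fit,
size/spacing/shape generalization, contrast and connectedness
manipulations, synthetic-cohort model fitting and eccentricity
statistics) and write their tables under `results/`. A thin CLI mirrors
the stages: `numspec stimgen … | fourier … | features … | simulate … |
fit … | run`.

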