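# gincseg

Level-set image segmentation with embedded bias-field correction, for 2D
grayscale and multichannel images whose intensities are corrupted by a
smooth multiplicative inhomogeneity — the situation typical of MR images
(coil sensitivity profiles) and unevenly lit photographs, where class
intensity histograms overlap and plain thresholding or piecewise-constant
active contours fail.

## The model

The observed image is modelled as

    I(x) = b(x) · J(x) + n(x),

where `J` is piecewise constant (one intensity `c_i` per region `Ω_i`),
`b` is a smooth, slowly varying bias field, and `n` is zero-mean noise.
The bias is expanded in an orthogonal 2D Legendre polynomial basis,
`b(x) = wᵀG(x)`, with `M = (k+1)(k+2)/2` functions at total degree `k`
(15 at the default order 4). Regions are encoded by `Q = ⌈log₂N⌉`
level-set functions `Φ = (φ₁ … φ_Q)` through smooth membership functions
`M_i(Φ)` built from the arctan-smoothed Heaviside `H_ε`. All unknowns
minimise one energy

    E(Φ, C, W) = Σ_i λ_i ∫ e_i(x) M_i(Φ(x)) dx  +  ν·L(Φ)  +  μ·P(Φ),

with per-pixel residuals `e_i(x) = Σ_j γ_j (I_j(x) − w_jᵀG(x) c_ij)²`
summed over channels `j`, an arc-length term `L` that smooths the
zero-level contour, and a distance-regularisation term
`P = ½∫(|∇φ|−1)²` that keeps each `φ` close to a signed distance
function without reinitialisation. Minimisation alternates closed-form
updates of the class intensities `C` and bias coefficients `W` (both
exact least-squares minimisers) with one explicit gradient step on `Φ`
per iteration, stopping when `Σ_ij |Δc_ij| < 0.001`. With the bias
frozen at `b ≡ 1` the model reduces exactly to the Chan–Vese
piecewise-constant model.

Two-phase (`N = 2`), three/four-phase (two level sets) and multichannel
(`L ≥ 1`) variants are provided, together with a synthetic phantom
generator implementing the image model above with known ground truth,
and the standard overlap metrics (Dice coefficient, false positive
ratio, false negative ratio).

## Worked example

```python
import numpy as np
from gincseg import (ModelParams, standard_phantom, segment,
                     relabel_by_intensity, dsc)

phantom = standard_phantom(noise_sigma=5.0, seed=1)   # 128x128, classes 60/140
result = segment(phantom.image, ModelParams(), "threshold", n_regions=2)
labels, C = relabel_by_intensity(result.label_map, result.C_final)
print(f"iterations run : {result.n_iterations} (converged={result.converged})")
print(f"class intensities (sorted): {np.round(C.ravel(), 1)}")
print(f"bias constant term        : {result.W_final[0, 0]:.3f}")
print(f"Dice, background          : {dsc(phantom.labels == 1, labels == 1):.4f}")
print(f"Dice, disc                : {dsc(phantom.labels == 2, labels == 2):.4f}")
```

prints

```
iterations run : 500 (converged=False)
class intensities (sorted): [ 61.9 131.4]
bias constant term        : 1.029
Dice, background          : 1.0000
Dice, disc                : 1.0000
```

The label map matches the ground truth exactly (Dice 1.0) long before
the strict cluster-centre stopping rule fires; at the default 500
iteration cap the rule has not yet triggered (raise `max_iter` to run it
to completion — see `docs/methods.md` on why this criterion is slow).
The fitted class intensities sit a few percent inside the true values
(60/140) because the smooth memberships give each region a small weight
on the other region's pixels.

A command-line interface mirrors the library:

```sh
gincseg phantom --shape 128 128 --sigma 5 --seed 1 --out fixtures/
gincseg segment fixtures/phantom.png --n-regions 2 --out run/
gincseg evaluate fixtures/phantom_labels.png run/labels.png
```

`segment` writes the label map (PNG), per-channel bias field and
bias-corrected image (float32 TIFF), the fitted `C`/`W` matrices
(JSON), the per-iteration energy trace (CSV) and a replayable run
config (JSON).

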