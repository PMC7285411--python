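"""Synthetic phantoms: piecewise-constant scenes times a smooth bias plus noise.

Every phantom follows the multiplicative image model I = b * J + n: a
piecewise-constant true image J (one intensity per region), a smooth bias
field b in the span of the 2D Legendre basis, and i.i.d. zero-mean Gaussian
noise.  Ground truth (label map, bias field, class intensities, basis
coefficients, noise sigma, seed) is stored alongside the image, so
segmentation and bias-correction accuracy can be scored exactly without any
external data.

``REFERENCE_BIAS_COEFFS`` is the package's reference bias: 15 order-4
coefficients producing a smooth field with mean level 1.05 — a realistic,
slowly varying inhomogeneity of roughly ±30% across the frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .basis import BasisStack, build_basis, evaluate_bias

__all__ = [
    "Phantom",
    "REFERENCE_BIAS_COEFFS",
    "make_scene",
    "make_phantom",
    "standard_phantom",
    "histogram_separation",
]

# Reference coefficient set for a smooth order-4 bias field near unit level
# (constant term 1.05), used by the standard fixture.
REFERENCE_BIAS_COEFFS = np.array([
    1.05, -0.05, -0.06, 0.01, 0.01, -0.20, 0.04, 0.12,
    -0.02, 0.02, 0.01, -0.02, 0.05, -0.03, -0.01,
])


@dataclass
class Phantom:
    """A synthetic image with full ground truth.

    image : (L, rows, cols); labels : (rows, cols) int in 1..N;
    bias_true : (L, rows, cols); C_true : (N, L); W_true : (M, L).
    """

    image: np.ndarray
    labels: np.ndarray
    bias_true: np.ndarray
    C_true: np.ndarray
    W_true: np.ndarray
    noise_sigma: float
    seed: int

    @property
    def n_regions(self) -> int:
        return self.C_true.shape[0]

    @property
    def n_channels(self) -> int:
        return self.C_true.shape[1]

    def true_image(self) -> np.ndarray:
        """The noiseless piecewise-constant image J, per channel."""
        return np.stack(
            [self.C_true[self.labels - 1, j] for j in range(self.n_channels)]
        )

    def metadata(self) -> dict:
        return {
            "n_regions": int(self.n_regions),
            "n_channels": int(self.n_channels),
            "C_true": self.C_true.tolist(),
            "W_true": self.W_true.tolist(),
            "noise_sigma": float(self.noise_sigma),
            "seed": int(self.seed),
            "shape": list(self.labels.shape),
        }


def make_scene(
    shape: tuple[int, int],
    n_regions: int,
    geometry: str = "discs",
    seed: int = 0,
) -> np.ndarray:
    """Deterministic ground-truth label map, values 1..n_regions.

    Geometries: ``discs`` (n_regions-1 discs on a background), ``checker``
    (alternating blocks), ``brain_like`` (nested ellipses).  Every region
    covers at least 5% of the pixels.
    """
    rows, cols = shape
    if rows < 32 or cols < 32:
        raise ValueError(f"shape must be >= 32x32, got {shape}")
    if n_regions not in (2, 3, 4):
        raise ValueError(f"n_regions must be 2, 3 or 4, got {n_regions}")
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0:rows, 0:cols]
    labels = np.ones(shape, dtype=np.int32)

    if geometry == "discs":
        # non-overlapping discs at jittered anchor points
        radius = 0.22 * min(rows, cols)
        anchors = [(0.35, 0.35), (0.62, 0.65), (0.30, 0.72)]
        for k in range(n_regions - 1):
            fr, fc = anchors[k]
            r0 = fr * rows + rng.uniform(-0.03, 0.03) * rows
            c0 = fc * cols + rng.uniform(-0.03, 0.03) * cols
            rad = radius * (1.0 + rng.uniform(-0.1, 0.1)) * (0.8 ** k)
            labels[(rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2] = k + 2
    elif geometry == "checker":
        br, bc = rows // 4, cols // 4
        labels = ((rr // br + cc // bc) % n_regions).astype(np.int32) + 1
    elif geometry == "brain_like":
        # nested ellipses: background, outer rim, inner tissue(s)
        r0, c0 = rows / 2, cols / 2
        axes = [(0.42, 0.38), (0.32, 0.28), (0.18, 0.15)]
        for k in range(n_regions - 1):
            ar, ac = axes[k]
            mask = ((rr - r0) / (ar * rows)) ** 2 \
                + ((cc - c0) / (ac * cols)) ** 2 <= 1.0
            labels[mask] = k + 2
    else:
        raise ValueError(f"unknown geometry {geometry!r}")

    counts = np.bincount(labels.ravel(), minlength=n_regions + 1)[1:]
    if (counts < 0.05 * labels.size).any():
        raise ValueError(
            f"geometry {geometry!r} infeasible for {n_regions} regions: "
            f"region sizes {counts.tolist()}"
        )
    return labels


def make_phantom(
    labels: np.ndarray,
    C_true: np.ndarray,
    W_true: np.ndarray,
    noise_sigma: float = 0.0,
    seed: int = 0,
    *,
    basis: BasisStack | None = None,
) -> Phantom:
    """Assemble I = b * J + n from a label map and ground-truth parameters.

    ``C_true`` is (N,) or (N, L); ``W_true`` is (M,) or (M, L) with M
    matching an order-inferable basis (M = (k+1)(k+2)/2).  Noise is i.i.d.
    Gaussian per pixel and channel, drawn from ``default_rng(seed)``.
    """
    labels = np.asarray(labels)
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    C_true = np.atleast_2d(np.asarray(C_true, dtype=float))
    if C_true.shape[0] == 1 and C_true.shape[1] == labels.max():
        C_true = C_true.T  # accept a flat (N,) vector
    W_true = np.asarray(W_true, dtype=float)
    if W_true.ndim == 1:
        W_true = W_true[:, None]
    n_ch = C_true.shape[1]
    if W_true.shape[1] == 1 and n_ch > 1:
        W_true = np.repeat(W_true, n_ch, axis=1)
    if int(labels.max()) != C_true.shape[0]:
        raise ValueError(
            f"label map has {int(labels.max())} regions but C_true has "
            f"{C_true.shape[0]} rows")

    if basis is None:
        m = W_true.shape[0]
        order = int(round((np.sqrt(8 * m + 1) - 3) / 2))
        if (order + 1) * (order + 2) // 2 != m:
            raise ValueError(f"coefficient count {m} is not triangular")
        basis = build_basis(labels.shape, order)

    rng = np.random.default_rng(seed)
    bias = np.stack(
        [evaluate_bias(basis, W_true[:, j]) for j in range(n_ch)])
    true_img = np.stack([C_true[labels - 1, j] for j in range(n_ch)])
    noise = (rng.normal(0.0, noise_sigma, size=bias.shape)
             if noise_sigma > 0 else np.zeros_like(bias))
    return Phantom(
        image=bias * true_img + noise,
        labels=labels.astype(np.int32),
        bias_true=bias,
        C_true=C_true,
        W_true=W_true,
        noise_sigma=float(noise_sigma),
        seed=int(seed),
    )


def standard_phantom(noise_sigma: float = 5.0, seed: int = 1) -> Phantom:
    """The package's standard fixture, version 1.

    128 x 128, two regions (disc on background), class intensities 60 and
    140, bias from :data:`REFERENCE_BIAS_COEFFS`, Gaussian noise.  The
    recommended sigma grid is {0, 5, 15} with seeds {1, 2, 3}.
    """
    labels = make_scene((128, 128), 2, "discs", seed=seed)
    return make_phantom(
        labels, np.array([60.0, 140.0]), REFERENCE_BIAS_COEFFS,
        noise_sigma=noise_sigma, seed=seed,
    )


def histogram_separation(image: np.ndarray, labels: np.ndarray) -> float:
    """Class-overlap statistic: pooled within-class std over min mean gap.

    Zero for a noiseless unbiased phantom; grows as bias and noise smear
    the class histograms together.  Invariant to global intensity scaling.
    Channels are pooled.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = image[None]
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 classes present")
    means, var_sum, n_sum = [], 0.0, 0
    for k in classes:
        vals = image[:, labels == k].ravel()
        means.append(vals.mean())
        var_sum += vals.size * vals.var()
        n_sum += vals.size
    pooled_std = np.sqrt(var_sum / n_sum)
    means = np.sort(np.asarray(means))
    min_gap = float(np.diff(means).min())
    if min_gap == 0:
        return float("inf") if pooled_std > 0 else 0.0
    return float(pooled_std / min_gap)


def save_phantom(phantom: Phantom, directory: str | Path, stem: str = "phantom") -> dict:
    """Write a phantom as 8-bit PNG + labels PNG + JSON sidecar.

    The PNG stores the image linearly rescaled to 0..255; the sidecar
    records the scale so values can be recovered, plus all ground truth.
    Returns the sidecar dict.
    """
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    img = phantom.image
    lo, hi = float(img.min()), float(img.max())
    scale = (hi - lo) or 1.0
    img8 = np.round((img - lo) / scale * 255).astype(np.uint8)
    arr = img8[0] if img8.shape[0] == 1 else np.moveaxis(img8, 0, -1)
    iio.imwrite(directory / f"{stem}.png", arr)
    iio.imwrite(directory / f"{stem}_labels.png",
                phantom.labels.astype(np.uint8))
    sidecar = phantom.metadata() | {
        "image_path": f"{stem}.png",
        "labels_path": f"{stem}_labels.png",
        "intensity_offset": lo,
        "intensity_scale": scale / 255.0,
    }
    with open(directory / f"{stem}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return sidecar
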