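"""Reading images, writing run outputs, and run configuration.

Inputs are ordinary 8/16-bit PNG or TIFF rasters; grayscale loads as a
single channel and RGB as three, always as float arrays on the nominal
0-255 scale with channels first.  Outputs: label maps as indexed PNG,
bias fields and corrected images as float32 TIFF, fitted matrices and
configuration as JSON, traces and metrics as CSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .model import ModelParams
from .segment import SegmentationResult

logger = logging.getLogger("gincseg")

__all__ = ["RunConfig", "read_image", "write_result", "setup_logging"]

_RASTER_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass
class RunConfig:
    """Everything needed to reproduce a segmentation run.

    Round-trips losslessly through JSON (:meth:`to_json` /
    :meth:`from_json`); a saved run can be replayed bit-identically from
    its config alone.
    """

    input_path: str
    n_regions: int = 2
    channel_mode: str = "gray"  # gray | multichannel
    order: int = 4
    lambdas: list[float] = field(default_factory=lambda: [1.0, 1.0])
    mu: float = 1.0
    nu: float = 0.005 * 255 * 255
    epsilon: float = 1.0
    dt: float = 0.1
    gammas: list[float] = field(default_factory=lambda: [1.0])
    a: float = 2.0
    tol: float = 0.001
    max_iter: int = 500
    init_strategy: str = "threshold"
    init_options: dict = field(default_factory=dict)
    output_dir: str = "out"
    seed: int = 0
    verbosity: int = 0

    def model_params(self) -> ModelParams:
        return ModelParams(
            lambdas=tuple(self.lambdas), mu=self.mu, nu=self.nu,
            epsilon=self.epsilon, dt=self.dt, gammas=tuple(self.gammas),
            a=self.a, tol=self.tol, max_iter=self.max_iter,
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def read_image(path: str | Path) -> tuple[np.ndarray, dict]:
    """Load a PNG/TIFF raster as a channels-first float image on 0-255.

    Returns ``(image, meta)`` with image of shape (L, rows, cols) — L = 1
    for grayscale, 3 for RGB (an alpha channel, if present, is dropped) —
    and meta recording the source dtype and the applied scale factor.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    if path.suffix.lower() not in _RASTER_SUFFIXES:
        raise IOError(f"unsupported image format {path.suffix!r}: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"cannot read image {path}: {exc}") from exc
    src_dtype = str(arr.dtype)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    elif arr.ndim == 3:
        if arr.shape[-1] == 4:
            arr = arr[..., :3]
        arr = np.moveaxis(arr, -1, 0)
    else:
        raise IOError(f"unsupported image layout {arr.shape} in {path}")
    arr = arr.astype(float)
    scale = 1.0
    if src_dtype == "uint16":
        scale = 255.0 / 65535.0
        arr = arr * scale
    return arr, {"path": str(path), "dtype": src_dtype, "scale": scale}


def write_result(
    result: SegmentationResult,
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> dict[str, str]:
    """Write all artefacts of a run; returns a name -> path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(name: str) -> Path:
        p = out / name
        paths[name] = str(p)
        return p

    iio.imwrite(_p("labels.png"), result.label_map.astype(np.uint8))
    tifffile.imwrite(_p("bias.tif"),
                     result.bias_fields.astype(np.float32))
    corrected = np.atleast_3d(result.corrected_image)
    if corrected.shape[-1] in (1, 3) and corrected.ndim == 3 \
            and corrected.shape[0] not in (1, 3):
        corrected = np.moveaxis(corrected, -1, 0)
    tifffile.imwrite(_p("corrected.tif"), corrected.astype(np.float32))
    with open(_p("fit.json"), "w") as fh:
        json.dump({"C": result.C_final.tolist(),
                   "W": result.W_final.tolist(),
                   "n_iterations": result.n_iterations,
                   "converged": bool(result.converged)}, fh, indent=2)
    with open(_p("energy_trace.csv"), "w") as fh:
        fh.write("iteration,energy,sum_abs_dC\n")
        for k, (e, dc) in enumerate(
                zip(result.energy_trace, result.c_change_trace), start=1):
            fh.write(f"{k},{e!r},{dc!r}\n")
    if config is not None:
        config.to_json(_p("config.json"))
    return paths


def setup_logging(verbosity: int = 0) -> None:
    """Console logging; -v gives per-iteration energy and sum|dC| lines."""
    level = (logging.WARNING, logging.INFO, logging.DEBUG)[
        min(max(verbosity, 0), 2)]
    logging.basicConfig(
        format="%(levelname)s %(name)s: %(message)s")
    logging.getLogger("gincseg").setLevel(level)
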