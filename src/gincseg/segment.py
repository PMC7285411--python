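"""Alternating-minimisation driver: initialisation, iteration, convergence.

Each iteration performs one exact update of the class intensities C, one
exact update of the bias coefficients W, and one gradient step on the
level-set functions Phi.  Iteration stops when the summed absolute change
of the cluster centres falls below the tolerance (default 0.001) or the
iteration cap is reached.  The solver is deterministic: identical inputs
give bit-identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .basis import BasisStack, build_basis
from .model import (
    DegenerateRegionError,
    FitState,
    LevelSetState,
    ModelParams,
    bias_corrected,
    bias_fields,
    energy,
    memberships,
    n_level_sets,
    residuals,
    update_c,
    update_phi,
    update_w,
    _as_channels,
)

logger = logging.getLogger("gincseg")

__all__ = [
    "SegmentationResult",
    "DegenerateInitializationError",
    "initialize_levelsets",
    "has_converged",
    "segment",
    "labels_from_state",
    "relabel_by_intensity",
]


class DegenerateInitializationError(RuntimeError):
    """An initialisation strategy produced an empty side of a contour."""


@dataclass
class SegmentationResult:
    """Everything a run produces.

    ``label_map`` holds region indices 1..N, the argmax of the final
    membership weights.  ``energy_trace`` has one total-energy value per
    completed iteration; ``substep_trace`` (when recorded) additionally
    holds the energy after the C update and after the W update within each
    iteration.  ``label_history`` (when recorded) holds the label map at
    the end of every iteration.
    """

    label_map: np.ndarray
    final_state: LevelSetState
    C_final: np.ndarray
    W_final: np.ndarray
    bias_fields: np.ndarray
    corrected_image: np.ndarray
    energy_trace: list[float]
    n_iterations: int
    converged: bool
    c_change_trace: list[float] = field(default_factory=list)
    substep_trace: list[dict[str, float]] = field(default_factory=list)
    label_history: list[np.ndarray] = field(default_factory=list)

    @property
    def final_phis(self) -> np.ndarray:
        return self.final_state.phis


def _binarize(mask: np.ndarray, a: float) -> np.ndarray:
    """Level-set function at -a inside the mask, +a outside."""
    return np.where(mask, -a, a).astype(float)


def _check_two_sided(mask: np.ndarray, what: str) -> None:
    if mask.all() or not mask.any():
        raise DegenerateInitializationError(
            f"{what} leaves one side of the contour empty"
        )


def initialize_levelsets(
    image: np.ndarray,
    n_regions: int,
    strategy: str = "threshold",
    options: dict | None = None,
    *,
    a: float = 2.0,
) -> LevelSetState:
    """Build initial level-set functions (piecewise constant at ±a).

    Strategies
    ----------
    threshold
        Adaptive intensity thresholds on the (channel-mean) image.  For
        three or four regions, phi_1 uses 0.8 x max intensity and phi_2
        uses 0.3 x max; for two regions a single threshold at 0.5 x max.
        Pixels above the threshold are "inside" (phi = -a).
    mask
        ``options["masks"]`` supplies one boolean inside-mask per level set.
    shape
        A geometric primitive per level set from ``options["shapes"]``,
        each a dict: {"kind": "disc", "center": (r, c), "radius": r} or
        {"kind": "rectangle", "top_left": (r, c), "bottom_right": (r, c)}
        or {"kind": "discs", "centers": [...], "radius": r} (union of
        discs).
    """
    options = options or {}
    img = _as_channels(image)
    shape = img.shape[1:]
    q = n_level_sets(n_regions)

    if strategy == "threshold":
        mean_img = img.mean(axis=0)
        vmax = float(mean_img.max())
        if q == 1:
            fracs = [0.5]
        else:
            fracs = [0.8, 0.3][:q]
        phis = []
        for frac in fracs:
            mask = mean_img > frac * vmax
            _check_two_sided(mask, f"threshold at {frac:g} x max intensity")
            phis.append(_binarize(mask, a))
        return LevelSetState(np.stack(phis), n_regions)

    if strategy == "mask":
        masks = options.get("masks")
        if masks is None:
            raise ValueError("mask strategy requires options['masks']")
        if not isinstance(masks, (list, tuple)):
            masks = [masks]
        masks = [np.asarray(m, dtype=bool) for m in masks]
        if len(masks) != q:
            raise ValueError(f"need {q} masks for {n_regions} regions, "
                             f"got {len(masks)}")
        phis = []
        for mask in masks:
            if mask.shape != shape:
                raise ValueError(
                    f"mask shape {mask.shape} != image grid {shape}")
            _check_two_sided(mask, "user mask")
            phis.append(_binarize(mask, a))
        return LevelSetState(np.stack(phis), n_regions)

    if strategy == "shape":
        shapes = options.get("shapes")
        if shapes is None:
            raise ValueError("shape strategy requires options['shapes']")
        if isinstance(shapes, dict):
            shapes = [shapes]
        if len(shapes) != q:
            raise ValueError(f"need {q} shapes for {n_regions} regions, "
                             f"got {len(shapes)}")
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        phis = []
        for spec in shapes:
            kind = spec.get("kind")
            if kind == "disc":
                r0, c0 = spec["center"]
                mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= spec["radius"] ** 2
            elif kind == "discs":
                mask = np.zeros(shape, dtype=bool)
                for r0, c0 in spec["centers"]:
                    mask |= ((rr - r0) ** 2 + (cc - c0) ** 2
                             <= spec["radius"] ** 2)
            elif kind == "rectangle":
                r0, c0 = spec["top_left"]
                r1, c1 = spec["bottom_right"]
                mask = (rr >= r0) & (rr < r1) & (cc >= c0) & (cc < c1)
            else:
                raise ValueError(f"unknown shape kind {kind!r}")
            _check_two_sided(mask, f"shape {kind!r}")
            phis.append(_binarize(mask, a))
        return LevelSetState(np.stack(phis), n_regions)

    raise ValueError(f"unknown initialization strategy {strategy!r}")


def has_converged(C_prev: np.ndarray, C_curr: np.ndarray, tol: float) -> bool:
    """Cluster-centre convergence: sum_ij |c_ij' - c_ij| < tol."""
    C_prev = np.atleast_2d(np.asarray(C_prev, dtype=float))
    C_curr = np.atleast_2d(np.asarray(C_curr, dtype=float))
    if C_prev.shape != C_curr.shape:
        raise ValueError(
            f"shape mismatch: {C_prev.shape} vs {C_curr.shape}")
    return float(np.abs(C_curr - C_prev).sum()) < tol


def labels_from_state(
    state: LevelSetState, epsilon: float = 1.0
) -> np.ndarray:
    """Hard label map 1..N: argmax of the membership weights."""
    m = memberships(state, epsilon)
    return np.argmax(m, axis=0).astype(np.int32) + 1


def relabel_by_intensity(
    labels: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Renumber regions so class intensities ascend with the label index.

    The model's region numbering is an arbitrary gauge (it depends on the
    initialisation); sorting by the channel-mean class intensity gives a
    canonical order for comparing against ground truth.  Returns the
    renumbered label map and the row-sorted C.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    order = np.argsort(C.mean(axis=1), kind="stable")
    remap = np.empty(len(order), dtype=np.int32)
    remap[order] = np.arange(1, len(order) + 1)
    return remap[np.asarray(labels) - 1], C[order]


def segment(
    image: np.ndarray,
    params: ModelParams | None = None,
    init: LevelSetState | str = "threshold",
    *,
    n_regions: int | None = None,
    order: int = 4,
    init_options: dict | None = None,
    freeze_bias: bool = False,
    record_labels: bool = False,
    record_substeps: bool = False,
    basis: BasisStack | None = None,
) -> SegmentationResult:
    """Run the full alternating minimisation on an image.

    Parameters
    ----------
    image : (rows, cols) or (L, rows, cols) array
        Grayscale or multichannel image, nominally on a 0-255 scale.
    params : ModelParams
        Model weights and numerics; defaults are the standard setting.
    init : LevelSetState or strategy name
        Either a prepared state or one of the strategies of
        :func:`initialize_levelsets`.
    n_regions : int
        Number of regions N (required when ``init`` is a strategy name
        and differs from ``len(params.lambdas)``).
    order : int
        Polynomial order of the bias basis (15 functions at order 4).
    freeze_bias : bool
        Keep W fixed at the identity column (1, 0, ..., 0): the bias is
        then the constant field 1 and the data term reduces to the
        Chan-Vese piecewise-constant model.
    record_labels, record_substeps : bool
        Store the per-iteration label maps / sub-step energies.

    Notes
    -----
    The basis design matrix is built once and reused across iterations;
    only memberships, residuals and the small (M x M per channel) normal
    equations are recomputed.  A region whose membership mass falls below
    10 pixels after the first iteration keeps its previous intensity (with
    a logged warning); at the first iteration it is an error.
    """
    img = _as_channels(image)
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    n_ch = img.shape[0]
    grid = img.shape[1:]

    if isinstance(init, LevelSetState):
        state = init.copy()
        n = state.n_regions
        if n_regions is not None and n_regions != n:
            raise ValueError(
                f"n_regions={n_regions} conflicts with provided state (N={n})")
    else:
        if n_regions is None:
            n_regions = 2 if params is None else params.n_regions
        n = n_regions
        a = 2.0 if params is None else params.a
        state = initialize_levelsets(img, n, init, init_options, a=a)

    params = (params or ModelParams()).with_regions(n).with_channels(n_ch)
    if basis is None:
        basis = build_basis(grid, order)
    elif basis.grid_shape != grid:
        raise ValueError(
            f"basis grid {basis.grid_shape} != image grid {grid}")

    w0 = np.zeros((basis.n_functions, n_ch))
    w0[0, :] = 1.0
    fit = FitState(C=np.zeros((n, n_ch)), W=w0)

    energy_trace: list[float] = []
    c_change_trace: list[float] = []
    substep_trace: list[dict[str, float]] = []
    label_history: list[np.ndarray] = []
    converged = False
    it = 0

    for it in range(1, params.max_iter + 1):
        m = memberships(state, params.epsilon)
        c_prev = fit.C.copy()
        try:
            fit.C = update_c(
                img, basis, state, fit, params,
                memberships_cache=m,
                on_degenerate="raise" if it == 1 else "hold",
            )
        except DegenerateRegionError as exc:
            raise DegenerateRegionError(f"iteration {it}: {exc}") from exc
        if record_substeps:
            e_after_c, _ = energy(img, basis, state, fit, params)
        if not freeze_bias:
            fit.W = update_w(img, basis, state, fit, params,
                             memberships_cache=m)
        if record_substeps:
            e_after_w, _ = energy(img, basis, state, fit, params)
        e_i = residuals(img, basis, fit, params)
        state = update_phi(img, basis, state, fit, params,
                           residuals_cache=e_i, iteration=it)

        e_total, _ = energy(img, basis, state, fit, params)
        energy_trace.append(e_total)
        if record_substeps:
            substep_trace.append(
                {"after_c": e_after_c, "after_w": e_after_w, "end": e_total})
        if record_labels:
            label_history.append(
                labels_from_state(state, params.epsilon).astype(np.uint8))
        c_change = float(np.abs(fit.C - c_prev).sum())
        c_change_trace.append(c_change)
        logger.info(
            "iter %d  energy=%.6g  sum|dC|=%.3g", it, e_total, c_change)
        if it > 1 and has_converged(c_prev, fit.C, params.tol):
            converged = True
            break

    b = bias_fields(basis, fit)
    corrected = bias_corrected(img, basis, fit)
    return SegmentationResult(
        label_map=labels_from_state(state, params.epsilon),
        final_state=state,
        C_final=fit.C.copy(),
        W_final=fit.W.copy(),
        bias_fields=b,
        corrected_image=corrected,
        energy_trace=energy_trace,
        n_iterations=it,
        converged=converged,
        c_change_trace=c_change_trace,
        substep_trace=substep_trace,
        label_history=label_history,
    )
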