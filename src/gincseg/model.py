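"""Core energy model: clustering data term, level-set numerics, updates.

The observed image is modelled as I(x) = b(x) J(x) + n(x), with J piecewise
constant (one intensity c_i per region), b a smooth multiplicative bias in
the span of an orthogonal polynomial basis (b = w^T G), and n zero-mean
noise.  Segmentation, class intensities C and bias coefficients W are found
by minimising a single energy

    E(Phi, C, W) = sum_i lambda_i * integral( e_i(x) M_i(Phi(x)) dx )
                   + nu * L(Phi) + mu * P(Phi),

where e_i(x) = sum_j gamma_j (I_j(x) - w_j^T G(x) c_ij)^2 is the
multichannel residual of assigning pixel x to region i, M_i are smooth
membership functions built from Heaviside compositions of Q = ceil(log2 N)
level-set functions, L is the arc-length of the zero-level contours and P
the distance-regularisation term (1/2) * integral (|grad phi| - 1)^2 that
keeps each phi close to a signed distance function without reinitialisation.

Minimisation alternates exact updates of C and W (closed-form least-squares
stationarity conditions) with an explicit gradient-descent step on Phi; the
driver loop lives in :mod:`gincseg.segment`.

Sign convention, used everywhere: phi > 0 is "outside" (region 1 for the
two-phase model, where M_1 = H(phi)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .basis import BasisStack, evaluate_bias

logger = logging.getLogger("gincseg")

__all__ = [
    "ModelParams",
    "LevelSetState",
    "FitState",
    "DegenerateRegionError",
    "IllConditionedError",
    "NumericalBlowupError",
    "heaviside_smooth",
    "dirac_smooth",
    "n_level_sets",
    "memberships",
    "membership_derivatives",
    "residuals",
    "energy",
    "update_c",
    "update_w",
    "update_phi",
    "bias_corrected",
]

# |grad phi| regulariser added in quadrature inside the square root
GRAD_EPS = 1e-10
# condition-number ceiling for the bias-coefficient linear systems
COND_LIMIT = 1e12
# bias magnitudes below this are clamped when dividing the image by the bias
BIAS_FLOOR = 1e-3


class DegenerateRegionError(RuntimeError):
    """A region's membership mass vanished, so its intensity is undefined."""


class IllConditionedError(RuntimeError):
    """The bias-coefficient normal equations are numerically singular."""


class NumericalBlowupError(RuntimeError):
    """A level-set update produced non-finite values."""


@dataclass(frozen=True)
class ModelParams:
    """Scalar knobs of the model.

    Defaults follow the standard setting for 8-bit intensity ranges:
    epsilon = 1.0, dt = 0.1, lambda_i = 1.0, mu = 1.0,
    nu = 0.005 * 255 * 255, gamma_j = 1.0, a = 2.0, tol = 0.001.

    ``a`` is the binary-initialisation magnitude: initial level-set
    functions are piecewise constant at -a inside and +a outside the
    initial contour.
    """

    lambdas: tuple[float, ...] = (1.0, 1.0)
    mu: float = 1.0
    nu: float = 0.005 * 255 * 255
    epsilon: float = 1.0
    dt: float = 0.1
    gammas: tuple[float, ...] = (1.0,)
    a: float = 2.0
    tol: float = 0.001
    max_iter: int = 500

    def __post_init__(self) -> None:
        if any(lam <= 0 for lam in self.lambdas):
            raise ValueError("class weights lambda_i must be positive")
        if any(g <= 0 for g in self.gammas):
            raise ValueError("channel weights gamma_j must be positive")
        if self.mu < 0 or self.nu < 0:
            raise ValueError("mu and nu must be non-negative")
        for name in ("epsilon", "dt", "a", "tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    @property
    def n_regions(self) -> int:
        return len(self.lambdas)

    def with_regions(self, n: int) -> "ModelParams":
        """Copy with the lambda vector resized to n regions (new entries 1)."""
        lams = tuple(self.lambdas[i] if i < len(self.lambdas) else 1.0
                     for i in range(n))
        return replace(self, lambdas=lams)

    def with_channels(self, n: int) -> "ModelParams":
        gams = tuple(self.gammas[j] if j < len(self.gammas) else 1.0
                     for j in range(n))
        return replace(self, gammas=gams)


def n_level_sets(n_regions: int) -> int:
    """Q = ceil(log2(N)) level-set functions encode N regions."""
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    return int(np.ceil(np.log2(n_regions)))


@dataclass
class LevelSetState:
    """Q level-set functions jointly encoding N regions.

    ``phis`` has shape (Q, rows, cols).  The membership scheme mapping the Q
    functions to N region weights is fixed per N (see :func:`memberships`).
    """

    phis: np.ndarray
    n_regions: int

    def __post_init__(self) -> None:
        self.phis = np.asarray(self.phis, dtype=float)
        if self.phis.ndim == 2:
            self.phis = self.phis[None]
        q_needed = n_level_sets(self.n_regions)
        if self.phis.shape[0] != q_needed:
            raise ValueError(
                f"{self.n_regions} regions need {q_needed} level sets, "
                f"got {self.phis.shape[0]}"
            )
        if not np.all(np.isfinite(self.phis)):
            raise ValueError("level-set functions must be finite")

    @property
    def n_phis(self) -> int:
        return self.phis.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.phis.shape[1:]

    def copy(self) -> "LevelSetState":
        return LevelSetState(self.phis.copy(), self.n_regions)


@dataclass
class FitState:
    """Current class-intensity matrix C (N x L) and bias coefficients W (M x L)."""

    C: np.ndarray
    W: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim == 1:
            self.W = self.W[:, None]
        if self.C.shape[1] != self.W.shape[1]:
            raise ValueError(
                f"C has {self.C.shape[1]} channels but W has {self.W.shape[1]}"
            )

    @property
    def n_channels(self) -> int:
        return self.C.shape[1]

    def copy(self) -> "FitState":
        return FitState(self.C.copy(), self.W.copy())


# ---------------------------------------------------------------------------
# smooth Heaviside / Dirac
# ---------------------------------------------------------------------------

def heaviside_smooth(x: np.ndarray | float, epsilon: float = 1.0):
    """Smooth Heaviside H_eps(x) = (1/2)(1 + (2/pi) arctan(x/eps))."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(np.asarray(x) / epsilon))


def dirac_smooth(x: np.ndarray | float, epsilon: float = 1.0):
    """Smooth Dirac delta_eps(x) = (1/pi) * eps / (eps^2 + x^2)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    x = np.asarray(x)
    return (epsilon / np.pi) / (epsilon**2 + x**2)


# ---------------------------------------------------------------------------
# membership functions
# ---------------------------------------------------------------------------

def memberships(state: LevelSetState, epsilon: float = 1.0) -> np.ndarray:
    """Smooth region-membership weights M_i(Phi), shape (N, rows, cols).

    Encodings (H_q = H_eps(phi_q)):

    * N = 2: M_1 = H_1, M_2 = 1 - H_1.
    * N = 3: M_1 = (1-H_1)(1-H_2), M_2 = (1-H_1) H_2, M_3 = H_1  — the
      three-phase scheme used for WM/GM/CSF brain segmentation.
    * N = 4: full binary products (1-H_1)(1-H_2), (1-H_1)H_2,
      H_1(1-H_2), H_1 H_2.

    The weights form a partition of unity at every pixel.
    """
    n = state.n_regions
    h = heaviside_smooth(state.phis, epsilon)
    if n == 2:
        return np.stack([h[0], 1.0 - h[0]])
    if n == 3:
        h1, h2 = h
        return np.stack([(1 - h1) * (1 - h2), (1 - h1) * h2, h1])
    if n == 4:
        h1, h2 = h
        return np.stack(
            [(1 - h1) * (1 - h2), (1 - h1) * h2, h1 * (1 - h2), h1 * h2]
        )
    raise NotImplementedError(f"membership scheme for N={n} not implemented")


def membership_derivatives(
    state: LevelSetState, epsilon: float = 1.0
) -> np.ndarray:
    """Analytic dM_i/dphi_q, shape (Q, N, rows, cols).

    Chain rule through the encodings of :func:`memberships`; each H_q
    differentiates to the smooth Dirac delta_eps(phi_q).
    """
    n = state.n_regions
    h = heaviside_smooth(state.phis, epsilon)
    d = dirac_smooth(state.phis, epsilon)
    if n == 2:
        return np.stack([np.stack([d[0], -d[0]])])
    if n == 3:
        h1, h2 = h
        d1, d2 = d
        d_phi1 = np.stack([-d1 * (1 - h2), -d1 * h2, d1])
        zero = np.zeros_like(h1)
        d_phi2 = np.stack([-(1 - h1) * d2, (1 - h1) * d2, zero])
        return np.stack([d_phi1, d_phi2])
    if n == 4:
        h1, h2 = h
        d1, d2 = d
        d_phi1 = np.stack([-d1 * (1 - h2), -d1 * h2, d1 * (1 - h2), d1 * h2])
        d_phi2 = np.stack([-(1 - h1) * d2, (1 - h1) * d2, -h1 * d2, h1 * d2])
        return np.stack([d_phi1, d_phi2])
    raise NotImplementedError(f"membership scheme for N={n} not implemented")


# ---------------------------------------------------------------------------
# residuals and energy
# ---------------------------------------------------------------------------

def _as_channels(image: np.ndarray) -> np.ndarray:
    """Coerce a 2D (rows, cols) or 3D (L, rows, cols) image to 3D."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image[None]
    if image.ndim == 3:
        return image
    raise ValueError(f"expected 2D or 3D image, got ndim={image.ndim}")


def bias_fields(basis: BasisStack, fit: FitState) -> np.ndarray:
    """Per-channel bias fields b_j = w_j^T G, shape (L, rows, cols)."""
    return np.stack(
        [evaluate_bias(basis, fit.W[:, j]) for j in range(fit.n_channels)]
    )


def residuals(
    image: np.ndarray,
    basis: BasisStack,
    fit: FitState,
    params: ModelParams,
) -> np.ndarray:
    """Per-region squared fitting residuals e_i(x), shape (N, rows, cols).

    e_i(x) = sum_j gamma_j (I_j(x) - b_j(x) c_ij)^2, non-negative, zero
    exactly where the bias-times-constant model fits the pixel in every
    channel.
    """
    img = _as_channels(image)
    n_ch = img.shape[0]
    if fit.n_channels != n_ch:
        raise ValueError(
            f"image has {n_ch} channels but fit has {fit.n_channels}"
        )
    if img.shape[1:] != basis.grid_shape:
        raise ValueError(
            f"image grid {img.shape[1:]} != basis grid {basis.grid_shape}"
        )
    params = params.with_channels(n_ch)
    b = bias_fields(basis, fit)
    n_regions = fit.C.shape[0]
    e = np.zeros((n_regions,) + basis.grid_shape)
    for i in range(n_regions):
        for j in range(n_ch):
            e[i] += params.gammas[j] * (img[j] - b[j] * fit.C[i, j]) ** 2
    return e


def _grad(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient (d/dcol, d/drow), replicate boundaries."""
    p = np.pad(u, 1, mode="edge")
    ux = (p[1:-1, 2:] - p[1:-1, :-2]) / 2.0
    uy = (p[2:, 1:-1] - p[:-2, 1:-1]) / 2.0
    return ux, uy


def _laplacian(u: np.ndarray) -> np.ndarray:
    """5-point Laplacian with replicate (Neumann) boundaries."""
    p = np.pad(u, 1, mode="edge")
    return (
        p[1:-1, 2:] + p[1:-1, :-2] + p[2:, 1:-1] + p[:-2, 1:-1]
        - 4.0 * p[1:-1, 1:-1]
    )


def curvature(phi: np.ndarray) -> np.ndarray:
    """div(grad phi / |grad phi|), the mean curvature of the level lines."""
    ux, uy = _grad(phi)
    norm = np.sqrt(ux**2 + uy**2 + GRAD_EPS**2)
    dxx, _ = _grad(ux / norm)
    _, dyy = _grad(uy / norm)
    return dxx + dyy


def energy(
    image: np.ndarray,
    basis: BasisStack,
    state: LevelSetState,
    fit: FitState,
    params: ModelParams,
) -> tuple[float, dict[str, float]]:
    """Total energy and its breakdown into data, arc-length and
    distance-regularisation terms.

    Returns ``(total, {"data": F, "length": L, "regularization": P})`` where
    total = F + nu*L + mu*P; each addend is the *unweighted* integral.
    """
    params = params.with_regions(state.n_regions)
    e = residuals(image, basis, fit, params)
    m = memberships(state, params.epsilon)
    data = float(sum(
        params.lambdas[i] * np.sum(e[i] * m[i])
        for i in range(state.n_regions)
    ))
    length = 0.0
    reg = 0.0
    for q in range(state.n_phis):
        phi = state.phis[q]
        ux, uy = _grad(phi)
        gnorm = np.sqrt(ux**2 + uy**2 + GRAD_EPS**2)
        length += float(np.sum(dirac_smooth(phi, params.epsilon) * gnorm))
        reg += float(0.5 * np.sum((gnorm - 1.0) ** 2))
    total = data + params.nu * length + params.mu * reg
    return total, {"data": data, "length": length, "regularization": reg}


# ---------------------------------------------------------------------------
# alternating updates
# ---------------------------------------------------------------------------

def update_c(
    image: np.ndarray,
    basis: BasisStack,
    state: LevelSetState | None,
    fit: FitState,
    params: ModelParams,
    *,
    memberships_cache: np.ndarray | None = None,
    on_degenerate: str = "raise",
    min_mass: float = 10.0,
) -> np.ndarray:
    """Exact minimiser of the energy in the class intensities C.

    c_ij = int I_j b_j M_i dx / int b_j^2 M_i dx — a bias-weighted region
    mean.  With b == 1 this is the ordinary region mean of the Chan-Vese
    model.  ``state`` may be None if a membership stack is supplied
    directly (e.g. a single all-ones region for pure bias fitting).

    ``on_degenerate`` controls what happens when a region's membership mass
    drops below ``min_mass`` pixels: "raise" raises
    :class:`DegenerateRegionError`; "hold" keeps the previous c_ij and logs
    a warning (used mid-run, where transient empty regions occur).
    """
    img = _as_channels(image)
    if memberships_cache is not None:
        m = np.asarray(memberships_cache, dtype=float)
    elif state is not None:
        m = memberships(state, params.epsilon)
    else:
        raise ValueError("need a LevelSetState or a membership stack")
    n_regions, n_ch = m.shape[0], img.shape[0]
    params = params.with_regions(n_regions).with_channels(n_ch)
    b = bias_fields(basis, fit)
    c_new = fit.C.copy()
    for i in range(n_regions):
        mass = float(np.sum(m[i]))
        if mass < min_mass:
            if on_degenerate == "raise":
                raise DegenerateRegionError(
                    f"region {i + 1} has membership mass {mass:.3g} "
                    f"(< {min_mass} pixels)"
                )
            logger.warning(
                "region %d membership mass %.3g < %g px; holding its "
                "intensity at %s", i + 1, mass, min_mass,
                np.array2string(fit.C[i], precision=3),
            )
            continue
        for j in range(n_ch):
            num = float(np.sum(img[j] * b[j] * m[i]))
            den = float(np.sum(b[j] ** 2 * m[i]))
            if den <= 0:
                raise DegenerateRegionError(
                    f"region {i + 1}, channel {j + 1}: vanishing "
                    f"denominator in the intensity update"
                )
            c_new[i, j] = num / den
    return c_new


def update_w(
    image: np.ndarray,
    basis: BasisStack,
    state: LevelSetState | None,
    fit: FitState,
    params: ModelParams,
    *,
    memberships_cache: np.ndarray | None = None,
) -> np.ndarray:
    """Exact minimiser of the energy in the bias coefficients W.

    For each channel j solves the M x M normal equations A_j w_j = v_j with

        A_j = int sum_i lambda_i c_ij^2 M_i * G G^T dx,
        v_j = int I_j sum_i lambda_i c_ij M_i * G dx.

    ``state`` may be None if a membership stack is supplied directly; with
    a single all-ones region and c = 1 this is a pure least-squares fit of
    the basis to the image, recovering the coefficients of any field in
    the span exactly.
    """
    img = _as_channels(image)
    if memberships_cache is not None:
        m = np.asarray(memberships_cache, dtype=float)
    elif state is not None:
        m = memberships(state, params.epsilon)
    else:
        raise ValueError("need a LevelSetState or a membership stack")
    n_regions, n_ch = m.shape[0], img.shape[0]
    params = params.with_regions(n_regions).with_channels(n_ch)
    g = basis.flat  # (n_pixels, M)
    lam = np.asarray(params.lambdas)
    w_new = np.empty_like(fit.W)
    m_flat = m.reshape(n_regions, -1)
    for j in range(n_ch):
        d = np.zeros(m_flat.shape[1])  # sum_i lambda_i c_ij^2 M_i
        s = np.zeros(m_flat.shape[1])  # sum_i lambda_i c_ij M_i
        for i in range(n_regions):
            d += lam[i] * fit.C[i, j] ** 2 * m_flat[i]
            s += lam[i] * fit.C[i, j] * m_flat[i]
        a_mat = g.T @ (d[:, None] * g)
        v = g.T @ (img[j].ravel() * s)
        cond = np.linalg.cond(a_mat)
        if not np.isfinite(cond) or cond > COND_LIMIT:
            raise IllConditionedError(
                f"channel {j + 1}: bias normal equations have condition "
                f"number {cond:.3g} (> {COND_LIMIT:.0g})"
            )
        w_new[:, j] = np.linalg.solve(a_mat, v)
    return w_new


def update_phi(
    image: np.ndarray,
    basis: BasisStack,
    state: LevelSetState,
    fit: FitState,
    params: ModelParams,
    *,
    residuals_cache: np.ndarray | None = None,
    iteration: int | None = None,
) -> LevelSetState:
    """One explicit gradient-descent step on every level-set function.

    phi_q <- phi_q + dt * ( -sum_i dM_i/dphi_q * lambda_i e_i
                            + mu * (lap phi_q - curv(phi_q))
                            + nu * delta_eps(phi_q) * curv(phi_q) ),

    where curv is the level-line curvature div(grad phi / |grad phi|).
    The data force moves each phi so pixels drift toward the region with
    the smaller weighted residual.
    """
    params = params.with_regions(state.n_regions)
    e = (residuals_cache if residuals_cache is not None
         else residuals(image, basis, fit, params))
    dm = membership_derivatives(state, params.epsilon)
    lam = np.asarray(params.lambdas)
    new_phis = np.empty_like(state.phis)
    for q in range(state.n_phis):
        phi = state.phis[q]
        data_force = -sum(
            dm[q, i] * lam[i] * e[i] for i in range(state.n_regions)
        )
        curv = curvature(phi)
        reg_force = params.mu * (_laplacian(phi) - curv)
        length_force = params.nu * dirac_smooth(phi, params.epsilon) * curv
        new_phis[q] = phi + params.dt * (data_force + reg_force + length_force)
    if not np.all(np.isfinite(new_phis)):
        where = "" if iteration is None else f" at iteration {iteration}"
        raise NumericalBlowupError(
            f"level-set update produced non-finite values{where}; "
            f"consider a smaller dt"
        )
    return LevelSetState(new_phis, state.n_regions)


def bias_corrected(
    image: np.ndarray,
    basis: BasisStack,
    fit: FitState,
    *,
    floor: float = BIAS_FLOOR,
) -> np.ndarray:
    """Divide each channel by its estimated bias field.

    Bias magnitudes below ``floor`` are clamped (sign-preserving) before
    dividing; if more than 1% of pixels hit the floor a warning is logged,
    since the correction is unreliable there.
    """
    img = _as_channels(image)
    b = bias_fields(basis, fit)
    flagged = np.abs(b) < floor
    frac = float(flagged.mean())
    if frac > 0.01:
        logger.warning(
            "bias magnitude below %g on %.1f%% of pixels; corrected image "
            "is unreliable there", floor, 100 * frac,
        )
    b_safe = np.where(flagged, np.where(b >= 0, floor, -floor), b)
    out = img / b_safe
    return out if np.asarray(image).ndim == 3 else out[0]
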