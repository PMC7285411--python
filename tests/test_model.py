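"""Core model: Heaviside/Dirac numerics, memberships, residuals, energy,
and the three alternating updates."""

import numpy as np
import pytest

from gincseg import (
    DegenerateRegionError,
    FitState,
    LevelSetState,
    ModelParams,
    NumericalBlowupError,
    bias_corrected,
    build_basis,
    dirac_smooth,
    energy,
    evaluate_bias,
    heaviside_smooth,
    memberships,
    residuals,
    update_c,
    update_phi,
    update_w,
)
from gincseg.model import curvature, membership_derivatives, _laplacian


# ---------------------------------------------------------------- Heaviside

@pytest.mark.parametrize("x,expected", [(0.0, 0.5), (1.0, 0.75), (-1.0, 0.25)])
def test_heaviside_reference_values(x, expected):
    assert heaviside_smooth(x, 1.0) == pytest.approx(expected)


def test_heaviside_complement_identity():
    x = np.linspace(-50, 50, 301)
    np.testing.assert_allclose(
        heaviside_smooth(x, 2.0) + heaviside_smooth(-x, 2.0), 1.0, atol=1e-14)
    assert np.all(np.diff(heaviside_smooth(x, 0.5)) > 0)


def test_dirac_reference_values_and_symmetry():
    assert dirac_smooth(0.0, 1.0) == pytest.approx(1 / np.pi)
    x = np.linspace(0, 30, 100)
    np.testing.assert_allclose(dirac_smooth(x, 1.0), dirac_smooth(-x, 1.0))


def test_dirac_integrates_to_one():
    """Quadrature oracle: trapezoid over [-100, 100] captures ~unit mass."""
    x = np.linspace(-100, 100, 200001)
    integral = np.trapezoid(dirac_smooth(x, 1.0), x)
    assert integral == pytest.approx(1.0, abs=1e-2)


# -------------------------------------------------------------- memberships

def _random_state(n_regions, shape=(24, 24), seed=0):
    from gincseg.model import n_level_sets
    rng = np.random.default_rng(seed)
    phis = rng.normal(scale=3.0, size=(n_level_sets(n_regions),) + shape)
    return LevelSetState(phis, n_regions)


@pytest.mark.parametrize("n", [2, 3, 4])
def test_partition_of_unity(n):
    m = memberships(_random_state(n, seed=n), epsilon=1.0)
    assert m.shape[0] == n
    assert m.min() >= 0.0 and m.max() <= 1.0
    np.testing.assert_allclose(m.sum(axis=0), 1.0, atol=1e-14)


def test_two_phase_memberships_saturate():
    state = LevelSetState(np.full((1, 8, 8), 10.0), 2)
    m = memberships(state, 1.0)
    assert np.all(m[0] > 0.96) and np.all(m[1] < 0.04)


def test_three_phase_needs_two_level_sets():
    with pytest.raises(ValueError):
        LevelSetState(np.zeros((1, 8, 8)), 3)
    state = LevelSetState(np.zeros((2, 8, 8)), 3)
    assert state.n_phis == 2


def test_unsupported_region_count():
    state = LevelSetState(np.zeros((3, 8, 8)), 5)
    with pytest.raises(NotImplementedError):
        memberships(state, 1.0)


@pytest.mark.parametrize("n", [2, 3, 4])
def test_membership_derivatives_match_finite_differences(n):
    """dM_i/dphi_q agrees with central finite differences (oracle)."""
    state = _random_state(n, shape=(6, 6), seed=10 + n)
    eps = 1.0
    analytic = membership_derivatives(state, eps)
    h = 1e-6
    for q in range(state.n_phis):
        plus, minus = state.copy(), state.copy()
        plus.phis[q] += h
        minus.phis[q] -= h
        numeric = (memberships(plus, eps) - memberships(minus, eps)) / (2 * h)
        np.testing.assert_allclose(analytic[q], numeric, atol=1e-8)


# ---------------------------------------------------------------- residuals

def test_residuals_zero_when_model_exact(basis64):
    w = np.random.default_rng(1).normal(scale=0.05, size=15)
    w[0] = 1.0
    fit = FitState(C=[[7.0]], W=w)
    image = evaluate_bias(basis64, w) * 7.0
    e = residuals(image, basis64, fit, ModelParams(lambdas=(1.0,)))
    np.testing.assert_allclose(e, 0.0, atol=1e-18)


def test_residuals_constant_case(basis64):
    w = np.zeros(15)
    w[0] = 1.0
    fit = FitState(C=[[3.0]], W=w)
    e = residuals(np.full((64, 64), 5.0), basis64, fit,
                  ModelParams(lambdas=(1.0,)))
    np.testing.assert_allclose(e, 4.0)


def test_residuals_linear_in_gamma(basis64):
    w = np.zeros((15, 2))
    w[0] = 1.0
    fit = FitState(C=[[3.0, 9.0]], W=w)
    img = np.stack([np.full((64, 64), 5.0), np.full((64, 64), 10.0)])
    p1 = ModelParams(lambdas=(1.0,), gammas=(1.0, 1.0))
    p2 = ModelParams(lambdas=(1.0,), gammas=(2.0, 1.0))
    e1 = residuals(img, basis64, fit, p1)
    e2 = residuals(img, basis64, fit, p2)
    # channel 0 contributes (5-3)^2 = 4, channel 1 (10-9)^2 = 1
    np.testing.assert_allclose(e1, 5.0)
    np.testing.assert_allclose(e2, 9.0)


# ------------------------------------------------------------------- energy

def _crisp_state(labels, magnitude=1e12):
    """Two-phase state with essentially hard memberships (label 1 <-> phi>0)."""
    return LevelSetState(np.where(labels == 1, magnitude, -magnitude), 2)


def test_energy_zero_for_perfect_fit(basis64):
    labels = np.ones((64, 64), dtype=int)
    labels[20:40, 20:40] = 2
    w = np.zeros(15)
    w[0] = 1.0
    fit = FitState(C=[[10.0], [50.0]], W=w)
    image = np.where(labels == 1, 10.0, 50.0)
    params = ModelParams(mu=0.0, nu=0.0)
    total, parts = energy(image, basis64, _crisp_state(labels), fit, params)
    assert total == pytest.approx(0.0, abs=1e-3)
    assert parts["data"] >= 0.0


def test_distance_regularizer_zero_on_unit_plane(basis64):
    """P vanishes where |grad phi| = 1 (checked away from the border)."""
    cols = np.arange(64, dtype=float)
    phi = np.tile(cols - 32.0, (64, 1))
    from gincseg.model import _grad, GRAD_EPS
    ux, uy = _grad(phi)
    gnorm = np.sqrt(ux**2 + uy**2 + GRAD_EPS**2)
    assert np.allclose((gnorm[:, 1:-1] - 1.0), 0.0, atol=1e-12)


def test_energy_breakdown_nonnegative(basis64, small_phantom):
    state = _crisp_state(small_phantom.labels, magnitude=5.0)
    fit = FitState(C=small_phantom.C_true, W=small_phantom.W_true)
    total, parts = energy(small_phantom.image, basis64, state, fit,
                          ModelParams())
    assert parts["data"] >= 0 and parts["length"] >= 0
    assert parts["regularization"] >= 0
    assert total == pytest.approx(
        parts["data"] + ModelParams().nu * parts["length"]
        + ModelParams().mu * parts["regularization"])


def test_scale_gauge_invariance(basis64, small_phantom):
    """(W*s, C/s) leaves residuals and energy unchanged."""
    rng = np.random.default_rng(5)
    w = rng.normal(scale=0.05, size=15)
    w[0] = 1.0
    fit = FitState(C=[[55.0], [150.0]], W=w)
    s = 3.7
    fit_scaled = FitState(C=fit.C / s, W=fit.W * s)
    state = _crisp_state(small_phantom.labels, magnitude=4.0)
    p = ModelParams()
    e1 = residuals(small_phantom.image, basis64, fit, p)
    e2 = residuals(small_phantom.image, basis64, fit_scaled, p)
    np.testing.assert_allclose(e1, e2, rtol=1e-9, atol=1e-9)
    t1, _ = energy(small_phantom.image, basis64, state, fit, p)
    t2, _ = energy(small_phantom.image, basis64, state, fit_scaled, p)
    assert t1 == pytest.approx(t2, rel=1e-12)


# ----------------------------------------------------------------- update_c

def test_update_c_reduces_to_region_means(basis64):
    labels = np.ones((64, 64), dtype=int)
    labels[10:30, 10:30] = 2
    image = np.where(labels == 1, 10.0, 50.0)
    w = np.zeros(15)
    w[0] = 1.0
    fit = FitState(C=[[0.0], [0.0]], W=w)
    c = update_c(image, basis64, _crisp_state(labels), fit, ModelParams())
    np.testing.assert_allclose(c.ravel(), [10.0, 50.0], rtol=1e-9)


def test_update_c_exact_recovery_under_bias(basis64):
    rng = np.random.default_rng(2)
    w = rng.normal(scale=0.05, size=15)
    w[0] = 1.0
    bias = evaluate_bias(basis64, w)
    labels = np.ones((64, 64), dtype=int)
    labels[5:25, 30:60] = 2
    image = bias * np.where(labels == 1, 60.0, 140.0)
    fit = FitState(C=[[0.0], [0.0]], W=w)
    c = update_c(image, basis64, _crisp_state(labels), fit, ModelParams())
    np.testing.assert_allclose(c.ravel(), [60.0, 140.0], rtol=1e-9)


def test_update_c_matches_weighted_least_squares_oracle(basis128,
                                                        phantom_sigma5):
    """On the noisy phantom with true bias and crisp truth memberships the
    update agrees with an independent per-region weighted LS fit and lands
    within 3*sigma/sqrt(region size) of the true intensities."""
    ph = phantom_sigma5
    state = _crisp_state(ph.labels, magnitude=1e9)
    fit = FitState(C=np.zeros((2, 1)), W=ph.W_true)
    c = update_c(ph.image, basis128, state, fit, ModelParams())
    bias = ph.bias_true[0]
    for i in (1, 2):
        mask = ph.labels == i
        # oracle: argmin_c sum (I - b c)^2 over the region, via lstsq
        oracle, *_ = np.linalg.lstsq(
            bias[mask][:, None], ph.image[0][mask], rcond=None)
        assert c[i - 1, 0] == pytest.approx(oracle[0], rel=1e-9)
        bound = 3 * ph.noise_sigma / np.sqrt(mask.sum())
        assert abs(c[i - 1, 0] - ph.C_true[i - 1, 0]) < bound


def test_update_c_degenerate_region_error(basis64):
    m = np.zeros((2, 64, 64))
    m[0] = 1.0  # region 2 empty
    fit = FitState(C=np.zeros((2, 1)), W=np.eye(15, 1).ravel())
    with pytest.raises(DegenerateRegionError, match="region 2"):
        update_c(np.ones((64, 64)), basis64, None, fit, ModelParams(),
                 memberships_cache=m)


# ----------------------------------------------------------------- update_w

def test_update_w_recovers_coefficients_single_region(basis128):
    """A field synthesized from known coefficients is recovered exactly
    when fitted with one unit-intensity region."""
    from gincseg import REFERENCE_BIAS_COEFFS

    image = evaluate_bias(basis128, REFERENCE_BIAS_COEFFS)
    fit = FitState(C=[[1.0]], W=np.zeros(15))
    m = np.ones((1, 128, 128))
    w = update_w(image, basis128, None, fit, ModelParams(lambdas=(1.0,)),
                 memberships_cache=m)
    np.testing.assert_allclose(w[:, 0], REFERENCE_BIAS_COEFFS, atol=1e-10)
    assert w[0, 0] == pytest.approx(1.05)


def test_update_w_constant_image_gives_unit_coefficients(basis64):
    fit = FitState(C=[[42.0]], W=np.zeros(15))
    m = np.ones((1, 64, 64))
    w = update_w(np.full((64, 64), 42.0), basis64, None, fit,
                 ModelParams(lambdas=(1.0,)), memberships_cache=m)
    expected = np.zeros(15)
    expected[0] = 1.0
    np.testing.assert_allclose(w[:, 0], expected, atol=1e-12)


def test_update_w_solves_normal_equations(basis64, small_phantom):
    """The returned coefficients satisfy A w = v to 1e-8 relative."""
    ph = small_phantom
    state = _crisp_state(ph.labels, magnitude=4.0)
    fit = FitState(C=ph.C_true, W=ph.W_true)
    params = ModelParams()
    w = update_w(ph.image, basis64, state, fit, params)
    # rebuild the normal equations independently
    m = memberships(state, params.epsilon).reshape(2, -1)
    g = basis64.flat
    d = (ph.C_true[0, 0] ** 2) * m[0] + (ph.C_true[1, 0] ** 2) * m[1]
    s = ph.C_true[0, 0] * m[0] + ph.C_true[1, 0] * m[1]
    a_mat = g.T @ (d[:, None] * g)
    v = g.T @ (ph.image[0].ravel() * s)
    assert np.linalg.norm(a_mat @ w[:, 0] - v) / np.linalg.norm(v) <= 1e-8


# --------------------------------------------------- coordinate descent

def test_energy_nonincreasing_under_c_and_w_updates(basis64, small_phantom):
    """update_c and update_w are exact minimisers: the energy never rises
    across either sub-step (1e-10 relative slack for round-off)."""
    ph = small_phantom
    params = ModelParams()
    state = _crisp_state(ph.labels, magnitude=2.0)
    w0 = np.zeros((15, 1))
    w0[0] = 1.0
    fit = FitState(C=np.array([[80.0], [120.0]]), W=w0)
    for _ in range(5):
        e0, _ = energy(ph.image, basis64, state, fit, params)
        fit.C = update_c(ph.image, basis64, state, fit, params)
        e1, _ = energy(ph.image, basis64, state, fit, params)
        assert e1 <= e0 * (1 + 1e-10)
        fit.W = update_w(ph.image, basis64, state, fit, params)
        e2, _ = energy(ph.image, basis64, state, fit, params)
        assert e2 <= e1 * (1 + 1e-10)
        state = update_phi(ph.image, basis64, state, fit, params)


# ---------------------------------------------------------------- update_phi

def test_mu_force_vanishes_on_unit_plane():
    cols = np.arange(64, dtype=float)
    phi = np.tile(cols - 32.0, (64, 1))
    force = _laplacian(phi) - curvature(phi)
    assert np.abs(force[2:-2, 2:-2]).max() < 1e-9


def test_curvature_of_disc_is_inverse_radius():
    """div(grad phi/|grad phi|) on a signed distance to a circle ~ 1/r."""
    rr, cc = np.mgrid[0:128, 0:128]
    for r in (12, 20, 30):
        dist = np.sqrt((rr - 64.0) ** 2 + (cc - 64.0) ** 2)
        phi = dist - r  # signed distance, negative inside
        kappa = curvature(phi)
        ring = np.abs(dist - r) < 0.5
        assert np.median(kappa[ring]) == pytest.approx(1.0 / r, rel=0.1)


def test_data_force_sign_two_phase(basis64):
    """Where region 1 fits worse (e1 > e2), phi is pushed down."""
    w = np.zeros(15)
    w[0] = 1.0
    fit = FitState(C=[[10.0], [50.0]], W=w)
    image = np.full((64, 64), 50.0)  # everything looks like region 2
    state = LevelSetState(np.zeros((1, 64, 64)), 2)
    params = ModelParams(mu=0.0, nu=1e-12, dt=0.1)
    new = update_phi(image, basis64, state, fit, params)
    assert np.all(new.phis < state.phis)


def test_update_phi_blowup_detection(basis64):
    fit = FitState(C=[[1e200], [5e200]], W=np.eye(15, 1).ravel())
    state = LevelSetState(np.zeros((1, 64, 64)), 2)
    with pytest.raises(NumericalBlowupError), \
            np.errstate(over="ignore", invalid="ignore"):
        update_phi(np.full((64, 64), 1e200), basis64, state, fit,
                   ModelParams())


# ------------------------------------------------------------ bias_corrected

def test_bias_corrected_identity_and_exact_division(basis64):
    w = np.zeros(15)
    w[0] = 1.0
    image = np.random.default_rng(0).uniform(10, 200, (64, 64))
    np.testing.assert_array_equal(
        bias_corrected(image, basis64, FitState(C=[[1.0]], W=w)), image)
    rng = np.random.default_rng(4)
    wb = rng.normal(scale=0.05, size=15)
    wb[0] = 1.0
    j = np.where(np.arange(64)[:, None] < 32, 30.0, 170.0) * np.ones((64, 64))
    biased = evaluate_bias(basis64, wb) * j
    corrected = bias_corrected(biased, basis64, FitState(C=[[1.0]], W=wb))
    np.testing.assert_allclose(corrected, j, rtol=1e-12)


def test_bias_corrected_reduces_class_variance(basis128, phantom_sigma5):
    ph = phantom_sigma5
    fit = FitState(C=ph.C_true, W=ph.W_true)
    corrected = bias_corrected(ph.image, basis128, fit)[0]
    raw = ph.image[0]
    for i in (1, 2):
        mask = ph.labels == i
        assert corrected[mask].var() < raw[mask].var()


def test_bias_corrected_floor_warning(basis64, caplog):
    """A bias crossing zero on a large area triggers the logging contract."""
    w = np.zeros(15)
    w[0] = 1e-4  # constant bias far below the floor everywhere
    import logging
    with caplog.at_level(logging.WARNING, logger="gincseg"):
        bias_corrected(np.ones((64, 64)), basis64, FitState(C=[[1.0]], W=w))
    assert any("bias magnitude" in r.message for r in caplog.records)
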