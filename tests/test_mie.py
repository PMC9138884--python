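"""Forward Mie model: coefficients, Mueller elements, q/u profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pclar import (OpticalContext, SphereParticle, default_angle_grid,
                   mie_coefficients, mueller_profile, simulate_pclar,
                   size_parameter)
from pclar.mie import MieNumericalError, amplitude_functions, wiscombe_order

VACUUM = OpticalContext(wavelength_nm=532.0, n_medium=1.0)


def rayleigh_sphere(x: float = 0.01, m: float = 1.5) -> SphereParticle:
    d = x * 0.532 / np.pi  # diameter giving size parameter x in vacuum context
    return SphereParticle(d, m)


def test_size_parameter_matches_definition(silica_particle, water_context):
    x = size_parameter(silica_particle, water_context)
    assert x == pytest.approx(np.pi * 10.0 * 1.330 / 0.532, rel=1e-12)
    assert x == pytest.approx(78.56, abs=0.03)


def test_index_matched_sphere_does_not_scatter(water_context):
    p = SphereParticle(10.0, 1.330 + 0.0j)
    s = mie_coefficients(p, water_context)
    assert np.all(s.a == 0) and np.all(s.b == 0)


def test_truncation_meets_wiscombe_criterion(silica_particle, water_context):
    s = mie_coefficients(silica_particle, water_context)
    assert s.order >= wiscombe_order(s.x)


def test_forward_scattering_symmetry(silica_particle, water_context):
    """At θ=0 the amplitudes coincide, so S12 = 0 and S33 = S11."""
    s = mie_coefficients(silica_particle, water_context)
    mm = mueller_profile(s, np.array([0.0]))
    assert mm.S12[0] == pytest.approx(0.0, abs=1e-10 * mm.S11[0])
    assert mm.S33[0] == pytest.approx(mm.S11[0], rel=1e-12)


def test_rayleigh_closed_forms():
    """x = 0.01, m = 1.5: dipole formulas for −S12/S11 and S33/S11."""
    s = mie_coefficients(rayleigh_sphere(), VACUUM)
    theta = np.linspace(0.0, 180.0, 361)
    mm = mueller_profile(s, theta)
    mu = np.cos(np.deg2rad(theta))
    assert np.abs(-mm.S12 / mm.S11 - (1 - mu**2) / (1 + mu**2)).max() < 1e-4
    assert np.abs(mm.S33 / mm.S11 - 2 * mu / (1 + mu**2)).max() < 1e-4


def test_rayleigh_limit_under_45deg_illumination():
    prof = simulate_pclar(rayleigh_sphere(), VACUUM, np.array([90.0]))
    assert prof.q[0] == pytest.approx(-1.0, abs=1e-3)
    assert prof.u[0] == pytest.approx(0.0, abs=1e-3)


def test_forward_limit_q0_u1(silica_particle, water_context):
    prof = simulate_pclar(silica_particle, water_context, np.array([1e-9]))
    assert prof.q[0] == pytest.approx(0.0, abs=1e-9)
    assert prof.u[0] == pytest.approx(1.0, abs=1e-9)


def test_sphere_mueller_identity(silica_particle, water_context, theta_grid):
    """S11² = S12² + S33² + S34² holds to 1e−10 relative at all angles."""
    s = mie_coefficients(silica_particle, water_context)
    mm = mueller_profile(s, theta_grid)
    lhs = mm.S11**2
    rhs = mm.S12**2 + mm.S33**2 + mm.S34**2
    assert np.abs(lhs - rhs).max() <= 1e-10 * lhs.max()


def test_full_polarization_identity(silica_profile, silica_particle,
                                    water_context, theta_grid):
    """q² + u² + v² = 1 for fully polarized sphere scattering; the linear
    part alone satisfies q² + u² ≤ 1."""
    s = mie_coefficients(silica_particle, water_context)
    mm = mueller_profile(s, theta_grid)
    v = -mm.S34 / mm.S11
    total = silica_profile.q**2 + silica_profile.u**2 + v**2
    assert np.abs(total - 1.0).max() < 1e-9
    assert np.all(silica_profile.q**2 + silica_profile.u**2 <= 1 + 1e-9)


def test_series_convergence_in_truncation_order(silica_particle, water_context,
                                                theta_grid):
    base = simulate_pclar(silica_particle, water_context, theta_grid)
    s = mie_coefficients(silica_particle, water_context)
    doubled = simulate_pclar(silica_particle, water_context, theta_grid,
                             n_terms=2 * s.order)
    assert np.abs(base.q - doubled.q).max() < 1e-9
    assert np.abs(base.u - doubled.u).max() < 1e-9


def test_empty_angle_grid_rejected(silica_particle, water_context):
    s = mie_coefficients(silica_particle, water_context)
    with pytest.raises(ValueError):
        mueller_profile(s, np.array([]))


def test_size_parameter_guard(water_context):
    huge = SphereParticle(1.0e4, 1.5)
    with pytest.raises(ValueError, match="size parameter"):
        mie_coefficients(huge, water_context)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(d=st.floats(0.2, 25.0), nr=st.floats(1.05, 1.7), ni=st.floats(0.0, 0.01))
def test_qu_stay_physical_over_parameter_space(d, nr, ni):
    """For any sphere, q and u are bounded and the linear polarization never
    exceeds full polarization."""
    prof = simulate_pclar(SphereParticle(d, complex(nr, ni)),
                          OpticalContext(), default_angle_grid(97))
    assert np.all(np.abs(prof.q) <= 1 + 1e-9)
    assert np.all(np.abs(prof.u) <= 1 + 1e-9)
    assert np.all(prof.q**2 + prof.u**2 <= 1 + 1e-9)


# --- independent high-precision oracle ------------------------------------

def _oracle_coefficients(x: float, m: complex, N: int):
    """a_n, b_n from Riccati–Bessel functions evaluated with mpmath at 30
    significant digits — an algorithmic route (direct Bessel evaluation)
    independent of the package's recurrence implementation."""
    from mpmath import besselj, bessely, mp, mpc, mpf, pi, sqrt

    mp.dps = 30
    xm, mm_ = mpf(repr(x)), mpc(m)

    def psi(n, z):
        return sqrt(pi * z / 2) * besselj(n + mpf(1) / 2, z)

    def chi(n, z):
        return -sqrt(pi * z / 2) * bessely(n + mpf(1) / 2, z)

    a = np.empty(N, dtype=complex)
    b = np.empty(N, dtype=complex)
    for n in range(1, N + 1):
        pn, pn1 = psi(n, xm), psi(n - 1, xm)
        pmn, pmn1 = psi(n, mm_ * xm), psi(n - 1, mm_ * xm)
        xin = pn + 1j * chi(n, xm)
        xin1 = pn1 + 1j * chi(n - 1, xm)
        dpn = pn1 - n / xm * pn
        dpmn = pmn1 - n / (mm_ * xm) * pmn
        dxin = xin1 - n / xm * xin
        a[n - 1] = complex((mm_ * pmn * dpn - pn * dpmn)
                           / (mm_ * pmn * dxin - xin * dpmn))
        b[n - 1] = complex((pmn * dpn - mm_ * pn * dpmn)
                           / (pmn * dxin - mm_ * xin * dpmn))
    return a, b


def test_coefficients_match_independent_oracle(silica_particle, water_context):
    """Silica sphere in water: a_n, b_n agree with the arbitrary-precision
    Riccati–Bessel evaluation to 1e−10 of the dominant coefficient."""
    s = mie_coefficients(silica_particle, water_context)
    ao, bo = _oracle_coefficients(s.x, s.m, s.order)
    scale = max(np.abs(ao).max(), np.abs(bo).max())
    assert np.abs(s.a - ao).max() < 1e-10 * scale
    assert np.abs(s.b - bo).max() < 1e-10 * scale


@pytest.mark.parametrize("x,m", [(0.01, 1.5 + 0.0j), (1.0, 1.33 + 0.001j),
                                 (10.0, 1.2 + 0.01j)])
def test_profiles_match_independent_oracle(x, m):
    """q(θ), u(θ) from the package agree with profiles rebuilt from oracle
    coefficients to better than 1e−6 over the measured angular range."""
    d = x * 0.532 / np.pi
    particle = SphereParticle(d, m)
    prof = simulate_pclar(particle, VACUUM, default_angle_grid(81))
    s = mie_coefficients(particle, VACUUM)
    ao, bo = _oracle_coefficients(s.x, s.m, s.order)
    # rebuild q,u from oracle coefficients through the standard angular sums
    theta = default_angle_grid(81)
    mu = np.cos(np.deg2rad(theta))
    S1 = np.zeros_like(mu, dtype=complex)
    S2 = np.zeros_like(mu, dtype=complex)
    pi_nm1 = np.zeros_like(mu)
    pi_n = np.ones_like(mu)
    for k in range(1, s.order + 1):
        tau = k * mu * pi_n - (k + 1) * pi_nm1
        f = (2 * k + 1) / (k * (k + 1))
        S1 += f * (ao[k - 1] * pi_n + bo[k - 1] * tau)
        S2 += f * (ao[k - 1] * tau + bo[k - 1] * pi_n)
        pi_nm1, pi_n = pi_n, ((2 * k + 1) * mu * pi_n - (k + 1) * pi_nm1) / k
    S11 = 0.5 * (np.abs(S1) ** 2 + np.abs(S2) ** 2)
    q_oracle = 0.5 * (np.abs(S2) ** 2 - np.abs(S1) ** 2) / S11
    u_oracle = (S2 * np.conj(S1)).real / S11
    assert np.abs(prof.q - q_oracle).max() < 1e-6
    assert np.abs(prof.u - u_oracle).max() < 1e-6
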