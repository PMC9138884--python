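"""Mie forward model: angle-resolved Mueller elements and scattered q(θ), u(θ).

The instrument illuminates a single suspended particle with 45° linearly
polarized light and records the linear Stokes parameters of the side-scattered
light over a continuously large angular range (60°–120°).  For a homogeneous
sphere the scattering matrix is block diagonal, and with the incident Stokes
vector ``[1, 0, 1, 0]`` (45° to the scattering plane) the normalized scattered
parameters reduce to ``q = S12/S11`` and ``u = S33/S11``.

Conventions follow Bohren & Huffman: amplitude functions

    S1(θ) = Σ_n (2n+1)/(n(n+1)) (a_n π_n + b_n τ_n)
    S2(θ) = Σ_n (2n+1)/(n(n+1)) (a_n τ_n + b_n π_n)

with S11 = (|S1|² + |S2|²)/2, S12 = (|S2|² − |S1|²)/2, S33 = Re(S2 S1*),
S34 = Im(S2 S1*).  The size parameter uses the wavelength in the medium:
x = π d n_medium / λ_vacuum; the relative index is m = n_particle / n_medium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profiles import PCLARProfile, default_angle_grid

__all__ = [
    "OpticalContext",
    "SphereParticle",
    "MieSeries",
    "MuellerProfile",
    "MieNumericalError",
    "size_parameter",
    "wiscombe_order",
    "mie_coefficients",
    "amplitude_functions",
    "mueller_profile",
    "simulate_pclar",
]

_X_GUARD = 1.0e4


class MieNumericalError(RuntimeError):
    """Raised when the series evaluation produces non-finite coefficients."""


@dataclass(frozen=True)
class OpticalContext:
    """Illumination wavelength and host-medium refractive index.

    Parameters
    ----------
    wavelength_nm
        Vacuum wavelength in nanometres (the instrument uses 532 nm).
    n_medium
        Real refractive index of the suspending medium (water: 1.330).
    """

    wavelength_nm: float = 532.0
    n_medium: float = 1.330

    def __post_init__(self) -> None:
        if not self.wavelength_nm > 0:
            raise ValueError("wavelength_nm must be positive")
        if not self.n_medium >= 1.0:
            raise ValueError("n_medium must be >= 1")

    @property
    def wavelength_um(self) -> float:
        return self.wavelength_nm / 1000.0


@dataclass(frozen=True)
class SphereParticle:
    """Homogeneous sphere: diameter (μm) and complex refractive index.

    The imaginary part of ``n_particle`` is absorption and must be >= 0.
    """

    diameter_um: float
    n_particle: complex

    def __post_init__(self) -> None:
        if not self.diameter_um > 0:
            raise ValueError("diameter_um must be positive")
        if complex(self.n_particle).imag < 0:
            raise ValueError("Im(n_particle) must be >= 0 (absorption)")


@dataclass(frozen=True)
class MieSeries:
    """Converged Lorenz–Mie expansion for one particle/context pair."""

    x: float
    m: complex
    a: np.ndarray  # a_n, n = 1..N
    b: np.ndarray  # b_n, n = 1..N

    @property
    def order(self) -> int:
        return len(self.a)


@dataclass(frozen=True)
class MuellerProfile:
    """Non-zero scattering-matrix elements of a sphere versus angle."""

    theta_deg: np.ndarray
    S11: np.ndarray
    S12: np.ndarray
    S33: np.ndarray
    S34: np.ndarray


def size_parameter(particle: SphereParticle, context: OpticalContext) -> float:
    """x = π d n_medium / λ_vacuum (wavelength in the medium)."""
    return float(np.pi * particle.diameter_um * context.n_medium / context.wavelength_um)


def wiscombe_order(x: float) -> int:
    """Series truncation order N = ceil(x + 4.05 x^(1/3) + 2)."""
    return int(np.ceil(x + 4.05 * x ** (1.0 / 3.0) + 2.0))


def mie_coefficients(
    particle: SphereParticle,
    context: OpticalContext,
    n_terms: int | None = None,
) -> MieSeries:
    """Expansion coefficients a_n, b_n for a homogeneous sphere.

    Uses the logarithmic derivative D_n(mx) by downward recurrence (started
    well above the truncation order) and upward recurrence for the
    Riccati–Bessel functions ψ_n(x), χ_n(x) — the numerically stable route
    for size parameters up to a few hundred.
    """
    x = size_parameter(particle, context)
    if x > _X_GUARD:
        raise ValueError(f"size parameter x={x:.3g} exceeds guard {_X_GUARD:g}")
    m = complex(particle.n_particle) / context.n_medium
    N = n_terms if n_terms is not None else wiscombe_order(x)
    if N < 1:
        N = 1

    if m == 1.0:  # index matched: no scattering contrast
        z = np.zeros(N, dtype=complex)
        return MieSeries(x=x, m=m, a=z, b=z.copy())

    mx = m * x
    # downward recurrence for the logarithmic derivative
    n_start = max(N, int(np.ceil(abs(mx)))) + 16
    D = np.zeros(n_start + 1, dtype=complex)
    for n in range(n_start, 0, -1):
        D[n - 1] = n / mx - 1.0 / (D[n] + n / mx)
    D = D[1 : N + 1]

    n = np.arange(1, N + 1, dtype=float)
    # Riccati–Bessel via upward recurrence
    psi = np.empty(N + 1)
    chi = np.empty(N + 1)
    psi_m1, psi[0] = np.cos(x), np.sin(x)
    chi_m1, chi[0] = -np.sin(x), np.cos(x)
    for k in range(1, N + 1):
        fac = (2.0 * k - 1.0) / x
        psi[k] = fac * psi[k - 1] - (psi[k - 2] if k >= 2 else psi_m1)
        chi[k] = fac * chi[k - 1] - (chi[k - 2] if k >= 2 else chi_m1)
    xi = psi + 1j * chi
    psi_n, psi_nm1 = psi[1:], psi[:-1]
    xi_n, xi_nm1 = xi[1:], xi[:-1]

    da = D / m + n / x
    db = D * m + n / x
    a = (da * psi_n - psi_nm1) / (da * xi_n - xi_nm1)
    b = (db * psi_n - psi_nm1) / (db * xi_n - xi_nm1)

    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise MieNumericalError(f"non-finite Mie coefficients at x={x:.6g}, m={m:.6g}")
    return MieSeries(x=x, m=m, a=a, b=b)


def amplitude_functions(series: MieSeries, theta_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scattering amplitudes S1(θ), S2(θ) from the expansion coefficients."""
    theta_deg = np.atleast_1d(np.asarray(theta_deg, dtype=float))
    if theta_deg.size == 0:
        raise ValueError("empty angle grid")
    if np.any(theta_deg < 0) or np.any(theta_deg > 180):
        raise ValueError("scattering angles must lie in [0°, 180°]")
    mu = np.cos(np.deg2rad(theta_deg))
    N = series.order
    S1 = np.zeros_like(mu, dtype=complex)
    S2 = np.zeros_like(mu, dtype=complex)
    # angular functions π_n, τ_n by upward recurrence, accumulated in place
    pi_nm1 = np.zeros_like(mu)
    pi_n = np.ones_like(mu)
    for k in range(1, N + 1):
        tau_n = k * mu * pi_n - (k + 1) * pi_nm1
        f = (2.0 * k + 1.0) / (k * (k + 1.0))
        S1 += f * (series.a[k - 1] * pi_n + series.b[k - 1] * tau_n)
        S2 += f * (series.a[k - 1] * tau_n + series.b[k - 1] * pi_n)
        pi_np1 = ((2.0 * k + 1.0) * mu * pi_n - (k + 1.0) * pi_nm1) / k
        pi_nm1, pi_n = pi_n, pi_np1
    return S1, S2


def mueller_profile(series: MieSeries, theta_deg: np.ndarray) -> MuellerProfile:
    """S11, S12, S33, S34 per angle (unnormalized intensity units)."""
    theta_deg = np.atleast_1d(np.asarray(theta_deg, dtype=float))
    S1, S2 = amplitude_functions(series, theta_deg)
    a1, a2 = np.abs(S1) ** 2, np.abs(S2) ** 2
    cross = S2 * np.conj(S1)
    return MuellerProfile(
        theta_deg=theta_deg,
        S11=0.5 * (a1 + a2),
        S12=0.5 * (a2 - a1),
        S33=cross.real,
        S34=cross.imag,
    )


def simulate_pclar(
    particle: SphereParticle,
    context: OpticalContext | None = None,
    theta_deg: np.ndarray | None = None,
    n_terms: int | None = None,
) -> PCLARProfile:
    """Scattered q(θ), u(θ) for 45°-linear illumination.

    The incident Stokes vector in the scattering-plane frame is [1, 0, 1, 0],
    so the scattered linear parameters are q = S12/S11 and u = S33/S11; the
    unnormalized intensity S11 is attached for detector simulation.
    """
    context = context or OpticalContext()
    if theta_deg is None:
        theta_deg = default_angle_grid()
    series = mie_coefficients(particle, context, n_terms=n_terms)
    mm = mueller_profile(series, theta_deg)
    if np.any(mm.S11 <= 0):
        raise MieNumericalError("S11 vanished at one or more angles; cannot normalize q, u")
    return PCLARProfile(
        theta_deg=mm.theta_deg,
        q=mm.S12 / mm.S11,
        u=mm.S33 / mm.S11,
        intensity=mm.S11,
    )
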