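"""Linear-Stokes reconstruction and per-pixel polarimetric calibration.

The detector has three polarizer rows at 0°, 135° and 90°.  From their
intensities the linear part of the Stokes vector is

    I = I0 + I90,   Q = I0 − I90,   U = I0 + I90 − 2·I135.

Production deviations (per-pixel gain, polarizer-angle error, finite
extinction) make the raw reconstruction biased.  They are corrected with a
per-pixel 3×3 calibration matrix fitted from a sweep of 18 known linear
polarization states (a rotating polarizer stepped 0°..170°):

    A = S_meas · pinv(S_ref)        (fit, reference → measured)
    S_corrected = pinv(A) · S_meas  (application)

Scalar summaries: DoLP = √(Q²+U²)/I and AoP = ½·atan2(U, Q) in [−90°, 90°).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "StokesLinear",
    "StokesSweep",
    "CalibrationMatrix",
    "DegenerateSweepError",
    "IllConditionedError",
    "UndefinedAngleError",
    "stokes_linear",
    "fit_calibration",
    "apply_calibration",
    "dolp",
    "aop",
    "write_calibration",
    "read_calibration",
]

N_SWEEP_STATES = 18


class DegenerateSweepError(ValueError):
    """Reference sweep does not span the 3-D linear-Stokes space."""


class IllConditionedError(RuntimeError):
    """Calibration matrix condition number exceeds the configured bound."""


class UndefinedAngleError(ValueError):
    """AoP requested for a beam with Q = U = 0."""


@dataclass
class StokesLinear:
    """Linear Stokes triple (I, Q, U); fields may be scalars or arrays."""

    I: np.ndarray | float
    Q: np.ndarray | float
    U: np.ndarray | float

    def as_array(self) -> np.ndarray:
        """Stack to shape (..., 3)."""
        return np.stack(np.broadcast_arrays(self.I, self.Q, self.U), axis=-1)

    @property
    def q(self) -> np.ndarray | float:
        if np.any(np.asarray(self.I) == 0):
            raise ZeroDivisionError("q undefined for I = 0")
        return self.Q / self.I

    @property
    def u(self) -> np.ndarray | float:
        if np.any(np.asarray(self.I) == 0):
            raise ZeroDivisionError("u undefined for I = 0")
        return self.U / self.I

    @classmethod
    def linear_beam(cls, intensity: float, angle_deg: float) -> "StokesLinear":
        """Fully linearly polarized beam at the given polarization angle."""
        a = np.deg2rad(2.0 * angle_deg)
        return cls(I=intensity, Q=intensity * np.cos(a), U=intensity * np.sin(a))


def stokes_linear(I0, I135, I90) -> StokesLinear:
    """Linear Stokes triple from the three analyzer-row intensities."""
    I0, I135, I90 = (np.asarray(v, dtype=float) for v in (I0, I135, I90))
    if np.any(I0 < 0) or np.any(I135 < 0) or np.any(I90 < 0):
        raise ValueError("row intensities must be non-negative")
    I = I0 + I90
    return StokesLinear(I=I, Q=I0 - I90, U=I - 2.0 * I135)


@dataclass
class StokesSweep:
    """3×18 matrix of linear Stokes columns, one per polarizer setting."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, N_SWEEP_STATES):
            raise ValueError(f"sweep must be 3x{N_SWEEP_STATES}, got {self.matrix.shape}")

    @classmethod
    def ideal_rotating_polarizer(cls, intensity: float = 1.0) -> "StokesSweep":
        """Reference states for a polarizer stepped 0°..170° in 10° steps."""
        angles = np.arange(N_SWEEP_STATES) * 10.0
        a = np.deg2rad(2.0 * angles)
        return cls(np.stack([np.full_like(a, intensity),
                             intensity * np.cos(a),
                             intensity * np.sin(a)]))


@dataclass
class CalibrationMatrix:
    """Per-pixel 3×3 calibration matrices with fit diagnostics.

    ``A`` has shape (n_pixels, 3, 3); a single-pixel (3, 3) matrix is
    promoted.  ``condition`` records cond(A) per pixel, ``residual`` the
    per-pixel Frobenius norm of the training-sweep fit residual.
    """

    A: np.ndarray
    condition: np.ndarray = field(default=None)  # type: ignore[assignment]
    residual: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim == 2:
            self.A = self.A[None]
        if self.A.ndim != 3 or self.A.shape[1:] != (3, 3):
            raise ValueError("A must have shape (n_pixels, 3, 3)")
        if self.condition is None:
            self.condition = np.linalg.cond(self.A)

    @property
    def n_pixels(self) -> int:
        return self.A.shape[0]

    @classmethod
    def identity(cls, n_pixels: int = 1) -> "CalibrationMatrix":
        return cls(np.broadcast_to(np.eye(3), (n_pixels, 3, 3)).copy())


def fit_calibration(measured: StokesSweep | np.ndarray,
                    reference: StokesSweep) -> CalibrationMatrix:
    """Least-squares per-pixel calibration matrix A = S_meas · pinv(S_ref).

    ``measured`` may be one sweep (3×18) or a per-pixel stack (n_pixels, 3, 18).
    """
    ref = reference.matrix
    if np.linalg.matrix_rank(ref, tol=1e-9 * np.abs(ref).max()) < 3:
        raise DegenerateSweepError("reference sweep does not span linear-Stokes space")
    meas = measured.matrix if isinstance(measured, StokesSweep) else np.asarray(measured, float)
    single = meas.ndim == 2
    if single:
        meas = meas[None]
    if meas.shape[1:] != ref.shape:
        raise ValueError(f"measured sweep shape {meas.shape[1:]} != reference {ref.shape}")
    A = meas @ np.linalg.pinv(ref)
    residual = np.linalg.norm(A @ ref - meas, axis=(1, 2))
    return CalibrationMatrix(A=A, residual=residual)


def apply_calibration(cal: CalibrationMatrix,
                      s_meas: StokesLinear,
                      condition_bound: float = 1e8,
                      clip: bool = True) -> StokesLinear:
    """Correct measured Stokes vectors: s = pinv(A) · s_meas.

    ``s_meas`` fields are per-pixel arrays of length cal.n_pixels (or scalars
    for a single-pixel calibration).  Unphysical results (√(Q²+U²) > I) are
    clipped back to the physical cone with a warning.
    """
    if np.any(cal.condition > condition_bound):
        worst = float(np.max(cal.condition))
        raise IllConditionedError(f"calibration condition number {worst:.3g} exceeds bound")
    vec = np.atleast_2d(s_meas.as_array())  # (n_pixels, 3)
    Ainv = np.linalg.pinv(cal.A)
    out = np.einsum("pij,pj->pi", Ainv, vec)
    I, Q, U = out[:, 0], out[:, 1], out[:, 2]
    if clip:
        p = np.hypot(Q, U)
        bad = p > I
        if np.any(bad):
            warnings.warn(f"clipped {int(bad.sum())} unphysical Stokes vectors to DoLP = 1",
                          RuntimeWarning, stacklevel=2)
            with np.errstate(invalid="ignore", divide="ignore"):
                scale = np.where(bad & (p > 0), np.abs(I) / np.where(p > 0, p, 1.0), 1.0)
            Q, U = Q * scale, U * scale
    if np.isscalar(s_meas.I):
        return StokesLinear(I=float(I[0]), Q=float(Q[0]), U=float(U[0]))
    return StokesLinear(I=I, Q=Q, U=U)


def dolp(s: StokesLinear) -> np.ndarray | float:
    """Degree of linear polarization √(Q² + U²) / I."""
    I = np.asarray(s.I, dtype=float)
    if np.any(I <= 0):
        raise ValueError("DoLP requires I > 0")
    return np.hypot(s.Q, s.U) / s.I


def aop(s: StokesLinear) -> np.ndarray | float:
    """Angle of polarization ½·atan2(U, Q), in degrees, mapped to [−90°, 90°)."""
    Q, U = np.asarray(s.Q, float), np.asarray(s.U, float)
    if np.all((Q == 0) & (U == 0)):
        raise UndefinedAngleError("AoP undefined for Q = U = 0")
    ang = 0.5 * np.degrees(np.arctan2(U, Q))
    ang = np.where(ang >= 90.0, ang - 180.0, ang)
    return float(ang) if ang.ndim == 0 else ang


def write_calibration(cal: CalibrationMatrix, path: str | Path) -> None:
    """Delimited text: pixel index, 9 row-major matrix entries, condition."""
    with open(path, "w", newline="\n") as fh:
        fh.write("pixel," + ",".join(f"a{i}{j}" for i in range(3) for j in range(3))
                 + ",condition\n")
        for p in range(cal.n_pixels):
            entries = ",".join("%.17g" % v for v in cal.A[p].ravel())
            fh.write(f"{p},{entries},%.17g\n" % cal.condition[p])


def read_calibration(path: str | Path) -> CalibrationMatrix:
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    A = data[:, 1:10].reshape(-1, 3, 3)
    return CalibrationMatrix(A=A, condition=data[:, 10])
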