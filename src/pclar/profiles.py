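"""The PCLAR container: polarization parameters over a continuous angle range.

A profile holds q(θ) = Q/I and u(θ) = U/I of the light a single particle
scatters, sampled on a dense angular grid.  The standard instrument grid maps
1458 detector pixels linearly onto [60°, 120°] (≈0.0412° per pixel).
Profiles round-trip through delimited text files with columns
``theta_deg,q,u[,intensity]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "N_ANGLES",
    "THETA_MIN_DEG",
    "THETA_MAX_DEG",
    "PCLARProfile",
    "default_angle_grid",
    "read_profile",
    "write_profile",
]

N_ANGLES = 1458
THETA_MIN_DEG = 60.0
THETA_MAX_DEG = 120.0

#: floats are serialized at 17 significant digits for lossless round trips
_FLOAT_FMT = "%.17g"


def default_angle_grid(
    n_angles: int = N_ANGLES,
    theta_min: float = THETA_MIN_DEG,
    theta_max: float = THETA_MAX_DEG,
) -> np.ndarray:
    """Uniform angle grid inclusive of both endpoints (pixel-center angles)."""
    return np.linspace(theta_min, theta_max, n_angles)


@dataclass
class PCLARProfile:
    """q(θ), u(θ) (and optionally intensity) for one particle."""

    theta_deg: np.ndarray
    q: np.ndarray
    u: np.ndarray
    intensity: np.ndarray | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.theta_deg = np.asarray(self.theta_deg, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if not (len(self.theta_deg) == len(self.q) == len(self.u)):
            raise ValueError("theta, q, u must have equal length")
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)
            if len(self.intensity) != len(self.theta_deg):
                raise ValueError("intensity length mismatch")
        if np.any(np.abs(self.q) > 1 + 1e-9) or np.any(np.abs(self.u) > 1 + 1e-9):
            raise ValueError("q and u must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(self.theta_deg)

    @property
    def degree_of_polarization(self) -> np.ndarray:
        """√(q² + u²); ≤ 1, and = 1 for noiseless fully polarized scattering."""
        return np.hypot(self.q, self.u)


def write_profile(profile: PCLARProfile, path: str | Path) -> None:
    data = {"theta_deg": profile.theta_deg, "q": profile.q, "u": profile.u}
    if profile.intensity is not None:
        data["intensity"] = profile.intensity
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_profile(path: str | Path, label: str | None = None) -> PCLARProfile:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("theta_deg", "q", "u"):
        if col not in df.columns:
            raise ValueError(f"profile file {path} lacks required column {col!r}")
    intensity = df["intensity"].to_numpy() if "intensity" in df.columns else None
    return PCLARProfile(
        theta_deg=df["theta_deg"].to_numpy(),
        q=df["q"].to_numpy(),
        u=df["u"].to_numpy(),
        intensity=intensity,
        label=label,
    )
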