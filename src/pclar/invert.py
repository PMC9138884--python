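"""Effective-sphere retrieval: diameter and complex index from a profile.

A measured q(θ), u(θ) profile is matched against the homogeneous-sphere
forward model over a parameter grid (diameter, Re n, Im n), with an optional
Nelder–Mead refinement from the best grid node.  The objective is the
angle-mean of the squared q and u residuals, equally weighted; absolute
intensity carries no calibrated scale in the measurement and is excluded.

For non-spherical particles the result is an *effective* sphere: the size
dominates the number and angular locations of the oscillation extrema while
the refractive index mainly sets the value range, so the fit is a compact,
physically interpretable summary rather than a shape reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .mie import OpticalContext, SphereParticle, simulate_pclar
from .profiles import PCLARProfile

__all__ = [
    "ParameterGrid",
    "ForwardGrid",
    "FitResult",
    "BoundaryWarning",
    "objective",
    "fit_sphere",
]


class BoundaryWarning(UserWarning):
    """Grid minimum on the boundary — the search range should be extended."""


@dataclass(frozen=True)
class ParameterGrid:
    """Search grid over (diameter μm, Re n, Im n).

    The default spans all the instrument's specimen families (2–40 μm,
    n 1.33–1.65, absorption up to 0.01); narrower grids focus on a known
    particle family at far lower cost.
    """

    diameters_um: np.ndarray = field(
        default_factory=lambda: np.arange(2.0, 40.0 + 1e-9, 0.25))
    n_reals: np.ndarray = field(
        default_factory=lambda: np.arange(1.33, 1.65 + 1e-9, 0.002))
    n_imags: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 0.01 + 1e-9, 0.0005))

    def __post_init__(self) -> None:
        for name in ("diameters_um", "n_reals", "n_imags"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.size == 0:
                raise ValueError(f"{name} must be non-empty")
            object.__setattr__(self, name, v)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.diameters_um), len(self.n_reals), len(self.n_imags))


def _boxcar(v: np.ndarray, w: int) -> np.ndarray:
    kernel = np.ones(w) / w
    pad = np.pad(v, (w // 2, w - 1 - w // 2), mode="edge")
    return np.convolve(pad, kernel, mode="valid")


def objective(observed: PCLARProfile, candidate: SphereParticle,
              context: OpticalContext | None = None,
              smooth_window: int | None = None) -> float:
    """Mean over angles of (q_obs − q_sim)² + (u_obs − u_sim)².

    ``smooth_window`` (pixels) applies a boxcar to the *simulated* profile to
    mimic the angular blurring of pulse-averaged measurements.
    """
    context = context or OpticalContext()
    sim = simulate_pclar(candidate, context, observed.theta_deg)
    qs, us = sim.q, sim.u
    if smooth_window is not None and smooth_window > 1:
        qs, us = _boxcar(qs, smooth_window), _boxcar(us, smooth_window)
    return float(np.mean((observed.q - qs) ** 2 + (observed.u - us) ** 2))


@dataclass
class ForwardGrid:
    """Cached simulated (q, u) over a parameter grid on a fixed angle grid.

    Building once and fitting many observations amortizes the forward-model
    cost (e.g. repeated noisy retrievals in a recovery study).
    """

    grid: ParameterGrid
    context: OpticalContext
    theta_deg: np.ndarray
    q: np.ndarray = field(default=None)  # type: ignore[assignment]
    u: np.ndarray = field(default=None)  # type: ignore[assignment]

    @classmethod
    def build(cls, grid: ParameterGrid, context: OpticalContext,
              theta_deg: np.ndarray) -> "ForwardGrid":
        nd, nr, ni = grid.shape
        nt = len(theta_deg)
        q = np.empty((nd, nr, ni, nt), dtype=np.float32)
        u = np.empty_like(q)
        for i, d in enumerate(grid.diameters_um):
            for j, nre in enumerate(grid.n_reals):
                for k, nim in enumerate(grid.n_imags):
                    prof = simulate_pclar(SphereParticle(d, complex(nre, nim)),
                                          context, theta_deg)
                    q[i, j, k] = prof.q
                    u[i, j, k] = prof.u
        return cls(grid=grid, context=context, theta_deg=np.asarray(theta_deg),
                   q=q, u=u)

    def surface(self, observed: PCLARProfile) -> np.ndarray:
        """Objective over every grid node, vectorized."""
        dq = self.q - observed.q.astype(np.float32)
        du = self.u - observed.u.astype(np.float32)
        return (dq ** 2 + du ** 2).mean(axis=-1).astype(float)


@dataclass
class FitResult:
    """Best-fitting sphere, objective value and diagnostics."""

    particle: SphereParticle
    objective_value: float
    surface: np.ndarray  # (n_d, n_real, n_imag)
    grid: ParameterGrid
    grid_particle: SphereParticle
    refined: bool
    n_evaluations: int


def fit_sphere(observed: PCLARProfile,
               grid: ParameterGrid | None = None,
               context: OpticalContext | None = None,
               refine: bool = True,
               forward: ForwardGrid | None = None) -> FitResult:
    """Exhaustive grid search for the best-fitting homogeneous sphere.

    A prebuilt :class:`ForwardGrid` may be supplied to reuse cached forward
    simulations.  With ``refine`` a Nelder–Mead simplex polishes the best
    node in continuous parameter space (bounded to the grid's hull).  A
    minimum on the grid boundary raises :class:`BoundaryWarning`.
    """
    context = context or OpticalContext()
    if forward is None:
        grid = grid or ParameterGrid()
        forward = ForwardGrid.build(grid, context, observed.theta_deg)
    else:
        grid = forward.grid
        if len(forward.theta_deg) != len(observed.theta_deg):
            raise ValueError("forward grid angle grid does not match observation")
    surface = forward.surface(observed)
    flat = int(np.argmin(surface))
    i, j, k = np.unravel_index(flat, surface.shape)
    for axis, idx, n in (("diameter", i, surface.shape[0]),
                         ("n_real", j, surface.shape[1]),
                         ("n_imag", k, surface.shape[2])):
        if n > 1 and idx in (0, n - 1):
            warnings.warn(f"fit minimum on the {axis} grid boundary; "
                          "extend the search range", BoundaryWarning, stacklevel=2)
    best = SphereParticle(float(grid.diameters_um[i]),
                          complex(grid.n_reals[j], grid.n_imags[k]))
    best_val = float(surface[i, j, k])
    n_eval = surface.size
    refined_particle, refined_val, did_refine = best, best_val, False
    if refine:
        lo = np.array([grid.diameters_um[0], grid.n_reals[0], grid.n_imags[0]])
        hi = np.array([grid.diameters_um[-1], grid.n_reals[-1], grid.n_imags[-1]])

        def f(p: np.ndarray) -> float:
            p = np.clip(p, lo, hi)
            cand = SphereParticle(float(p[0]), complex(p[1], max(p[2], 0.0)))
            return objective(observed, cand, context)

        x0 = np.array([best.diameter_um, best.n_particle.real, best.n_particle.imag])
        res = optimize.minimize(f, x0, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-10,
                                         "maxfev": 400})
        n_eval += res.nfev
        if res.fun < best_val:
            p = np.clip(res.x, lo, hi)
            refined_particle = SphereParticle(float(p[0]),
                                              complex(p[1], max(p[2], 0.0)))
            refined_val = float(res.fun)
            did_refine = True
    return FitResult(particle=refined_particle, objective_value=refined_val,
                     surface=surface, grid=grid, grid_particle=best,
                     refined=did_refine, n_evaluations=n_eval)
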