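"""Porous polystyrene sphere (PSH) geometry by iterative surface erosion.

The structured microsphere is modelled by starting from a solid 10 μm host
sphere and repeatedly subtracting small spheres (0.4 μm diameter) whose
centers are drawn uniformly at random from the *current* model surface —
200 spheres per iteration, 50 iterations by default.  The surface of the
evolving model is operationalized as the boundary voxels of a working
lattice (occupied voxels with at least one empty 6-neighbor); subtraction is
kept lazy in continuous space (a point is inside the model iff it is inside
the host sphere and outside every subtracted sphere), so voxelization at any
spacing is exact with respect to the model.

The voxelized geometry exports to a plain-text dipole list (one ``ix iy iz``
triple per occupied voxel, comment header with the spacing) for DDA-class
electromagnetic solvers; the solve itself is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "PSHBuildSpec",
    "PorousSphereModel",
    "VoxelGrid",
    "ErosionError",
    "VoxelBudgetError",
    "build_psh_model",
    "voxelize",
    "porosity",
    "export_dda_geometry",
    "import_dda_geometry",
]

_DEFAULT_VOXEL_BUDGET = 80_000_000


class ErosionError(RuntimeError):
    """The model was eroded to nothing before the iterations finished."""


class VoxelBudgetError(MemoryError):
    """Requested lattice exceeds the configured voxel budget."""


@dataclass(frozen=True)
class PSHBuildSpec:
    """Parameters of the erosion construction (defaults per the standard
    porous-sphere recipe: 10 μm host, 0.4 μm holes, 200 per iteration,
    50 iterations)."""

    host_diameter_um: float = 10.0
    small_diameter_um: float = 0.4
    spheres_per_iteration: int = 200
    iterations: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.host_diameter_um <= 0 or self.small_diameter_um <= 0:
            raise ValueError("diameters must be positive")
        if self.small_diameter_um >= self.host_diameter_um:
            raise ValueError("small_diameter must be below host_diameter")
        if self.spheres_per_iteration < 1 or self.iterations < 0:
            raise ValueError("counts must be non-negative (iterations) / positive")


@dataclass
class PorousSphereModel:
    """Host sphere plus the list of subtracted-sphere centers (μm)."""

    host_diameter_um: float
    small_diameter_um: float
    subtracted_centers: np.ndarray  # (k, 3)
    seed: int

    @property
    def host_radius(self) -> float:
        return self.host_diameter_um / 2.0

    @property
    def small_radius(self) -> float:
        return self.small_diameter_um / 2.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Continuous-space membership test: inside host, outside every
        subtracted sphere."""
        points = np.atleast_2d(points)
        # squared-distance comparison: bitwise consistent with lattice masks
        inside = np.einsum("ij,ij->i", points, points) <= self.host_radius ** 2
        if len(self.subtracted_centers):
            tree = cKDTree(self.subtracted_centers)
            d, _ = tree.query(points, k=1)
            inside &= d > self.small_radius
        return inside


@dataclass
class VoxelGrid:
    """Cubic lattice: boolean occupancy, voxel edge length and origin.

    Voxel (i, j, k) has its center at origin + spacing·(i, j, k).
    """

    spacing_um: float
    origin_um: np.ndarray
    occupancy: np.ndarray  # 3-D bool

    def __post_init__(self) -> None:
        if self.spacing_um <= 0:
            raise ValueError("spacing must be positive")
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be a 3-D lattice")

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())

    @property
    def occupied_volume_um3(self) -> float:
        return self.n_occupied * self.spacing_um ** 3


def _lattice(radius: float, spacing: float) -> np.ndarray:
    """Voxel-center coordinate axis covering [−radius−spacing, radius+spacing].

    Computed as origin + k·spacing so every consumer reproduces the exact
    same floating-point coordinates.
    """
    n_half = int(np.ceil(radius / spacing)) + 1
    origin = -n_half * spacing
    return origin + np.arange(2 * n_half + 1) * spacing


_SIX_NEIGHBORS = ndimage.generate_binary_structure(3, 1)


def build_psh_model(spec: PSHBuildSpec,
                    lattice_spacing_um: float | None = None) -> PorousSphereModel:
    """Run the iterative surface-subtraction construction.

    Each iteration draws ``spheres_per_iteration`` centers uniformly from the
    boundary voxels of the current model (integer lattice draws only, so a
    fixed seed reproduces the build bit for bit), subtracts their spheres,
    and updates the lattice before the next iteration.
    """
    spacing = lattice_spacing_um if lattice_spacing_um is not None \
        else spec.small_diameter_um / 4.0
    R = spec.host_diameter_um / 2.0
    r = spec.small_diameter_um / 2.0
    axis = _lattice(R, spacing)
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    occ = (X ** 2 + Y ** 2 + Z ** 2) <= R ** 2

    rng = np.random.default_rng(spec.seed)
    centers: list[np.ndarray] = []
    # subtraction stencil: voxel offsets within the small-sphere radius
    reach = int(np.ceil(r / spacing))
    off = np.arange(-reach, reach + 1)
    OX, OY, OZ = np.meshgrid(off, off, off, indexing="ij")
    stencil = np.stack([OX, OY, OZ], axis=-1).reshape(-1, 3)
    stencil = stencil[np.linalg.norm(stencil * spacing, axis=1) <= r]

    for it in range(spec.iterations):
        boundary = occ & ~ndimage.binary_erosion(occ, structure=_SIX_NEIGHBORS)
        b_idx = np.argwhere(boundary)
        if len(b_idx) == 0:
            raise ErosionError(f"model eroded to empty at iteration {it}")
        draws = rng.integers(0, len(b_idx), size=spec.spheres_per_iteration)
        chosen = b_idx[draws]
        centers.append(axis[0] + chosen.astype(float) * spacing)
        # carve the new spheres out of the working lattice
        hit = chosen[:, None, :] + stencil[None, :, :]
        hit = hit.reshape(-1, 3)
        ok = np.all((hit >= 0) & (hit < occ.shape[0]), axis=1)
        hit = hit[ok]
        occ[hit[:, 0], hit[:, 1], hit[:, 2]] = False
        if not occ.any():
            raise ErosionError(f"model eroded to empty at iteration {it}")

    all_centers = (np.concatenate(centers) if centers
                   else np.empty((0, 3)))
    return PorousSphereModel(host_diameter_um=spec.host_diameter_um,
                             small_diameter_um=spec.small_diameter_um,
                             subtracted_centers=all_centers, seed=spec.seed)


def voxelize(model: PorousSphereModel, spacing_um: float,
             voxel_budget: int = _DEFAULT_VOXEL_BUDGET) -> VoxelGrid:
    """Discretize the continuous model: a voxel is occupied iff its center
    lies inside the host sphere and outside every subtracted sphere.

    ``spacing_um`` must resolve the pores: spacing ≤ small_diameter / 4.
    """
    if spacing_um > model.small_diameter_um / 4.0:
        raise ValueError("spacing must be <= small_diameter / 4 to resolve pores")
    axis = _lattice(model.host_radius, spacing_um)
    n = len(axis)
    if n ** 3 > voxel_budget:
        raise VoxelBudgetError(f"lattice {n}^3 exceeds budget {voxel_budget}")
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    occ = model.contains(pts).reshape(n, n, n)
    return VoxelGrid(spacing_um=spacing_um,
                     origin_um=np.array([axis[0]] * 3),
                     occupancy=occ)


def porosity(model: PorousSphereModel, spacing_um: float | None = None,
             grid: VoxelGrid | None = None) -> float:
    """Void fraction of the host sphere: 1 − occupied / host-sphere voxels,
    both counted on the same lattice (discretization-consistent)."""
    if grid is None:
        grid = voxelize(model, spacing_um if spacing_um is not None
                        else model.small_diameter_um / 4.0)
    axis = grid.origin_um[0] + np.arange(grid.occupancy.shape[0]) * grid.spacing_um
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    host = (X ** 2 + Y ** 2 + Z ** 2) <= model.host_radius ** 2
    n_host = int(host.sum())
    return 1.0 - grid.n_occupied / n_host


def export_dda_geometry(grid: VoxelGrid, path: str | Path) -> None:
    """ASCII dipole list: comment header, then one ``ix iy iz`` per voxel."""
    if grid.n_occupied == 0:
        raise ValueError("cannot export an empty voxel grid")
    idx = np.argwhere(grid.occupancy)
    with open(path, "w", newline="\n") as fh:
        fh.write(f"#spacing_um %.17g\n" % grid.spacing_um)
        fh.write("#origin_um " + " ".join("%.17g" % v for v in grid.origin_um) + "\n")
        fh.write("#shape " + " ".join(str(s) for s in grid.occupancy.shape) + "\n")
        np.savetxt(fh, idx, fmt="%d")


def import_dda_geometry(path: str | Path) -> VoxelGrid:
    """Parse the geometry dialect written by :func:`export_dda_geometry`."""
    spacing = None
    origin = None
    shape = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, *vals = line[1:].split()
                if key == "spacing_um":
                    spacing = float(vals[0])
                elif key == "origin_um":
                    origin = np.array([float(v) for v in vals])
                elif key == "shape":
                    shape = tuple(int(v) for v in vals)
                continue
            rows.append([int(v) for v in line.split()])
    if spacing is None or origin is None or shape is None:
        raise ValueError("geometry file lacks the required header lines")
    occ = np.zeros(shape, dtype=bool)
    if rows:
        idx = np.asarray(rows)
        occ[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return VoxelGrid(spacing_um=spacing, origin_um=origin, occupancy=occ)
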