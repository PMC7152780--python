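"""Voronoi corral meshes: the geometric model of the submembranous actin network.

A mesh is generated by seeding points in a circular arena as a homogeneous
Poisson process whose mean nearest-neighbour distance equals the requested
``seed_spacing`` (for intensity lambda, that distance is 0.5/sqrt(lambda)),
taking the Voronoi tessellation of the seeds and clipping every cell to the
arena.  The summary statistic reported for a mesh is sqrt(mean cell area),
the conventional "mesh size" of the corral network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, Point

__all__ = ["CorralMesh", "DegenerateMeshError", "generate_corral_mesh"]

_ARENA_QUAD_SEGS = 64  # 256-gon circle approximation; area error ~2.5e-5 relative


class DegenerateMeshError(ValueError):
    """Raised when too few seed points fall inside the arena to tessellate."""


@dataclass
class CorralMesh:
    """Voronoi compartments clipped to a circular arena.

    Attributes
    ----------
    seed_points : (n, 2) float array, nm
        Voronoi generator points inside the arena.
    compartments : list of (k, 2) float arrays
        Exterior vertex rings of each clipped cell, same order as the seeds.
    arena_diameter : float, nm
    """

    seed_points: np.ndarray
    compartments: list
    arena_diameter: float
    _label_grid: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def arena_radius(self) -> float:
        return self.arena_diameter / 2.0

    @property
    def arena_area(self) -> float:
        return math.pi * self.arena_radius**2

    @property
    def compartment_areas(self) -> np.ndarray:
        return np.array(
            [shapely.Polygon(ring).area for ring in self.compartments], dtype=float
        )

    @property
    def mesh_size(self) -> float:
        """sqrt(mean compartment area), nm."""
        return float(math.sqrt(self.compartment_areas.mean()))

    def locate(self, points: np.ndarray) -> np.ndarray:
        """Compartment index for each (…, 2) point via nearest-seed lookup.

        Nearest-seed membership is exactly Voronoi containment; scipy's
        KD-tree breaks exact ties by lowest index.
        """
        pts = np.asarray(points, dtype=float)
        tree = cKDTree(self.seed_points)
        _, idx = tree.query(pts.reshape(-1, 2))
        return idx.reshape(pts.shape[:-1]).astype(np.int32)

    def label_grid(self, resolution: float = 1.0):
        """Rasterized nearest-seed label map covering the arena bounding box.

        Returns ``(grid, origin, resolution)`` where ``grid[iy, ix]`` is the
        compartment index of the pixel centred at
        ``origin + (ix + 0.5, iy + 0.5) * resolution``.  Used by the
        trajectory kernel for O(1) membership tests; cached per resolution.
        """
        if self._label_grid is not None and self._label_grid[2] == resolution:
            return self._label_grid
        r = self.arena_radius
        n = int(math.ceil(2.0 * r / resolution)) + 2
        origin = -(n * resolution) / 2.0
        centers = origin + (np.arange(n) + 0.5) * resolution
        xx, yy = np.meshgrid(centers, centers)
        tree = cKDTree(self.seed_points)
        _, idx = tree.query(np.column_stack([xx.ravel(), yy.ravel()]))
        grid = idx.reshape(n, n).astype(np.int32)
        self._label_grid = (grid, origin, resolution)
        return self._label_grid


def _poisson_seeds(
    seed_spacing: float, arena_radius: float, rng: np.random.Generator
) -> np.ndarray:
    # Homogeneous Poisson process: mean NN distance = 0.5 / sqrt(lambda).
    lam = (0.5 / seed_spacing) ** 2
    area = math.pi * arena_radius**2
    n = rng.poisson(lam * area)
    # uniform points in a disk
    radii = arena_radius * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2.0 * math.pi
    return np.column_stack([radii * np.cos(theta), radii * np.sin(theta)])


def generate_corral_mesh(
    seed_spacing: float,
    arena_diameter: float,
    rng_seed: int | np.random.Generator = 0,
    *,
    seed_points: np.ndarray | None = None,
) -> CorralMesh:
    """Generate a corral mesh by Voronoi transform of random seed points.

    Parameters
    ----------
    seed_spacing : float, nm
        Target mean nearest-neighbour distance between seeds (Poisson-process
        interpretation; intensity chosen so 0.5/sqrt(lambda) = spacing).
    arena_diameter : float, nm
        Diameter of the circular arena the cells are clipped to.
    rng_seed : int or Generator
        Seed for the point process.
    seed_points : array, optional
        Explicit seeds (bypasses the point process; used for degenerate and
        oracle cases).

    Raises
    ------
    DegenerateMeshError
        If fewer than 3 seeds are available (no 2-D tessellation); a single
        explicit seed is allowed and yields the whole arena as one cell.
    """
    if seed_points is None:
        if not seed_spacing < arena_diameter / 4.0:
            raise ValueError("seed_spacing must be < arena_diameter / 4")
        rng = (
            rng_seed
            if isinstance(rng_seed, np.random.Generator)
            else np.random.default_rng(rng_seed)
        )
        seed_points = _poisson_seeds(seed_spacing, arena_diameter / 2.0, rng)
    seed_points = np.atleast_2d(np.asarray(seed_points, dtype=float))

    radius = arena_diameter / 2.0
    arena = Point(0.0, 0.0).buffer(radius, quad_segs=_ARENA_QUAD_SEGS)

    if len(seed_points) == 1:
        ring = np.asarray(arena.exterior.coords)
        return CorralMesh(seed_points, [ring], float(arena_diameter))
    if len(seed_points) < 3:
        raise DegenerateMeshError(
            f"only {len(seed_points)} seeds inside the arena; need >= 3 "
            "for a Voronoi tessellation (or exactly 1 for the trivial mesh)"
        )

    cells = shapely.voronoi_polygons(
        MultiPoint(seed_points), extend_to=arena.buffer(radius)
    )
    # voronoi_polygons does not preserve seed order: match each cell to the
    # unique seed it contains.
    compartments: list = [None] * len(seed_points)
    tree = cKDTree(seed_points)
    for poly in cells.geoms:
        clipped = poly.intersection(arena)
        if clipped.is_empty:
            continue
        _, i = tree.query(np.asarray(poly.representative_point().coords)[0])
        if clipped.geom_type == "MultiPolygon":  # pragma: no cover - clipping artefact
            clipped = max(clipped.geoms, key=lambda g: g.area)
        compartments[int(i)] = np.asarray(clipped.exterior.coords)
    if any(c is None for c in compartments):  # pragma: no cover
        raise DegenerateMeshError("Voronoi cell/seed matching failed")
    return CorralMesh(seed_points, compartments, float(arena_diameter))
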