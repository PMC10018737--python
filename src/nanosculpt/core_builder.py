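"""Crystal-lattice cores for coarse-grained nanoparticle models.

A nanoparticle core is a rigid cluster of identical beads arranged on one
of the four crystal lattices most common in bulk metals (primitive cubic,
BCC, FCC, HCP), sculpted into an analytic shape, or placed quasi-uniformly
on a sphere for hollow shells.  Lattice constants follow the touching-sphere
convention: nearest neighbors sit exactly two bead radii apart, so the bead
radius alone fixes the lattice spacing and therefore the bead density of
the core.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "LatticeSpec",
    "ShapeSpec",
    "CoreModel",
    "BULK_COORDINATION",
    "build_lattice_block",
    "sculpt_core",
    "build_core",
    "build_shell",
    "identify_surface",
    "shape_geometry",
]

#: bulk coordination number (count of touching neighbors of an interior bead)
BULK_COORDINATION = {"primitive": 6, "bcc": 8, "fcc": 12, "hcp": 12}

#: relative tolerance used for neighbor detection, in units of bead radius
NEIGHBOR_TOL = 1.0e-3

_SHAPE_ARITY = {
    "sphere": 1,
    "shell": 1,
    "octahedron": 1,
    "cylinder": 2,
    "rod": 2,
    "pyramid": 2,
    "ellipsoid": 3,
    "rectangular_prism": 3,
}


@dataclass(frozen=True)
class LatticeSpec:
    """Crystal motif plus bead radius (nm).

    The lattice constant is derived from ``bead_radius`` so that nearest
    neighbors touch: a = 2r (primitive), 4r/sqrt(3) (bcc), 2*sqrt(2)*r (fcc);
    hcp uses a = 2r with the ideal axial ratio c/a = sqrt(8/3).
    """

    motif: str
    bead_radius: float

    def __post_init__(self) -> None:
        if self.motif not in BULK_COORDINATION:
            raise ValueError(
                f"unknown lattice motif {self.motif!r}; "
                f"choose from {sorted(BULK_COORDINATION)}"
            )
        if not self.bead_radius > 0:
            raise ValueError("bead_radius must be > 0")

    @property
    def lattice_constant(self) -> float:
        r = self.bead_radius
        if self.motif == "primitive":
            return 2.0 * r
        if self.motif == "bcc":
            return 4.0 * r / math.sqrt(3.0)
        if self.motif == "fcc":
            return 2.0 * math.sqrt(2.0) * r
        return 2.0 * r  # hcp in-plane constant

    @property
    def coordination(self) -> int:
        return BULK_COORDINATION[self.motif]

    def conventional_cell(self) -> tuple[np.ndarray, np.ndarray]:
        """Orthorhombic conventional cell: per-axis periods and fractional basis.

        All four motifs are expressed on an orthorhombic cell so replication
        counts are separable per axis; hcp uses the 4-point orthorhombic
        representation of the hexagonal cell (a x sqrt(3)a x c).
        """
        a = self.lattice_constant
        if self.motif == "primitive":
            return np.array([a, a, a]), np.array([[0.0, 0.0, 0.0]])
        if self.motif == "bcc":
            return np.array([a, a, a]), np.array(
                [[0.0, 0.0, 0.0], [0.5, 0.5, 0.5]]
            )
        if self.motif == "fcc":
            return np.array([a, a, a]), np.array(
                [
                    [0.0, 0.0, 0.0],
                    [0.0, 0.5, 0.5],
                    [0.5, 0.0, 0.5],
                    [0.5, 0.5, 0.0],
                ]
            )
        # hcp: A-layer pair plus B-layer pair half a c-period up
        c = 2.0 * self.bead_radius * math.sqrt(8.0 / 3.0)
        periods = np.array([a, math.sqrt(3.0) * a, c])
        basis = np.array(
            [
                [0.0, 0.0, 0.0],
                [0.5, 0.5, 0.0],
                [0.5, 1.0 / 6.0, 0.5],
                [0.0, 2.0 / 3.0, 0.5],
            ]
        )
        return periods, basis


@dataclass(frozen=True)
class ShapeSpec:
    """Target core geometry: shape name plus shape-specific dimensions (nm).

    Dimensions by shape: radius (sphere, shell); edge (octahedron);
    radius, length (cylinder, rod); base, height (pyramid); three semiaxes
    (ellipsoid); three edges (rectangular_prism).  Cylinder, rod and pyramid
    axes run along Z; every shape is centered at the origin.
    """

    shape: str
    dimensions: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.shape not in _SHAPE_ARITY:
            raise ValueError(
                f"unknown shape {self.shape!r}; choose from {sorted(_SHAPE_ARITY)}"
            )
        dims = tuple(float(d) for d in self.dimensions)
        object.__setattr__(self, "dimensions", dims)
        arity = _SHAPE_ARITY[self.shape]
        if len(dims) != arity:
            raise ValueError(
                f"shape {self.shape!r} takes {arity} dimension(s), got {len(dims)}"
            )
        if any(d <= 0 for d in dims):
            raise ValueError(f"dimensions must be strictly positive, got {dims}")
        if self.shape == "rod" and dims[1] < 2.0 * dims[0]:
            raise ValueError(
                "rod length must be >= 2*radius (hemispherical caps are "
                "included in the total length)"
            )

    def bounding_box(self) -> np.ndarray:
        """Full extents (nm) of the axis-aligned bounding box, per axis."""
        d = self.dimensions
        if self.shape in ("sphere", "shell"):
            return np.full(3, 2.0 * d[0])
        if self.shape == "octahedron":
            # regular octahedron, vertices on the axes at the circumradius
            s = math.sqrt(2.0) * d[0]
            return np.full(3, s)
        if self.shape in ("cylinder", "rod"):
            return np.array([2.0 * d[0], 2.0 * d[0], d[1]])
        if self.shape == "pyramid":
            return np.array([d[0], d[0], d[1]])
        if self.shape == "ellipsoid":
            return 2.0 * np.asarray(d)
        return np.asarray(d)  # rectangular_prism

    def contains(self, points: np.ndarray, tol: float = 1.0e-9) -> np.ndarray:
        """Boundary-inclusive center-inclusion test for an (N, 3) array."""
        p = np.asarray(points, dtype=float)
        d = self.dimensions
        if self.shape in ("sphere", "shell"):
            return np.einsum("ij,ij->i", p, p) <= (d[0] + tol) ** 2
        if self.shape == "octahedron":
            rho = d[0] / math.sqrt(2.0)  # circumradius of edge-length d[0]
            return np.abs(p).sum(axis=1) <= rho + tol
        if self.shape == "cylinder":
            radial = p[:, 0] ** 2 + p[:, 1] ** 2 <= (d[0] + tol) ** 2
            axial = np.abs(p[:, 2]) <= d[1] / 2.0 + tol
            return radial & axial
        if self.shape == "rod":
            rho, length = d
            half_cyl = length / 2.0 - rho  # cylindrical section half-length
            z = np.clip(p[:, 2], -half_cyl, half_cyl)
            dist2 = p[:, 0] ** 2 + p[:, 1] ** 2 + (p[:, 2] - z) ** 2
            return dist2 <= (rho + tol) ** 2
        if self.shape == "pyramid":
            base, height = d
            z = p[:, 2]
            inside_z = np.abs(z) <= height / 2.0 + tol
            # half-width shrinks linearly from b/2 at the base to 0 at the apex
            half_w = (base / 2.0) * (height / 2.0 - z) / height
            return (
                inside_z
                & (np.abs(p[:, 0]) <= half_w + tol)
                & (np.abs(p[:, 1]) <= half_w + tol)
            )
        if self.shape == "ellipsoid":
            scaled = p / np.asarray(d)
            return np.einsum("ij,ij->i", scaled, scaled) <= 1.0 + tol
        half = np.asarray(d) / 2.0
        return np.all(np.abs(p) <= half + tol, axis=1)


@dataclass
class CoreModel:
    """A built core: bead positions plus (lazily filled) surface information.

    ``lattice`` is ``None`` for hollow shells, which carry no crystal motif.
    ``masses`` stays ``None`` until :func:`nanosculpt.topology.assign_core_masses`
    distributes the bulk mass over the beads.
    """

    positions: np.ndarray
    bead_radius: float
    shape: ShapeSpec
    lattice: LatticeSpec | None = None
    masses: np.ndarray | None = None
    surface_index: np.ndarray | None = None
    normals: np.ndarray | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def is_shell(self) -> bool:
        return self.lattice is None

    def center_of_mass(self) -> np.ndarray:
        if self.masses is None:
            return self.positions.mean(axis=0)
        return self.masses @ self.positions / self.masses.sum()


def build_lattice_block(lattice: LatticeSpec, extents) -> np.ndarray:
    """Tile the conventional cell into a block centered on the origin.

    Replicates whole cells along each axis so that the resulting slab of
    lattice points fits inside the requested extents, then re-centers the
    point set on the origin.  For a primitive lattice this yields exactly
    (floor(L/a) + 1)**3 beads for an L x L x L block.
    """
    extents = np.asarray(extents, dtype=float)
    if extents.shape != (3,):
        raise ValueError("extents must be three lengths (nm)")
    for axis, name in enumerate("xyz"):
        if extents[axis] <= 0:
            raise ValueError(f"extent along {name} must be positive, got {extents[axis]}")

    periods, basis = lattice.conventional_cell()
    tol = NEIGHBOR_TOL * lattice.bead_radius
    n_cells = np.floor(extents / periods + tol).astype(int)

    grids = [np.arange(n + 1) for n in n_cells]
    ii, jj, kk = np.meshgrid(*grids, indexing="ij")
    cells = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(float)
    # every basis offset in every cell, then crop to the closed block
    pts = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 3) * periods
    keep = np.all(pts <= n_cells * periods + tol, axis=1)
    pts = pts[keep]
    return pts - n_cells * periods / 2.0


def sculpt_core(block: np.ndarray, shape: ShapeSpec,
                lattice: LatticeSpec | None = None,
                bead_radius: float | None = None) -> CoreModel:
    """Carve the target shape out of a lattice block.

    Keeps exactly the beads whose centers pass the boundary-inclusive
    analytic inside-test of ``shape``.  The block must circumscribe the
    shape's bounding box.
    """
    if shape.shape == "shell":
        raise ValueError("hollow shells are built with build_shell, not sculpted")
    block = np.asarray(block, dtype=float)
    if block.ndim != 2 or block.shape[1] != 3:
        raise ValueError("block must be an (N, 3) array of bead positions")
    if bead_radius is None:
        if lattice is None:
            raise ValueError("provide either a LatticeSpec or a bead_radius")
        bead_radius = lattice.bead_radius

    span = block.max(axis=0) - block.min(axis=0)
    need = shape.bounding_box()
    # allow up to one conventional cell of slack per side: near analytic
    # vertices (octahedron tips, pyramid apex) the outermost surviving bead
    # can sit almost a full cell inside the boundary, and re-sculpting an
    # already-sculpted core must be a no-op, not an error
    if lattice is not None:
        periods, _ = lattice.conventional_cell()
        slack = 2.0 * periods
    else:
        slack = np.full(3, 6.0 * bead_radius)
    if np.any(span + slack + NEIGHBOR_TOL * bead_radius < need):
        raise ValueError(
            f"block extents {span} cannot circumscribe shape bounding box {need}"
        )

    keep = shape.contains(block, tol=NEIGHBOR_TOL * bead_radius)
    positions = block[keep]
    if len(positions) == 0:
        raise ValueError("no beads survive sculpting; shape smaller than the lattice spacing")
    return CoreModel(
        positions=positions,
        bead_radius=float(bead_radius),
        shape=shape,
        lattice=lattice,
    )


def build_core(lattice: LatticeSpec, shape: ShapeSpec) -> CoreModel:
    """Convenience: tile a block with a one-cell margin and sculpt it."""
    periods, _ = lattice.conventional_cell()
    extents = shape.bounding_box() + 2.0 * periods
    block = build_lattice_block(lattice, extents)
    return sculpt_core(block, shape, lattice=lattice)


def build_shell(radius: float, bead_radius: float) -> CoreModel:
    """Hollow spherical shell of beads; no crystal lattice is involved.

    Beads are laid on a golden-angle (Fibonacci) spiral, a deterministic
    quasi-uniform spherical lattice.  The bead count comes from an area
    budget: each bead claims the area of a hexagonal-packing tile of
    side-to-side width 2*bead_radius, giving a mean nearest-neighbor
    spacing of about two bead radii.
    """
    if not radius > bead_radius:
        raise ValueError("shell radius must exceed the bead radius")
    # hexagonal tile area per bead: (sqrt(3)/2) * (2r)^2
    n = int(round(4.0 * math.pi * radius**2 / (2.0 * math.sqrt(3.0) * bead_radius**2)))
    if n < 4:
        raise ValueError(
            f"shell radius {radius} nm too small for bead radius {bead_radius} nm: "
            f"area budget allows only {n} beads (need >= 4)"
        )
    i = np.arange(n, dtype=float)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = golden * i
    unit = np.stack([rho * np.cos(theta), rho * np.sin(theta), z], axis=1)
    positions = radius * unit
    shape = ShapeSpec("shell", (radius,))
    return CoreModel(
        positions=positions,
        bead_radius=float(bead_radius),
        shape=shape,
        lattice=None,
        surface_index=np.arange(n),
        normals=unit,
    )


def identify_surface(core: CoreModel) -> CoreModel:
    """Flag superficial beads and store their outward normals.

    A bead is superficial when it has fewer touching neighbors (within
    2r + tolerance) than the bulk coordination of its lattice.  The normal
    is the unit vector from the core's center of mass to the bead — exact
    for spheres and a serviceable approximation on the flat faces of the
    other convex shapes.
    """
    if core.is_shell:
        return core  # every shell bead is superficial by construction
    r = core.bead_radius
    cutoff = 2.0 * r + NEIGHBOR_TOL * r
    if core.n_beads == 1:
        core.surface_index = np.array([0])
        core.normals = np.array([[0.0, 0.0, 1.0]])
        core.notes.append("single-bead core: surface normal is arbitrary (+Z)")
        return core
    tree = cKDTree(core.positions)
    counts = tree.query_ball_point(core.positions, cutoff, return_length=True) - 1
    bulk = core.lattice.coordination
    surface = np.flatnonzero(counts < bulk)
    com = core.positions.mean(axis=0)
    vec = core.positions[surface] - com
    norm = np.linalg.norm(vec, axis=1, keepdims=True)
    degenerate = norm[:, 0] < 1.0e-12
    if degenerate.any():
        vec[degenerate] = [0.0, 0.0, 1.0]
        norm[degenerate] = 1.0
        core.notes.append(
            f"{int(degenerate.sum())} surface bead(s) at the center of mass: "
            "normal set to +Z"
        )
    core.surface_index = surface
    core.normals = vec / norm
    return core


def shape_geometry(shape: ShapeSpec) -> tuple[float, float]:
    """Closed-form (surface area nm^2, volume nm^3) of the analytic shape.

    The rod is a cylinder with hemispherical caps included in its total
    length.  A shell reports the sphere's area and its *enclosed* volume
    (the shell stands in for the surface of a solid particle, whose bulk
    mass is later spread over the shell beads).  The ellipsoid area uses
    the Thomsen approximation (max relative error ~1.1%).
    """
    d = shape.dimensions
    if shape.shape in ("sphere", "shell"):
        R = d[0]
        return 4.0 * math.pi * R**2, 4.0 / 3.0 * math.pi * R**3
    if shape.shape == "octahedron":
        e = d[0]
        return 2.0 * math.sqrt(3.0) * e**2, math.sqrt(2.0) / 3.0 * e**3
    if shape.shape == "cylinder":
        rho, L = d
        return 2.0 * math.pi * rho * (rho + L), math.pi * rho**2 * L
    if shape.shape == "rod":
        rho, L = d
        body = L - 2.0 * rho
        area = 2.0 * math.pi * rho * body + 4.0 * math.pi * rho**2
        vol = math.pi * rho**2 * body + 4.0 / 3.0 * math.pi * rho**3
        return area, vol
    if shape.shape == "pyramid":
        b, h = d
        slant = math.sqrt(h**2 + (b / 2.0) ** 2)
        return b**2 + 2.0 * b * slant, b**2 * h / 3.0
    if shape.shape == "ellipsoid":
        a, b, c = d
        p = 1.6075
        area = 4.0 * math.pi * (
            ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
        ) ** (1.0 / p)
        return area, 4.0 / 3.0 * math.pi * a * b * c
    a, b, c = d
    return 2.0 * (a * b + b * c + a * c), a * b * c
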