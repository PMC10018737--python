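"""Ligand monolayers: anchor selection, morphology patterns, and grafting.

Anchors are chosen in three steps.  First the number of ligands follows
from the user's grafting density (nm^2 per ligand) and the core's analytic
surface area.  Second, that many virtual sites are spread over the unit
sphere by maximizing the sum of pairwise distances with a Metropolis–
Hastings walk constrained to the sphere.  Third, each site claims the
surface bead at the smallest angular distance; duplicate claims fall back
to the nearest still-available bead, so anchors are always unique.

Ligands are built bead-by-bead at their equilibrium bond lengths and
bending angles in an elongated (all-trans) conformation, then rigidly
roto-translated onto each anchor so the molecular long axis (PC1) lies
along the local surface normal.  A final sweep of 20 evenly spaced
rotations about PC1 keeps the orientation that maximizes the minimum
distance to the rest of the system, relieving steric clashes so the
monolayer stays as voluminous and unhindered as possible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .core_builder import CoreModel, identify_surface
from .parameters import BondedParameterSet

__all__ = [
    "AnchorSet",
    "MorphologySpec",
    "LigandBead",
    "LigandTemplate",
    "BuiltLigand",
    "GraftedLigand",
    "NanoparticleModel",
    "DEFAULT_SPACING",
    "ligand_count",
    "optimize_virtual_sites",
    "map_anchors",
    "label_morphology",
    "build_ligand",
    "graft_ligands",
]

#: fallback bead spacing (nm) when no bond parameter is available — a
#: typical coarse-grained bond length (Martini standard bond is 0.47 nm,
#: thiolate anchoring bonds are shorter)
DEFAULT_SPACING = 0.35

MORPHOLOGIES = (
    "homogeneous",
    "random",
    "janus_x",
    "janus_y",
    "janus_z",
    "stripe_x",
    "stripe_y",
    "stripe_z",
)

_AXIS = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class MorphologySpec:
    """Monolayer pattern: which ligand goes on which anchor.

    ``ratio`` is the mixing fraction f_m — the fraction of anchors carrying
    ligand 1 (random and Janus patterns).  ``n_stripes`` sets the number of
    alternating slabs for striped patterns; ``seed`` makes the random
    pattern reproducible.
    """

    kind: str
    ratio: float = 1.0
    n_stripes: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in MORPHOLOGIES:
            raise ValueError(
                f"unknown morphology {self.kind!r}; choose from {MORPHOLOGIES}"
            )
        if not 0.0 <= self.ratio <= 1.0:
            raise ValueError("ratio must lie in [0, 1]")
        if self.kind.startswith("stripe"):
            if self.n_stripes is None or self.n_stripes < 2:
                raise ValueError("striped morphologies need n_stripes >= 2")


@dataclass
class AnchorSet:
    """Surface beads selected to carry ligands, with normals and labels."""

    anchor_indices: np.ndarray        # indices into the core's bead array
    normals: np.ndarray               # outward unit normals, one per anchor
    positions: np.ndarray             # anchor bead coordinates (nm)
    labels: np.ndarray = None         # ligand id per anchor (1-based)

    def __post_init__(self) -> None:
        if self.labels is None:
            self.labels = np.ones(len(self.anchor_indices), dtype=int)

    @property
    def n_lig(self) -> int:
        return len(self.anchor_indices)


@dataclass(frozen=True)
class LigandBead:
    name: str
    type: str
    mass: float      # amu
    charge: float    # e


@dataclass(frozen=True)
class LigandTemplate:
    """Bead identities plus connectivity; bead 0 is the attachment point."""

    name: str
    beads: tuple[LigandBead, ...]
    bonds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.beads)
        if n < 1:
            raise ValueError("a ligand needs at least one bead")
        if n > 1 and not self.bonds:
            raise ValueError("multi-bead ligands need a bond graph")
        adj = self.adjacency()
        seen, stack = {0}, [0]
        while stack:
            for j in adj[stack.pop()]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        if len(seen) != n:
            raise ValueError("ligand bond graph must be connected")

    def adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {i: [] for i in range(len(self.beads))}
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return {i: sorted(v) for i, v in adj.items()}

    @property
    def n_beads(self) -> int:
        return len(self.beads)


@dataclass
class BuiltLigand:
    """A ligand template with elongated equilibrium coordinates."""

    template: LigandTemplate
    coordinates: np.ndarray
    notes: list[str] = field(default_factory=list)


@dataclass
class GraftedLigand:
    label: int
    anchor_index: int            # core bead index of the anchor
    coordinates: np.ndarray      # (n_beads, 3), ordered as the template
    template: LigandTemplate


@dataclass
class NanoparticleModel:
    """Assembled core + monolayer; bead order is core first, then ligands
    grouped per ligand in anchor order."""

    core: CoreModel
    anchors: AnchorSet
    ligands: list[GraftedLigand]
    notes: list[str] = field(default_factory=list)

    @property
    def n_beads(self) -> int:
        return self.core.n_beads + sum(l.template.n_beads for l in self.ligands)

    def positions(self) -> np.ndarray:
        parts = [self.core.positions] + [l.coordinates for l in self.ligands]
        return np.concatenate(parts, axis=0)

    def ligand_bead_ranges(self) -> list[tuple[int, int]]:
        """Half-open global index ranges, one per grafted ligand."""
        ranges, start = [], self.core.n_beads
        for lig in self.ligands:
            ranges.append((start, start + lig.template.n_beads))
            start += lig.template.n_beads
        return ranges

    def monolayer_indices(self) -> np.ndarray:
        return np.arange(self.core.n_beads, self.n_beads)


def ligand_count(area: float, grafting_density: float,
                 n_surface: int | None = None) -> int:
    """Number of ligands from the surface area and grafting density.

    ``grafting_density`` is the ligand footprint in nm^2 per ligand, so
    N_lig = round(area / density), at least 1.
    """
    if area <= 0 or grafting_density <= 0:
        raise ValueError("area and grafting density must both be positive")
    n = max(1, round(area / grafting_density))
    if n_surface is not None and n > n_surface:
        raise ValueError(
            f"requested {n} ligands but the core exposes only {n_surface} "
            "surface beads; lower the grafting density or enlarge the core"
        )
    return n


def _sum_pairwise(points: np.ndarray) -> float:
    diff = points[:, None, :] - points[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).sum() / 2.0)


def optimize_virtual_sites(
    n: int,
    seed: int = 0,
    budget: int | None = None,
    sigma: float = 0.1,
    t0: float = 0.1,
    return_history: bool = False,
):
    """Spread ``n`` virtual sites over the unit sphere.

    Sites start uniformly at random (seeded) and a Metropolis–Hastings walk
    maximizes the objective D_u — the sum of pairwise (chord) distances —
    under the constraint that every site stays on the sphere: each proposal
    perturbs one site in its tangent plane (Gaussian, ``sigma`` radians) and
    renormalizes, so the constraint holds after every move.  The effective
    temperature anneals linearly from ``t0`` to zero over the budget
    (default ``2000 * n`` proposals) and the best configuration seen is
    returned, so the final D_u never falls below the initial one.
    """
    if n < 1:
        raise ValueError("need at least one virtual site")
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    if n == 1:
        return (x, [0.0]) if return_history else x

    if budget is None:
        budget = 2000 * n
    dist = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    d_u = dist.sum() / 2.0
    best = d_u
    best_x = x.copy()
    history = [d_u]

    for step in range(budget):
        i = int(rng.integers(n))
        trial = x[i] + sigma * rng.normal(size=3)
        trial /= np.linalg.norm(trial)
        new_row = np.linalg.norm(x - trial, axis=1)
        new_row[i] = 0.0
        delta = new_row.sum() - dist[i].sum()
        temp = t0 * (1.0 - (step + 1) / budget)
        if delta >= 0 or (temp > 0 and rng.random() < math.exp(delta / temp)):
            x[i] = trial
            dist[i] = new_row
            dist[:, i] = new_row
            d_u += delta
            if d_u > best:
                best = d_u
                best_x = x.copy()
        if return_history:
            history.append(d_u)
    return (best_x, history) if return_history else best_x


def map_anchors(sites: np.ndarray, core: CoreModel) -> AnchorSet:
    """Claim, for each virtual site, the surface bead at minimal angular
    distance; duplicate claims fall back to the nearest available bead."""
    if core.surface_index is None:
        identify_surface(core)
    surf = core.surface_index
    if len(sites) > len(surf):
        raise ValueError(
            f"{len(sites)} virtual sites but only {len(surf)} surface beads"
        )
    com = core.positions.mean(axis=0)
    vec = core.positions[surf] - com
    norms = np.linalg.norm(vec, axis=1)
    norms[norms < 1e-12] = 1.0
    units = vec / norms[:, None]

    cos = np.asarray(sites) @ units.T        # (n_sites, n_surface)
    chosen = np.full(len(sites), -1, dtype=int)
    taken = np.zeros(len(surf), dtype=bool)
    first = np.argmax(cos, axis=1)
    for s, b in enumerate(first):            # uncontested claims, site order
        if not taken[b]:
            chosen[s] = b
            taken[b] = True
    for s in np.flatnonzero(chosen < 0):     # exchange for nearest available
        order = np.argsort(-cos[s])
        for b in order:
            if not taken[b]:
                chosen[s] = b
                taken[b] = True
                break

    sel = surf[chosen]
    normal_rows = np.searchsorted(surf, sel)
    return AnchorSet(
        anchor_indices=sel,
        normals=core.normals[normal_rows],
        positions=core.positions[sel],
    )


def label_morphology(anchors: AnchorSet, spec: MorphologySpec) -> AnchorSet:
    """Assign a ligand label (1 or 2) to every anchor following the pattern."""
    n = anchors.n_lig
    labels = np.full(n, 2, dtype=int)
    if spec.kind == "homogeneous":
        labels[:] = 1
    elif spec.kind == "random":
        k = round(spec.ratio * n)
        rng = np.random.default_rng(spec.seed)
        labels[rng.permutation(n)[:k]] = 1
    elif spec.kind.startswith("janus"):
        axis = _AXIS[spec.kind[-1]]
        k = round(spec.ratio * n)
        # dividing plane at the ratio-quantile: the k anchors furthest along
        # the positive axis carry ligand 1
        order = np.argsort(-anchors.positions[:, axis], kind="stable")
        labels[order[:k]] = 1
    else:  # stripes
        axis = _AXIS[spec.kind[-1]]
        coord = anchors.positions[:, axis]
        lo, hi = coord.min(), coord.max()
        width = (hi - lo) / spec.n_stripes or 1.0
        stripe = np.minimum(
            ((coord - lo) / width).astype(int), spec.n_stripes - 1
        )
        labels = 1 + stripe % 2              # stripe 0 (negative end) is ligand 1
    anchors.labels = labels
    return anchors


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          length: float, theta_deg: float, chi_deg: float) -> np.ndarray:
    """Place a fourth point at (length, angle at c, torsion a-b-c-d)."""
    w = c - b
    w /= np.linalg.norm(w)
    n = np.cross(b - a, w)
    nn = np.linalg.norm(n)
    if nn < 1e-12:                      # collinear reference: pick any normal
        n = np.cross(w, [0.0, 0.0, 1.0])
        if np.linalg.norm(n) < 1e-12:
            n = np.cross(w, [0.0, 1.0, 0.0])
        nn = np.linalg.norm(n)
    n /= nn
    u = np.cross(n, w)
    theta = math.radians(theta_deg)
    chi = math.radians(chi_deg)
    d = (-w * math.cos(theta)
         + u * math.sin(theta) * math.cos(chi)
         + n * math.sin(theta) * math.sin(chi))
    return c + length * d


def _subtree_depth(adj: dict[int, list[int]], node: int, parent: int | None) -> int:
    return 1 + max(
        (_subtree_depth(adj, ch, node) for ch in adj[node] if ch != parent),
        default=0,
    )


def build_ligand(
    template: LigandTemplate,
    params: BondedParameterSet | None = None,
    default_spacing: float = DEFAULT_SPACING,
) -> BuiltLigand:
    """Build elongated equilibrium coordinates for a ligand template.

    Beads are appended sequentially from the attachment point outward at
    the equilibrium bond length and bending angle found in ``params``
    (by bead-type lookup), with trans torsions so the chain extends along
    its principal axis.  Without parameters — or for any missing entry,
    which is recorded in the notes — beads fall back to a collinear chain
    at ``default_spacing``.  Branches are descended longest-chain first;
    sibling branches are splayed at 120-degree torsion offsets.
    """
    n = template.n_beads
    coords = np.zeros((n, 3))
    notes: list[str] = []
    if n == 1:
        return BuiltLigand(template, coords, notes)

    adj = template.adjacency()
    types = [b.type for b in template.beads]

    def bond_length(i: int, j: int) -> float:
        if params is not None:
            entry = params.bond(types[i], types[j])
            if entry is not None:
                return entry.length
            notes.append(
                f"missing bond parameters for ({types[i]}, {types[j]}): "
                f"default spacing {default_spacing} nm used"
            )
        return default_spacing

    def bend_angle(i: int, j: int, k: int) -> float:
        if params is not None:
            entry = params.angle(types[i], types[j], types[k])
            if entry is not None:
                return entry.theta
            notes.append(
                f"missing angle parameters for ({types[i]}, {types[j]}, "
                f"{types[k]}): 180 deg used"
            )
        return 180.0

    placed = {0}
    parent = {0: None}
    # depth-first, longest chain first, so PC1 tracks the backbone
    stack = [(0, ch) for ch in sorted(
        adj[0], key=lambda c: -_subtree_depth(adj, c, 0)
    )][::-1]
    sibling_rank: dict[int, int] = {}
    while stack:
        par, node = stack.pop()
        if node in placed:
            continue
        gp = parent[par]
        length = bond_length(par, node)
        rank = sibling_rank.get(par, 0)
        sibling_rank[par] = rank + 1
        if gp is None:
            if rank == 0:
                coords[node] = coords[par] + np.array([length, 0.0, 0.0])
            else:  # extra branches off the attachment bead
                theta = bend_angle(node, par, adj[par][0])
                coords[node] = _nerf(
                    coords[par] + np.array([0.0, 0.0, 1.0]),
                    coords[par] + np.array([1.0, 0.0, 0.0]),
                    coords[par], length, theta, 120.0 * rank,
                )
        else:
            theta = bend_angle(gp, par, node)
            ggp = parent[gp]
            ref = coords[ggp] if ggp is not None else coords[gp] + np.array(
                [0.0, 0.0, 1.0]
            )
            chi = 180.0 + 120.0 * rank      # trans backbone, splayed branches
            coords[node] = _nerf(ref, coords[gp], coords[par], length, theta, chi)
        placed.add(node)
        parent[node] = par
        for ch in sorted(adj[node], key=lambda c: -_subtree_depth(adj, c, node)):
            if ch not in placed:
                stack.append((node, ch))
    return BuiltLigand(template, coords, notes)


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    """PC1 oriented from the attachment bead toward the far end."""
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    pc1 = vt[0]
    tip = coords[np.argmax(np.linalg.norm(coords - coords[0], axis=1))]
    if np.dot(pc1, tip - coords[0]) < 0:
        pc1 = -pc1
    return pc1


def graft_ligands(
    core: CoreModel,
    anchors: AnchorSet,
    ligands: dict[int, BuiltLigand],
    params: BondedParameterSet | None = None,
    core_type: str = "C1",
    anchor_bond_length: float | None = None,
    n_rotations: int = 20,
) -> NanoparticleModel:
    """Rigidly place one ligand copy on every anchor.

    Each copy is rotated (quaternion) so its PC1 aligns with the anchor's
    outward normal and translated so the attachment bead sits one
    anchor-bond length beyond the anchor bead.  Twenty evenly spaced
    rotations about PC1 are then scored and the one maximizing the minimum
    distance to the rest of the system is kept.
    """
    notes: list[str] = []
    missing = {lab for lab in np.unique(anchors.labels) if lab not in ligands}
    if missing:
        raise ValueError(f"no built ligand supplied for label(s) {sorted(missing)}")

    def attach_length(built: BuiltLigand) -> float:
        if anchor_bond_length is not None:
            return anchor_bond_length
        if params is not None:
            entry = params.bond(core_type, built.template.beads[0].type)
            if entry is not None:
                return entry.length
        notes.append(
            f"no anchor bond parameter ({core_type}, "
            f"{built.template.beads[0].type}): default "
            f"{DEFAULT_SPACING} nm offset used"
        )
        return DEFAULT_SPACING

    core_tree = cKDTree(core.positions)
    placed: list[GraftedLigand] = []
    placed_pts: list[np.ndarray] = []
    d0 = {lab: attach_length(built) for lab, built in sorted(ligands.items())}

    for a in range(anchors.n_lig):
        label = int(anchors.labels[a])
        built = ligands[label]
        coords = built.coordinates - built.coordinates[0]
        normal = anchors.normals[a]
        if np.linalg.norm(normal) < 1e-12:
            raise ValueError(f"anchor {a} has a zero-length normal")
        base = anchors.positions[a] + d0[label] * normal

        if built.template.n_beads > 1:
            pc1 = _principal_axis(built.coordinates)
            rot, _ = Rotation.align_vectors([normal], [pc1])
            coords = rot.apply(coords)
        candidate_best = None
        best_score = -np.inf
        if built.template.n_beads == 1:
            candidate_best = coords + base
        else:
            others = np.concatenate(placed_pts) if placed_pts else None
            for k in range(n_rotations):
                spin = Rotation.from_rotvec(normal * (2.0 * math.pi * k / n_rotations))
                cand = spin.apply(coords) + base
                dmin = core_tree.query(cand)[0].min()
                if others is not None:
                    diff = cand[:, None, :] - others[None, :, :]
                    dmin = min(dmin, float(np.sqrt((diff**2).sum(-1)).min()))
                if dmin > best_score:
                    best_score = dmin
                    candidate_best = cand
        placed.append(
            GraftedLigand(
                label=label,
                anchor_index=int(anchors.anchor_indices[a]),
                coordinates=candidate_best,
                template=built.template,
            )
        )
        placed_pts.append(candidate_best)

    seen = set()
    for built in ligands.values():
        for note in built.notes:
            if note not in seen:
                seen.add(note)
                notes.append(note)
    return NanoparticleModel(core=core, anchors=anchors, ligands=placed, notes=notes)
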