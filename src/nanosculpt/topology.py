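"""Masses, elastic networks, bonded-term assignment, and file serialization.

The core is kept rigid by an elastic network of stiff harmonic bonds
between touching neighbors (coordination 6/8/12/12 for primitive/BCC/FCC/
HCP interiors; shells bond each bead to its six nearest neighbors plus the
antipodal bead).  Core beads are neutral and share the particle's bulk
mass equally, so the coarse model weighs the same as the atomically
detailed particle it replaces.  Ligand bonded parameters are assigned
"center out" — from the anchor bead to the ligand tip — by bead-type
lookup in a user-supplied parameter set; anything missing is skipped and
itemized in the job report rather than guessed.

Structure files (.gro in nm, .pdb in Angstrom) are written through
MDAnalysis.  The system topology (.top) references the nonbonded
interaction matrix through a single #include line, so swapping force
fields is a one-line edit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .core_builder import CoreModel, NEIGHBOR_TOL, shape_geometry
from .monolayer import NanoparticleModel
from .parameters import (  # noqa: F401  (re-exported module surface)
    BondedParameterSet,
    BondEntry,
    AngleEntry,
    DihedralEntry,
    parse_itp,
)

__all__ = [
    "AtomRecord",
    "BondTerm",
    "AngleTerm",
    "DihedralTerm",
    "TopologyDocument",
    "parse_itp",
    "BondedParameterSet",
    "AMU_PER_GCM3_NM3",
    "DEFAULT_K_ELASTIC",
    "assign_core_masses",
    "build_elastic_network",
    "assign_ligand_topology",
    "write_structure",
    "write_topology",
    "write_interaction_matrix_stub",
]

#: mass (amu) of 1 nm^3 of material at a bulk density of 1 g/cm^3
AMU_PER_GCM3_NM3 = 1.0e-21 / 1.66053906892e-24

#: default elastic-network force constant (kJ mol^-1 nm^-2)
DEFAULT_K_ELASTIC = 32_500.0


@dataclass
class AtomRecord:
    name: str
    type: str
    mass: float
    charge: float
    resname: str
    resid: int


@dataclass(frozen=True)
class BondTerm:
    i: int
    j: int
    length: float
    k: float
    func: int = 1


@dataclass(frozen=True)
class AngleTerm:
    i: int
    j: int
    k_idx: int
    theta: float
    k: float
    func: int = 2


@dataclass(frozen=True)
class DihedralTerm:
    i: int
    j: int
    k_idx: int
    l: int
    phi: float
    k: float
    multiplicity: int
    func: int = 1


@dataclass
class TopologyDocument:
    """Complete bonded/nonbonded description of one nanoparticle molecule."""

    name: str
    atoms: list[AtomRecord]
    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    dihedrals: list[DihedralTerm] = field(default_factory=list)
    elastic_bonds: list[BondTerm] = field(default_factory=list)
    include_file: str = "interaction_matrix.itp"
    nrexcl: int = 1
    report: dict = field(default_factory=dict)

    def validate(self) -> None:
        n = len(self.atoms)
        for term in self.bonds + self.elastic_bonds:
            assert 0 <= term.i < n and 0 <= term.j < n
        for term in self.angles:
            assert all(0 <= x < n for x in (term.i, term.j, term.k_idx))
        for term in self.dihedrals:
            assert all(0 <= x < n for x in (term.i, term.j, term.k_idx, term.l))

    def report_text(self) -> str:
        lines = [f"Job report for molecule {self.name}", "=" * 40]
        for key in ("enumerated", "assigned"):
            counts = self.report.get(key, {})
            lines.append(f"{key}: " + ", ".join(
                f"{kind}={counts.get(kind, 0)}" for kind in ("bonds", "angles", "dihedrals")
            ))
        skipped = self.report.get("skipped", [])
        lines.append(f"skipped terms: {len(skipped)}")
        lines.extend(f"  - {s}" for s in skipped)
        for note in self.report.get("notes", []):
            lines.append(f"note: {note}")
        return "\n".join(lines) + "\n"


def assign_core_masses(core: CoreModel, bulk_density: float) -> np.ndarray:
    """Distribute the bulk mass of the core equally over its beads.

    ``bulk_density`` is in g/cm^3 (19.3 for gold).  The total mass is the
    density times the analytic shape volume, converted to amu, so the
    coarse-grained core weighs the same as the real particle regardless of
    how many beads represent it.
    """
    if bulk_density <= 0:
        raise ValueError("bulk density must be positive")
    if core.n_beads == 0:
        raise ValueError("core has no beads")
    _, volume = shape_geometry(core.shape)
    total = bulk_density * volume * AMU_PER_GCM3_NM3
    core.masses = np.full(core.n_beads, total / core.n_beads)
    return core.masses


def build_elastic_network(core: CoreModel, k_b: float = DEFAULT_K_ELASTIC) -> list[BondTerm]:
    """Harmonic bonds keeping the core rigid.

    Lattice cores bond every pair of touching neighbors (separation
    2r +/- tolerance) at its current distance.  Shells bond each bead to
    its six nearest neighbors and to the bead closest to its exact
    antipode (quasi-uniform shells have no exact antipodal site).  Bonds
    are deduplicated as unordered pairs.
    """
    if k_b <= 0:
        raise ValueError("elastic constant k_b must be positive")
    pos = core.positions
    pairs: set[tuple[int, int]] = set()
    if core.is_shell:
        tree = cKDTree(pos)
        n_query = min(7, len(pos))
        _, idx = tree.query(pos, k=n_query)
        for i in range(len(pos)):
            for j in idx[i][1:]:
                pairs.add((min(i, int(j)), max(i, int(j))))
        _, anti = tree.query(-pos, k=1)
        for i, j in enumerate(anti):
            if int(j) != i:
                pairs.add((min(i, int(j)), max(i, int(j))))
    else:
        r = core.bead_radius
        tree = cKDTree(pos)
        pairs = {(int(i), int(j)) for i, j in tree.query_pairs(2.0 * r + NEIGHBOR_TOL * r)}
    bonds = []
    for i, j in sorted(pairs):
        length = float(np.linalg.norm(pos[i] - pos[j]))
        bonds.append(BondTerm(i=i, j=j, length=length, k=k_b))
    return bonds


def _ligand_tuples(adj: dict[int, list[int]]):
    """Enumerate bonded pairs, triplets, and quadruplets of a bond graph.

    Triplets are paths i-j-k centered on j; quadruplets are paths around
    each central edge j-k.  Each tuple appears once, in canonical
    orientation.
    """
    nodes = sorted(adj)
    bonds = sorted({(min(i, j), max(i, j)) for i in nodes for j in adj[i]})
    angles = []
    for j in nodes:
        nb = adj[j]
        for x in range(len(nb)):
            for y in range(x + 1, len(nb)):
                angles.append((nb[x], j, nb[y]))
    dihedrals = set()
    for j, k in bonds:
        for i in adj[j]:
            if i == k:
                continue
            for l in adj[k]:
                if l == j or l == i:
                    continue
                quad = (i, j, k, l)
                dihedrals.add(min(quad, quad[::-1]))
    return bonds, angles, sorted(dihedrals)


def assign_ligand_topology(
    model: NanoparticleModel,
    params: BondedParameterSet,
    core_type: str = "C1",
    k_elastic: float = DEFAULT_K_ELASTIC,
    molecule_name: str = "NP",
    include_file: str = "interaction_matrix.itp",
) -> TopologyDocument:
    """Assemble the full topology document for a grafted nanoparticle.

    Core beads come first (neutral, equal masses — call
    :func:`assign_core_masses` beforehand), then each ligand copy in
    anchor order.  Bonded tuples are enumerated center-out from the
    anchor bead to the ligand tip and parametrized by bead-type lookup;
    every missing entry is skipped and itemized in the report.
    """
    core = model.core
    if core.masses is None:
        raise ValueError("core masses not assigned; call assign_core_masses first")

    atoms = [
        AtomRecord(name=core_type, type=core_type, mass=float(m), charge=0.0,
                   resname="CORE", resid=1)
        for m in core.masses
    ]
    bonds: list[BondTerm] = []
    angles: list[AngleTerm] = []
    dihedrals: list[DihedralTerm] = []
    skipped: list[str] = []
    enumerated = {"bonds": 0, "angles": 0, "dihedrals": 0}
    assigned = {"bonds": 0, "angles": 0, "dihedrals": 0}

    offset = core.n_beads
    for lig_no, lig in enumerate(model.ligands):
        tpl = lig.template
        for bead in tpl.beads:
            atoms.append(
                AtomRecord(name=bead.name, type=bead.type, mass=bead.mass,
                           charge=bead.charge, resname=f"L{lig.label}",
                           resid=2 + lig_no)
            )
        # graph over local ids; -1 is the anchor bead of the core
        adj = {i: list(nb) for i, nb in tpl.adjacency().items()}
        adj[-1] = [0]
        adj[0] = [-1] + adj[0]
        glob = {i: offset + i for i in range(tpl.n_beads)}
        glob[-1] = lig.anchor_index
        types = {i: b.type for i, b in enumerate(tpl.beads)}
        types[-1] = core_type

        b_tuples, a_tuples, d_tuples = _ligand_tuples(adj)
        enumerated["bonds"] += len(b_tuples)
        enumerated["angles"] += len(a_tuples)
        enumerated["dihedrals"] += len(d_tuples)

        for i, j in b_tuples:
            entry = params.bond(types[i], types[j])
            if entry is None:
                skipped.append(f"bond ({types[i]}, {types[j]}) "
                               f"ligand {lig_no + 1}")
                continue
            assigned["bonds"] += 1
            bonds.append(BondTerm(glob[i], glob[j], entry.length, entry.k, entry.func))
        for i, j, k in a_tuples:
            entry = params.angle(types[i], types[j], types[k])
            if entry is None:
                skipped.append(f"angle ({types[i]}, {types[j]}, {types[k]}) "
                               f"ligand {lig_no + 1}")
                continue
            assigned["angles"] += 1
            angles.append(AngleTerm(glob[i], glob[j], glob[k],
                                    entry.theta, entry.k, entry.func))
        for i, j, k, l in d_tuples:
            entries = params.dihedral(types[i], types[j], types[k], types[l])
            if not entries:
                skipped.append(
                    f"dihedral ({types[i]}, {types[j]}, {types[k]}, {types[l]}) "
                    f"ligand {lig_no + 1}"
                )
                continue
            assigned["dihedrals"] += 1
            for entry in entries:  # stacked periodic functions all emitted
                dihedrals.append(
                    DihedralTerm(glob[i], glob[j], glob[k], glob[l],
                                 entry.phi, entry.k, entry.multiplicity, entry.func)
                )
        offset += tpl.n_beads

    doc = TopologyDocument(
        name=molecule_name,
        atoms=atoms,
        bonds=bonds,
        angles=angles,
        dihedrals=dihedrals,
        elastic_bonds=build_elastic_network(core, k_elastic),
        include_file=include_file,
        report={
            "enumerated": enumerated,
            "assigned": assigned,
            "skipped": skipped,
            "notes": list(model.notes) + list(core.notes),
        },
    )
    doc.validate()
    return doc


# ---------------------------------------------------------------------------
# serialization

def _as_universe(model: NanoparticleModel | CoreModel, doc: TopologyDocument | None):
    import MDAnalysis as mda

    if isinstance(model, CoreModel):
        positions = model.positions
        names = ["C1"] * model.n_beads
        resnames = ["CORE"]
        resids = np.zeros(model.n_beads, dtype=int)
    else:
        positions = model.positions()
        if doc is not None:
            names = [a.name for a in doc.atoms]
            res_keys = [(a.resid, a.resname) for a in doc.atoms]
        else:
            names = ["C1"] * model.core.n_beads
            res_keys = [(1, "CORE")] * model.core.n_beads
            for lig_no, lig in enumerate(model.ligands):
                names.extend(b.name for b in lig.template.beads)
                res_keys.extend([(2 + lig_no, f"L{lig.label}")] * lig.template.n_beads)
        uniq: list[tuple[int, str]] = []
        resids = np.empty(len(names), dtype=int)
        for at, key in enumerate(res_keys):
            if not uniq or uniq[-1] != key:
                uniq.append(key)
            resids[at] = len(uniq) - 1
        resnames = [key[1] for key in uniq]

    u = mda.Universe.empty(
        n_atoms=len(positions),
        n_residues=len(resnames),
        atom_resindex=resids,
        residue_segindex=np.zeros(len(resnames), dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", np.arange(1, len(resnames) + 1))
    u.atoms.positions = np.asarray(positions) * 10.0  # nm -> Angstrom
    span = positions.max(axis=0) - positions.min(axis=0)
    u.dimensions = [*(span * 10.0 + 40.0), 90.0, 90.0, 90.0]  # 2 nm padding
    return u


def write_structure(
    model: NanoparticleModel | CoreModel,
    path: str | Path,
    doc: TopologyDocument | None = None,
) -> Path:
    """Write coordinates as .gro (nm) or .pdb (Angstrom), by extension.

    Bead order matches the topology: core beads first, then ligands in
    anchor order.  PDB serial numbers beyond 99,999 wrap per convention
    (a warning is recorded in the document report when one is supplied).
    """
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("gro", "pdb"):
        raise ValueError(f"unsupported structure format {fmt!r} (use .gro or .pdb)")
    u = _as_universe(model, doc)
    if fmt == "pdb" and len(u.atoms) > 99_999 and doc is not None:
        doc.report.setdefault("notes", []).append(
            "PDB atom serials exceed 99999 and wrap per convention"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MDAnalysis warns about absent attrs
        u.atoms.write(str(path))
    return path


def _fmt_bond(term: BondTerm) -> str:
    return (f"{term.i + 1:6d} {term.j + 1:6d} {term.func:4d} "
            f"{term.length:10.5f} {term.k:12.2f}")


def write_topology(
    doc: TopologyDocument,
    top_path: str | Path,
    itp_path: str | Path | None = None,
) -> tuple[Path, Path]:
    """Serialize the molecule .itp and the system .top.

    The .top holds exactly one #include line for the nonbonded interaction
    matrix; pointing it at a different file swaps the force field without
    touching any other byte of the topology.
    """
    top_path = Path(top_path)
    if itp_path is None:
        itp_path = top_path.with_suffix(".itp")
    itp_path = Path(itp_path)

    lines = ["[ moleculetype ]", "; name    nrexcl", f"{doc.name}    {doc.nrexcl}", ""]
    lines.append("[ atoms ]")
    lines.append(";  nr  type  resnr  residue  atom  cgnr    charge       mass")
    for idx, a in enumerate(doc.atoms, start=1):
        lines.append(
            f"{idx:6d} {a.type:>5s} {a.resid:6d} {a.resname:>6s} "
            f"{a.name:>5s} {idx:6d} {a.charge:9.4f} {a.mass:12.4f}"
        )
    lines.append("")
    if doc.bonds or doc.elastic_bonds:
        lines.append("[ bonds ]")
        lines.append(";   i      j  func       l0          k")
        for term in doc.bonds:
            lines.append(_fmt_bond(term))
        if doc.elastic_bonds:
            lines.append("; elastic network")
            for term in doc.elastic_bonds:
                lines.append(_fmt_bond(term))
        lines.append("")
    if doc.angles:
        lines.append("[ angles ]")
        lines.append(";   i      j      k  func    theta0          k")
        for t in doc.angles:
            lines.append(
                f"{t.i + 1:6d} {t.j + 1:6d} {t.k_idx + 1:6d} {t.func:4d} "
                f"{t.theta:10.3f} {t.k:12.3f}"
            )
        lines.append("")
    if doc.dihedrals:
        lines.append("[ dihedrals ]")
        lines.append(";   i      j      k      l  func      phi0         k  mult")
        for t in doc.dihedrals:
            lines.append(
                f"{t.i + 1:6d} {t.j + 1:6d} {t.k_idx + 1:6d} {t.l + 1:6d} "
                f"{t.func:4d} {t.phi:10.3f} {t.k:10.4f} {t.multiplicity:4d}"
            )
        lines.append("")
    itp_path.write_text("\n".join(lines))

    top_lines = [
        f'#include "{doc.include_file}"',
        f'#include "{itp_path.name}"',
        "",
        "[ system ]",
        "Coarse-grained monolayer-protected nanoparticle",
        "",
        "[ molecules ]",
        f"{doc.name}    1",
        "",
    ]
    top_path.write_text("\n".join(top_lines))
    return top_path, itp_path


def write_interaction_matrix_stub(path: str | Path, types: list[str]) -> Path:
    """Write a minimal, syntactically valid interaction-matrix include file.

    This is a synthetic placeholder (zero Lennard-Jones parameters) so the
    emitted .top is self-contained; for production runs, point the single
    #include line of the .top at a real force-field matrix instead.
    """
    path = Path(path)
    lines = [
        "; synthetic placeholder interaction matrix — replace with a real",
        "; force-field file by editing the #include line of the .top",
        "[ defaults ]",
        "; nbfunc  comb-rule  gen-pairs  fudgeLJ  fudgeQQ",
        "  1       2          no         1.0      1.0",
        "",
        "[ atomtypes ]",
        "; name  mass    charge  ptype  sigma  epsilon",
    ]
    for t in dict.fromkeys(types):
        lines.append(f"  {t:<6s} 72.0    0.000   A      0.0    0.0")
    lines.append("")
    path.write_text("\n".join(lines))
    return path
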