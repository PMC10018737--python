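"""Deterministic toy inputs for exercising the builder without downloads.

The ligand fixtures mirror the coarse-grained alkylthiol chains used to
validate the method: a 4-to-1 heavy-atom mapping turns a 13-carbon thiol
into a three-bead chain of apolar beads (the sulfur is absorbed into the
core's anchor bead), and one-, two-, three-, and five-bead homologues
cover the chain-length series.  The jittered coordinate series stands in
for MD output frames: seeded isotropic Gaussian noise on the ligand beads
with the core held fixed, as the elastic network would hold it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .analysis import CoordinateFrameSeries, series_from_model
from .monolayer import LigandBead, LigandTemplate, NanoparticleModel

__all__ = [
    "FixtureSpec",
    "LigandFixture",
    "make_ligand_fixture",
    "alkyl_ligand_fixture",
    "make_jittered_series",
]

#: Martini-style defaults: C1 apolar bead of 72 amu (4 heavy atoms),
#: 0.47 nm bonds, straight 180-degree equilibrium angles
_DEFAULTS = dict(bead_type="C1", mass=72.0, charge=0.0,
                 l0=0.47, k_bond=1250.0, theta0=180.0, k_angle=25.0)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a linear test ligand and its parameter file."""

    n_beads: int
    bead_types: tuple[str, ...] | None = None
    masses: tuple[float, ...] | None = None
    charges: tuple[float, ...] | None = None
    l0: float = _DEFAULTS["l0"]
    k_bond: float = _DEFAULTS["k_bond"]
    theta0: float = _DEFAULTS["theta0"]
    k_angle: float = _DEFAULTS["k_angle"]
    dihedral: tuple[float, float, int] | None = None  # (phi0, k, multiplicity)
    anchor_type: str = "C1"
    anchor_l0: float | None = None
    name: str = "LIG"

    def __post_init__(self) -> None:
        if self.n_beads < 1:
            raise ValueError("a ligand fixture needs at least one bead")
        for attr in ("bead_types", "masses", "charges"):
            val = getattr(self, attr)
            if val is not None and len(val) != self.n_beads:
                raise ValueError(f"{attr} must have {self.n_beads} entries")


@dataclass
class LigandFixture:
    spec: FixtureSpec
    template: LigandTemplate
    itp_text: str

    def write_itp(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.itp_text)
        return path


def make_ligand_fixture(spec: FixtureSpec) -> LigandFixture:
    """Linear N-bead ligand template plus a matching .itp parameter file.

    The emitted file uses type-keyed [ bonds ]/[ angles ]/[ dihedrals ]
    sections and round-trips exactly through ``parse_itp``.  Single-bead
    ligands emit no bonded sections at all.
    """
    n = spec.n_beads
    types = spec.bead_types or tuple([_DEFAULTS["bead_type"]] * n)
    masses = spec.masses or tuple([_DEFAULTS["mass"]] * n)
    charges = spec.charges or tuple([0.0] * n)
    beads = tuple(
        LigandBead(name=f"{types[i][:2]}{i + 1}", type=types[i],
                   mass=masses[i], charge=charges[i])
        for i in range(n)
    )
    bonds = tuple((i, i + 1) for i in range(n - 1))
    template = LigandTemplate(name=spec.name, beads=beads, bonds=bonds)

    lines = [f"; toy ligand parameters: {spec.name}, {n} bead(s)"]
    pair_types = {tuple(sorted((types[i], types[j]))) for i, j in bonds}
    anchor_l0 = spec.anchor_l0 if spec.anchor_l0 is not None else spec.l0
    anchor_pair = tuple(sorted((spec.anchor_type, types[0])))
    if bonds or n >= 1:
        lines += ["[ bonds ]", "; type_i type_j  func   l0      k"]
        lines.append(
            f"  {anchor_pair[0]} {anchor_pair[1]}  1  {anchor_l0:.4f}  {spec.k_bond:.1f}"
        )
        for a, b in sorted(pair_types - {anchor_pair}):
            lines.append(f"  {a} {b}  1  {spec.l0:.4f}  {spec.k_bond:.1f}")
        lines.append("")
    if n >= 2:
        triplets = {(types[i], types[i + 1], types[i + 2]) for i in range(n - 2)}
        triplets.add((spec.anchor_type, types[0], types[1]) if n >= 2 else None)
        triplets.discard(None)
        canon = {min(t, t[::-1]) for t in triplets}
        lines += ["[ angles ]", "; type_i type_j type_k  func  theta0   k"]
        for t in sorted(canon):
            lines.append(
                f"  {t[0]} {t[1]} {t[2]}  2  {spec.theta0:.2f}  {spec.k_angle:.2f}"
            )
        lines.append("")
    if spec.dihedral is not None and n >= 3:
        phi0, k_d, mult = spec.dihedral
        quads = {
            (types[i], types[i + 1], types[i + 2], types[i + 3])
            for i in range(n - 3)
        }
        quads.add((spec.anchor_type, types[0], types[1], types[2]))
        canon_q = {min(q, q[::-1]) for q in quads}
        lines += ["[ dihedrals ]", "; types  func  phi0  k  mult"]
        for q in sorted(canon_q):
            lines.append(
                f"  {q[0]} {q[1]} {q[2]} {q[3]}  1  {phi0:.2f}  {k_d:.4f}  {mult}"
            )
        lines.append("")
    return LigandFixture(spec=spec, template=template, itp_text="\n".join(lines))


def alkyl_ligand_fixture(n_beads: int) -> LigandFixture:
    """Coarse-grained alkyl chain presets (1, 2, 3, or 5 beads).

    The 3-bead preset is the 13-carbon alkylthiol under a 4-to-1 mapping
    with the sulfur absorbed into the core anchor bead.
    """
    if n_beads not in (1, 2, 3, 5):
        raise ValueError("alkyl presets cover 1, 2, 3, and 5 beads")
    return make_ligand_fixture(FixtureSpec(n_beads=n_beads, name=f"ALK{n_beads}"))


def make_jittered_series(
    model: NanoparticleModel,
    amplitude: float,
    n_frames: int,
    seed: int = 0,
) -> CoordinateFrameSeries:
    """Perturbed coordinate frames standing in for MD trajectory output.

    Adds seeded isotropic Gaussian noise of the given amplitude (nm) to
    the ligand beads of every frame while keeping the core fixed; zero
    amplitude reproduces the built model in every frame.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    base = series_from_model(model)
    rng = np.random.default_rng(seed)
    frames = np.repeat(base.positions, n_frames, axis=0)
    mono = base.monolayer_indices()
    if amplitude > 0 and mono.size:
        frames[:, mono, :] += rng.normal(
            scale=amplitude, size=(n_frames, mono.size, 3)
        )
    return CoordinateFrameSeries(
        positions=frames,
        masses=base.masses,
        core_indices=base.core_indices,
        ligand_ranges=base.ligand_ranges,
        anchor_indices=base.anchor_indices,
        terminal_indices=base.terminal_indices,
    )
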