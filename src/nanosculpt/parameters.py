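"""Bonded parameter tables keyed by bead-type tuples.

Coarse-grained bonded parameters cannot be derived from bead types alone,
so they are supplied by the user in a Gromacs-dialect include-topology
(.itp) file.  Entries are keyed by type tuples and are symmetric under
sequence reversal (pair AB == BA, triplet ABC == CBA, quadruplet
ABCD == DCBA).  A quadruplet may carry several dihedral entries — some
force fields stack multiple periodic functions on one torsion — and all
of them are preserved and later emitted per matching quadruplet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

__all__ = ["BondEntry", "AngleEntry", "DihedralEntry", "BondedParameterSet", "parse_itp"]


@dataclass(frozen=True)
class BondEntry:
    length: float          # equilibrium length l0 (nm)
    k: float               # spring constant (kJ mol^-1 nm^-2)
    func: int = 1


@dataclass(frozen=True)
class AngleEntry:
    theta: float           # equilibrium angle theta0 (degrees)
    k: float               # spring constant (kJ mol^-1 rad^-2)
    func: int = 2


@dataclass(frozen=True)
class DihedralEntry:
    phi: float             # equilibrium angle (degrees)
    k: float               # amplitude (kJ mol^-1)
    multiplicity: int = 1
    func: int = 1


@dataclass
class BondedParameterSet:
    """Symmetric lookup tables for bond/angle/dihedral parameters."""

    bonds: dict[tuple[str, str], BondEntry] = field(default_factory=dict)
    angles: dict[tuple[str, str, str], AngleEntry] = field(default_factory=dict)
    dihedrals: dict[tuple[str, str, str, str], list[DihedralEntry]] = field(
        default_factory=dict
    )

    @staticmethod
    def _canonical(key: tuple[str, ...]) -> tuple[str, ...]:
        rev = key[::-1]
        return key if key <= rev else rev

    def add_bond(self, a: str, b: str, entry: BondEntry) -> None:
        self.bonds[self._canonical((a, b))] = entry

    def add_angle(self, a: str, b: str, c: str, entry: AngleEntry) -> None:
        self.angles[self._canonical((a, b, c))] = entry

    def add_dihedral(self, a: str, b: str, c: str, d: str, entry: DihedralEntry) -> None:
        self.dihedrals.setdefault(self._canonical((a, b, c, d)), []).append(entry)

    def bond(self, a: str, b: str) -> BondEntry | None:
        return self.bonds.get(self._canonical((a, b)))

    def angle(self, a: str, b: str, c: str) -> AngleEntry | None:
        return self.angles.get(self._canonical((a, b, c)))

    def dihedral(self, a: str, b: str, c: str, d: str) -> list[DihedralEntry]:
        return self.dihedrals.get(self._canonical((a, b, c, d)), [])

    def __len__(self) -> int:
        return len(self.bonds) + len(self.angles) + sum(
            len(v) for v in self.dihedrals.values()
        )


_SECTION_ALIASES = {
    "bonds": "bonds",
    "bondtypes": "bonds",
    "angles": "angles",
    "angletypes": "angles",
    "dihedrals": "dihedrals",
    "dihedraltypes": "dihedrals",
}

# names per entry kind; remaining tokens are numeric (with optional leading func)
_ARITY = {"bonds": 2, "angles": 3, "dihedrals": 4}


def parse_itp(path: str | Path) -> BondedParameterSet:
    """Parse a Gromacs-dialect .itp of type-keyed bonded parameters.

    Recognized sections (``[ bonds ]``/``[ bondtypes ]`` etc.) hold lines of
    bead-type names followed by an optional integer function type and the
    numeric parameters:

    * bonds:     ``A B [func] l0 k``
    * angles:    ``A B C [func] theta0 k``
    * dihedrals: ``A B C D [func] phi0 k multiplicity``

    Duplicate dihedral lines for one quadruplet are all retained.  Unknown
    sections are skipped with a logged warning.  A malformed numeric field
    raises ``ValueError`` naming the line number.
    """
    path = Path(path)
    params = BondedParameterSet()
    section: str | None = None
    known_unparsed: set[str] = set()

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        if line.startswith("#"):  # preprocessor directives are not resolved
            logger.warning("%s:%d: ignoring directive %r", path.name, lineno, line)
            continue
        if line.startswith("["):
            name = line.strip("[] \t").lower()
            section = _SECTION_ALIASES.get(name)
            if section is None and name not in known_unparsed:
                known_unparsed.add(name)
                logger.warning("%s:%d: ignoring section [ %s ]", path.name, lineno, name)
            continue
        if section is None:
            continue

        tokens = line.split()
        arity = _ARITY[section]
        names, rest = tokens[:arity], tokens[arity:]
        if len(names) < arity or not rest:
            raise ValueError(
                f"{path.name}:{lineno}: expected {arity} bead types plus "
                f"parameters, got {raw!r}"
            )
        try:
            values = [float(tok) for tok in rest]
        except ValueError as exc:
            raise ValueError(
                f"{path.name}:{lineno}: malformed numeric field in {raw!r}"
            ) from exc

        # leading integer-valued token is the Gromacs function type
        expected = {"bonds": 2, "angles": 2, "dihedrals": 3}[section]
        func = None
        if len(values) > expected and float(values[0]).is_integer():
            func = int(values[0])
            values = values[1:]
        if len(values) < expected:
            raise ValueError(
                f"{path.name}:{lineno}: expected {expected} numeric parameters "
                f"in {raw!r}"
            )

        if section == "bonds":
            params.add_bond(*names, BondEntry(values[0], values[1], func or 1))
        elif section == "angles":
            params.add_angle(*names, AngleEntry(values[0], values[1], func or 2))
        else:
            params.add_dihedral(
                *names,
                DihedralEntry(values[0], values[1], int(values[2]), func or 1),
            )
    return params
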