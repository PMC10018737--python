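"""Structural statistics used to validate built nanoparticle models.

The monolayer is characterized by the normalized cumulative radial
distribution G_mono(r) of its beads about the particle's center of mass:
the fraction of monolayer beads within radius r, a step CDF that rises
from 0 to 1.  The monolayer thickness is the 90%-probability shell,
r_max - r_min with G_mono(r_min) = 0.05 and G_mono(r_max) = 0.95.  Ligand
order is summarized by the tilt angle between each anchor-to-bead vector
and the surface normal at the anchor, averaged over beads, then ligands,
then frames.  Compactness is tracked by the mass-weighted radius of
gyration, and uncertainties by bootstrap resampling of the observable
distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CoordinateFrameSeries",
    "CumulativeRDF",
    "cumulative_rdf",
    "monolayer_distances",
    "monolayer_thickness",
    "tilt_angles",
    "radius_of_gyration",
    "bootstrap_error",
    "series_from_model",
    "load_frames",
]


@dataclass
class CoordinateFrameSeries:
    """One or more coordinate frames plus the bead group bookkeeping."""

    positions: np.ndarray                 # (n_frames, n_beads, 3), nm
    masses: np.ndarray                    # (n_beads,), amu
    core_indices: np.ndarray
    ligand_ranges: list[tuple[int, int]]  # half-open global ranges per ligand
    anchor_indices: np.ndarray            # core bead index per ligand
    terminal_indices: np.ndarray | None = None
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.atleast_3d(np.asarray(self.positions, dtype=float))
        if self.positions.ndim != 3:
            raise ValueError("positions must be (n_frames, n_beads, 3)")
        if len(self.positions) < 1:
            raise ValueError("need at least one frame")

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    def monolayer_indices(self) -> np.ndarray:
        return np.concatenate(
            [np.arange(a, b) for a, b in self.ligand_ranges]
        ) if self.ligand_ranges else np.empty(0, dtype=int)


@dataclass
class CumulativeRDF:
    """Empirical step CDF of bead distances from the center of mass."""

    distances: np.ndarray   # sorted, nm

    def __call__(self, r) -> np.ndarray:
        return np.searchsorted(self.distances, np.asarray(r), side="right") / len(
            self.distances
        )

    @property
    def r(self) -> np.ndarray:
        return self.distances

    @property
    def g(self) -> np.ndarray:
        return np.arange(1, len(self.distances) + 1) / len(self.distances)

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.distances, q, method="linear"))


def cumulative_rdf(distances) -> CumulativeRDF:
    """Normalized cumulative RDF of monolayer beads.

    G_mono(r) is the fraction of the N_mono bead distances r_i that satisfy
    r_i <= r; it is non-decreasing and reaches exactly 1 at long range.
    """
    d = np.asarray(distances, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("empty monolayer: no distances to accumulate")
    return CumulativeRDF(distances=np.sort(d))


def monolayer_distances(
    frame: np.ndarray,
    masses: np.ndarray,
    core_indices: np.ndarray,
    monolayer_indices: np.ndarray,
    com: str = "core",
) -> np.ndarray:
    """Distances of monolayer beads from the particle's center of mass.

    By default the center of mass is computed over core beads only — the
    core dominates the particle's mass, and a core-only reference keeps
    the measure insensitive to monolayer fluctuations.  Pass ``com="all"``
    to include the ligand beads.
    """
    frame = np.asarray(frame, dtype=float)
    if com == "core":
        sel = np.asarray(core_indices)
    elif com == "all":
        sel = np.concatenate([np.asarray(core_indices), np.asarray(monolayer_indices)])
    else:
        raise ValueError("com must be 'core' or 'all'")
    w = np.asarray(masses, dtype=float)[sel]
    center = w @ frame[sel] / w.sum()
    return np.linalg.norm(frame[np.asarray(monolayer_indices)] - center, axis=1)


def monolayer_thickness(data) -> float:
    """Width of the 90%-probability monolayer shell.

    Locates r_min and r_max where the cumulative RDF crosses 0.05 and 0.95
    (linear interpolation between order statistics) and returns
    r_max - r_min.  Accepts either a :class:`CumulativeRDF` or a raw
    distance sample.
    """
    rdf = data if isinstance(data, CumulativeRDF) else cumulative_rdf(data)
    if np.unique(rdf.distances).size < 2:
        warnings.warn("fewer than 2 distinct distances: thickness is 0")
        return 0.0
    return rdf.quantile(0.95) - rdf.quantile(0.05)


def tilt_angles(series: CoordinateFrameSeries) -> tuple[float, np.ndarray]:
    """Mean ligand tilt angle (degrees) and its per-frame distribution.

    For every ligand bead, the tilt is the angle between the vector from
    the ligand's anchor to that bead and the surface normal at the anchor
    (recomputed each frame from the instantaneous core center of mass).
    Angles are averaged over beads within a ligand, then over ligands,
    then over frames.  Beads coincident with their anchor are skipped and
    counted in the series notes.
    """
    if len(series.ligand_ranges) == 0:
        raise ValueError("series has no ligands")
    w = series.masses[series.core_indices]
    per_frame = np.empty(series.n_frames)
    skipped = 0
    for f in range(series.n_frames):
        frame = series.positions[f]
        core_com = w @ frame[series.core_indices] / w.sum()
        ligand_means = []
        for (a, b), anchor in zip(series.ligand_ranges, series.anchor_indices):
            anchor_pos = frame[anchor]
            normal = anchor_pos - core_com
            nn = np.linalg.norm(normal)
            if nn < 1e-12:
                skipped += b - a
                continue
            normal = normal / nn
            vec = frame[a:b] - anchor_pos
            norms = np.linalg.norm(vec, axis=1)
            ok = norms > 1e-12
            skipped += int((~ok).sum())
            if not ok.any():
                continue
            cosang = np.clip(vec[ok] @ normal / norms[ok], -1.0, 1.0)
            ligand_means.append(np.degrees(np.arccos(cosang)).mean())
        per_frame[f] = np.mean(ligand_means)
    if skipped:
        series.notes.append(f"{skipped} bead(s) coincident with their anchor skipped")
    return float(per_frame.mean()), per_frame


def radius_of_gyration(frame: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted root-mean-square distance from the center of mass (nm)."""
    frame = np.asarray(frame, dtype=float)
    m = np.asarray(masses, dtype=float)
    total = m.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = m @ frame / total
    return float(np.sqrt((m * ((frame - com) ** 2).sum(axis=1)).sum() / total))


def bootstrap_error(
    values,
    iterations: int = 1000,
    fraction: float = 0.01,
    seed: int | None = None,
) -> float:
    """Bootstrap standard error of the mean of an observable distribution.

    Draws ``iterations`` resamples with replacement, each of size
    ``fraction`` of the original sample (defaults: 1,000 iterations at 1%),
    and returns the standard deviation of the resampled means.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty sample")
    size = max(1, round(fraction * v.size))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(iterations, size))
    return float(v[idx].mean(axis=1).std())


def series_from_model(model) -> CoordinateFrameSeries:
    """Single-frame series straight from a built nanoparticle model."""
    core = model.core
    masses = [core.masses if core.masses is not None else np.ones(core.n_beads)]
    terminal = []
    for lig, (a, b) in zip(model.ligands, model.ligand_bead_ranges()):
        masses.append([bead.mass for bead in lig.template.beads])
        terminal.append(b - 1)
    return CoordinateFrameSeries(
        positions=model.positions()[None, :, :],
        masses=np.concatenate([np.asarray(m, dtype=float) for m in masses]),
        core_indices=np.arange(core.n_beads),
        ligand_ranges=model.ligand_bead_ranges(),
        anchor_indices=np.array([l.anchor_index for l in model.ligands]),
        terminal_indices=np.array(terminal, dtype=int),
    )


def load_frames(path: str | Path) -> np.ndarray:
    """Read coordinates (nm) from a .gro/.pdb file, including concatenated
    multi-frame .gro files, as an (n_frames, n_beads, 3) array."""
    import MDAnalysis as mda

    path = Path(path)
    if path.suffix.lower() == ".gro":
        frames = []
        lines = path.read_text().splitlines()
        pos = 0
        while pos < len(lines) - 1:
            n_atoms = int(lines[pos + 1].split()[0])
            block = lines[pos: pos + n_atoms + 3]
            coords = np.array(
                [
                    [float(l[20:28]), float(l[28:36]), float(l[36:44])]
                    for l in block[2: 2 + n_atoms]
                ]
            )
            frames.append(coords)
            pos += n_atoms + 3
        return np.stack(frames)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        return np.stack([u.atoms.positions / 10.0 for _ in u.trajectory])
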