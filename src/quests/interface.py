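"""Interface scoring: buried surface area, contact surrogate, steric clashes.

Solvent-accessible surface area (SASA) uses the Shrake–Rupley rolling-probe
construction: each atom sphere is inflated by the probe radius (1.4 Å, a
water molecule) and sampled with a fixed golden-spiral point lattice; points
falling inside any neighboring inflated sphere are occluded.  The lattice is
deterministic, so all areas are bit-reproducible.

``delta_sasa`` is the surface buried upon dimerization,
SASA(A) + SASA(B) − SASA(A·B): non-negative, zero for separated protomers,
and increasing as the protomers approach.  Ranking an ensemble of dimer
models by ΔSASA orders variants by predicted burial (larger burial
correlating with higher dimerization propensity).

``contact_score`` is an explicitly surrogate interface score — a smooth
distance well over inter-protomer atom pairs with a polar donor–acceptor
bonus — used to exercise energy-based triage end to end.  It is reported in
arbitrary surrogate units, never in Rosetta Energy Units.

``clash_count`` counts van der Waals overlaps r_i + r_j − d_ij ≥ cutoff
(default 0.6 Å, inclusive) between two atom sets, e.g. a receptor dimer vs a
docked β-arrestin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structures import Atom, DimerModel

__all__ = [
    "RadiusSet",
    "InterfaceScore",
    "ClashResult",
    "DEFAULT_RADII",
    "sasa",
    "total_sasa",
    "delta_sasa",
    "contact_score",
    "clash_count",
    "score_interface",
]

#: Standard per-element van der Waals radii (Å) used for SASA and clashes.
_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}


@dataclass(frozen=True)
class RadiusSet:
    """Van der Waals radii by element (optionally overridden per atom name) plus probe radius."""

    by_element: dict[str, float] = field(default_factory=lambda: dict(_VDW))
    by_name: dict[str, float] = field(default_factory=dict)
    probe_radius: float = 1.4

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.by_element.values()) or any(
            r <= 0 for r in self.by_name.values()
        ):
            raise ValueError("all radii must be positive")
        if self.probe_radius < 0:
            raise ValueError("probe radius must be non-negative")

    def radius(self, atom: Atom) -> float:
        if atom.name in self.by_name:
            return self.by_name[atom.name]
        key = atom.element.upper()
        if key not in self.by_element:
            raise KeyError(
                f"no van der Waals radius for element {atom.element!r} (atom {atom.name!r})"
            )
        return self.by_element[key]

    def radii_for(self, atoms: list[Atom]) -> np.ndarray:
        missing = [a.name for a in atoms if a.name not in self.by_name
                   and a.element.upper() not in self.by_element]
        if missing:
            raise KeyError(f"no van der Waals radius for atoms: {missing}")
        return np.asarray([self.radius(a) for a in atoms])


DEFAULT_RADII = RadiusSet()


@dataclass(frozen=True)
class InterfaceScore:
    """Summary scores of one dimer interface."""

    delta_sasa: float
    contact_score: float
    n_contacts: int
    clash_count: int


@dataclass(frozen=True)
class ClashResult:
    count: int
    worst: list[tuple[int, int, float]]  # (index in A, index in B, overlap Å), worst first


def _sphere_lattice(n: int) -> np.ndarray:
    """Deterministic golden-spiral lattice of n near-uniform points on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1
    )


def sasa(atoms: list[Atom], radii: RadiusSet = DEFAULT_RADII, n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake–Rupley sampling."""
    if not atoms:
        raise ValueError("sasa needs at least one atom")
    coords = np.asarray([a.xyz for a in atoms])
    expanded = radii.radii_for(atoms) + radii.probe_radius
    lattice = _sphere_lattice(n_points)
    tree = cKDTree(coords)
    out = np.empty(len(atoms))
    r_max = expanded.max()
    for i in range(len(atoms)):
        dists = {
            j: float(np.linalg.norm(coords[j] - coords[i]))
            for j in tree.query_ball_point(coords[i], expanded[i] + r_max)
            if j != i
        }
        neighbors = [j for j, d in dists.items() if d < expanded[i] + expanded[j]]
        # containment: a sphere inside another is fully buried; for exactly
        # coincident equal spheres the later atom is the buried one
        buried = any(
            dists[j] + expanded[i] < expanded[j] - 1e-9
            or (dists[j] < 1e-9 and expanded[i] == expanded[j] and j < i)
            for j in neighbors
        )
        if buried:
            out[i] = 0.0
            continue
        points = coords[i] + expanded[i] * lattice
        if neighbors:
            free = np.ones(n_points, dtype=bool)
            for j in neighbors:
                free &= np.linalg.norm(points - coords[j], axis=1) >= expanded[j] - 1e-9
            frac = free.mean()
        else:
            frac = 1.0
        out[i] = 4.0 * np.pi * expanded[i] ** 2 * frac
    return out


def total_sasa(atoms: list[Atom], radii: RadiusSet = DEFAULT_RADII, n_points: int = 960) -> float:
    return float(sasa(atoms, radii, n_points).sum())


def delta_sasa(
    dimer: DimerModel, radii: RadiusSet = DEFAULT_RADII, n_points: int = 960
) -> float:
    """Buried surface area upon dimerization: SASA(A) + SASA(B) − SASA(A·B), Å²."""
    atoms_a = dimer.a.atoms()
    atoms_b = dimer.b.atoms()
    if not atoms_a or not atoms_b:
        raise ValueError("both protomers need atoms")
    return (
        total_sasa(atoms_a, radii, n_points)
        + total_sasa(atoms_b, radii, n_points)
        - total_sasa(atoms_a + atoms_b, radii, n_points)
    )


_POLAR_ELEMENTS = {"N", "O"}


def contact_score(
    dimer: DimerModel,
    radii: RadiusSet = DEFAULT_RADII,
    well_depth: float = 1.0,
    cutoff: float = 5.5,
    polar_bonus: float = 0.5,
    well_width: float = 1.0,
) -> tuple[float, int]:
    """Surrogate interface score over inter-protomer atom pairs (lower = more favorable).

    Each pair within ``cutoff`` contributes a Gaussian well
    −well_depth·exp(−(d − r_i − r_j)² / 2·well_width²) centered at van der
    Waals contact; N/O–N/O pairs within 3.5 Å gain an extra −polar_bonus.
    Symmetric under protomer swap.  Returns (score, n_contacts).
    """
    atoms_a = dimer.a.atoms()
    atoms_b = dimer.b.atoms()
    ca = np.asarray([a.xyz for a in atoms_a])
    cb = np.asarray([a.xyz for a in atoms_b])
    ra = radii.radii_for(atoms_a)
    rb = radii.radii_for(atoms_b)
    pairs = cKDTree(ca).query_ball_tree(cKDTree(cb), cutoff)
    score = 0.0
    n_contacts = 0
    for i, js in enumerate(pairs):
        for j in js:
            d = float(np.linalg.norm(ca[i] - cb[j]))
            r0 = ra[i] + rb[j]
            score -= well_depth * float(np.exp(-((d - r0) ** 2) / (2.0 * well_width**2)))
            n_contacts += 1
            if (
                d <= 3.5
                and atoms_a[i].element.upper() in _POLAR_ELEMENTS
                and atoms_b[j].element.upper() in _POLAR_ELEMENTS
            ):
                score -= polar_bonus
    return score, n_contacts


def clash_count(
    atoms_a: list[Atom],
    atoms_b: list[Atom],
    radii: RadiusSet = DEFAULT_RADII,
    overlap_cutoff: float = 0.6,
    exclude_pairs: set[tuple[int, int]] | None = None,
    n_worst: int = 10,
) -> ClashResult:
    """Count steric clashes between two atom sets.

    A pair clashes when overlap = r_i + r_j − d_ij ≥ ``overlap_cutoff``
    (boundary inclusive).  ``exclude_pairs`` removes specific (i, j) index
    pairs, e.g. covalently bonded neighbors when the two sets share a chain.
    """
    if not atoms_a or not atoms_b:
        raise ValueError("both atom sets must be non-empty")
    ca = np.asarray([a.xyz for a in atoms_a])
    cb = np.asarray([a.xyz for a in atoms_b])
    ra = radii.radii_for(atoms_a)
    rb = radii.radii_for(atoms_b)
    # r_i + r_j - d >= cutoff  =>  d <= r_i + r_j - cutoff <= max sum - cutoff
    search = float(ra.max() + rb.max() - overlap_cutoff)
    clashes: list[tuple[int, int, float]] = []
    if search > 0:
        pairs = cKDTree(ca).query_ball_tree(cKDTree(cb), search)
        for i, js in enumerate(pairs):
            for j in js:
                if exclude_pairs and (i, j) in exclude_pairs:
                    continue
                overlap = ra[i] + rb[j] - float(np.linalg.norm(ca[i] - cb[j]))
                if overlap >= overlap_cutoff - 1e-12:
                    clashes.append((i, j, overlap))
    clashes.sort(key=lambda t: -t[2])
    return ClashResult(count=len(clashes), worst=clashes[:n_worst])


def score_interface(
    dimer: DimerModel,
    radii: RadiusSet = DEFAULT_RADII,
    overlap_cutoff: float = 0.6,
    n_points: int = 960,
) -> InterfaceScore:
    """All interface scores of one dimer model in one pass."""
    dsasa = delta_sasa(dimer, radii, n_points)
    score, n_contacts = contact_score(dimer, radii)
    clashes = clash_count(dimer.a.atoms(), dimer.b.atoms(), radii, overlap_cutoff)
    return InterfaceScore(
        delta_sasa=dsasa,
        contact_score=score,
        n_contacts=n_contacts,
        clash_count=clashes.count,
    )
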