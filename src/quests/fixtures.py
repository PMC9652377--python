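"""Synthetic structures, ensembles, and energy ledgers.

Everything downstream of a docking or design engine can be exercised without
one: this module builds ideal α-helices with closed-form geometry, toy
dimers with an exactly planted (theta, d), dimer ensembles with planted
conformational clusters and an exact out-of-membrane-window fraction, and
mock energy ledgers whose presets reproduce the qualitative open/closed
energy patterns of a TM5-interface receptor dimer:

* ``wt-like`` — the open dimer is the primary conformation in both
  signaling states; the closed conformation is markedly stabilized in the
  active state (the activation-coupled shift toward the closed dimer).
* ``open-stabilizing`` — an L194R-like design adding a strong polar contact
  across the TM5 interface: the open-dimer interface is stabilized by
  2.4 REU.
* ``closed-switch`` — a W195L-like design: the open form still dominates in
  the inactive state, but the closed form becomes the lowest-energy, dominant
  conformation in the active state (the open/closed majority flips).

All generators take an explicit seed (no hidden global RNG) and are
bit-reproducible given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .design import EnergyLedger, LedgerEntry, CONFORMATIONS, STATES
from .ensemble import EnsembleRecord
from .geometry import DimerGeometry, helix_axis
from .structures import Atom, DimerModel, HelixSegment, Protomer, Residue

__all__ = [
    "HelixSpec",
    "ClusterSpec",
    "EnsembleSpec",
    "LedgerSpec",
    "make_ideal_helix",
    "helix_protomer",
    "make_toy_dimer",
    "make_dimer_ensemble",
    "make_energy_ledger",
    "preset_ledger_spec",
    "LEDGER_PRESETS",
]


# ---------------------------------------------------------------------------
# ideal helices and toy dimers


@dataclass(frozen=True)
class HelixSpec:
    """Ideal α-helix: canonical 1.5 Å rise and 100° twist per residue, 2.3 Å Cα radius."""

    n_residues: int = 20
    rise: float = 1.5
    twist: float = 100.0
    radius: float = 2.3
    rotation: np.ndarray | None = None  # 3x3, applied after construction
    translation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValueError("a helix needs at least 4 residues")
        if self.rise <= 0:
            raise ValueError("rise must be positive")


def make_ideal_helix(spec: HelixSpec = HelixSpec()) -> np.ndarray:
    """Cα coordinates of an ideal helix wound around +z, shape (n, 3)."""
    k = np.arange(spec.n_residues)
    ang = np.radians(spec.twist) * k
    coords = np.stack(
        [spec.radius * np.cos(ang), spec.radius * np.sin(ang), spec.rise * k], axis=1
    )
    if spec.rotation is not None:
        coords = coords @ np.asarray(spec.rotation).T
    if spec.translation is not None:
        coords = coords + np.asarray(spec.translation)
    return coords


def helix_protomer(
    coords: np.ndarray,
    chain_id: str = "A",
    start_seq: int = 190,
    tm_index: int = 5,
    variant: str = "WT",
) -> Protomer:
    """Wrap Cα coordinates as a single-TM protomer (one Cα pseudo-atom per residue)."""
    residues = [
        Residue(
            seq_id=start_seq + i,
            chain_id=chain_id,
            aa="A",
            atoms=[Atom("CA", "C", xyz)],
        )
        for i, xyz in enumerate(np.asarray(coords))
    ]
    helices = [HelixSegment(tm_index, start_seq, start_seq + len(residues) - 1)]
    return Protomer(chain_id, residues, helices=helices, variant=variant)


def make_toy_dimer(
    theta: float,
    d: float,
    spec: HelixSpec = HelixSpec(),
    tm_index: int = 5,
) -> DimerModel:
    """Two-helix dimer whose fitted geometry is exactly (theta, d).

    Protomer A's fitted axis is aligned onto +z with its centroid at the
    origin; protomer B is A rotated by ``theta`` about the centroid-separation
    direction (+x) and translated ``d`` Å along it, which by construction
    reproduces the planted crossing angle and distance.
    """
    if not (-180.0 < theta <= 180.0):
        raise ValueError("theta must lie in (-180, 180]")
    if d < 0:
        raise ValueError("d must be non-negative")
    coords = make_ideal_helix(spec)
    axis = helix_axis(coords)
    align = Rotation.align_vectors([[0.0, 0.0, 1.0]], [axis.direction])[0]
    coords_a = align.apply(coords - axis.centroid)
    coords_a -= coords_a.mean(axis=0)  # fitted centroid exactly at origin
    rot_b = Rotation.from_rotvec(np.radians(theta) * np.array([1.0, 0.0, 0.0]))
    coords_b = rot_b.apply(coords_a) + np.array([d, 0.0, 0.0])
    return DimerModel(
        a=helix_protomer(coords_a, "A", tm_index=tm_index),
        b=helix_protomer(coords_b, "B", tm_index=tm_index),
    )


# ---------------------------------------------------------------------------
# planted ensembles


@dataclass(frozen=True)
class ClusterSpec:
    """One planted conformational cluster in (theta, d, energy) space."""

    weight: float
    theta_mean: float
    theta_sd: float
    d_mean: float
    d_sd: float
    energy_mean: float
    energy_sd: float
    name: str = ""


@dataclass(frozen=True)
class EnsembleSpec:
    """A planted dimer ensemble: cluster mixture plus an exact fraction of
    models whose crossing angle falls outside the membrane window."""

    clusters: Sequence[ClusterSpec]
    n_models: int
    seed: int
    outside_filter_fraction: float = 0.0
    theta_lo: float = -50.0
    theta_hi: float = 85.0

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        total = sum(c.weight for c in self.clusters)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cluster weights must sum to 1, got {total}")
        if not 0.0 <= self.outside_filter_fraction <= 1.0:
            raise ValueError("outside_filter_fraction must be in [0, 1]")


def make_dimer_ensemble(
    spec: EnsembleSpec,
) -> tuple[list[EnsembleRecord], dict[str, np.ndarray]]:
    """Sample an ensemble of (theta, d, energy) records with known ground truth.

    Exactly ``round(outside_filter_fraction · n_models)`` models have their
    theta resampled outside [theta_lo, theta_hi] so filter statistics are
    exact, not merely expected.  Returns (records, truth) where truth holds
    ``cluster`` (planted component index) and ``outside`` (bool) arrays.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_models
    weights = np.array([c.weight for c in spec.clusters])
    assignment = rng.choice(len(spec.clusters), size=n, p=weights)
    theta = np.empty(n)
    dist = np.empty(n)
    energy = np.empty(n)
    for idx, c in enumerate(spec.clusters):
        mask = assignment == idx
        m = int(mask.sum())
        theta[mask] = rng.normal(c.theta_mean, c.theta_sd, m)
        dist[mask] = np.abs(rng.normal(c.d_mean, c.d_sd, m))
        energy[mask] = rng.normal(c.energy_mean, c.energy_sd, m)

    n_outside = round(spec.outside_filter_fraction * n)
    outside = np.zeros(n, dtype=bool)
    if n_outside:
        chosen = rng.choice(n, size=n_outside, replace=False)
        outside[chosen] = True
        # place the resampled angles clearly beyond either boundary
        high = rng.uniform(spec.theta_hi + 5.0, min(spec.theta_hi + 60.0, 179.0), n_outside)
        low = rng.uniform(max(spec.theta_lo - 60.0, -179.0), spec.theta_lo - 5.0, n_outside)
        pick_high = rng.random(n_outside) < 0.5
        theta[chosen] = np.where(pick_high, high, low)

    width = len(str(n - 1))
    records = [
        EnsembleRecord(
            model_id=f"m{i:0{width}d}",
            geometry=DimerGeometry(theta=float(theta[i]), d=float(dist[i]),
                                   angle_tm5=float(theta[i])),
            interface_energy=float(energy[i]),
        )
        for i in range(n)
    ]
    return records, {"cluster": assignment, "outside": outside}


# ---------------------------------------------------------------------------
# mock energy ledgers


@dataclass(frozen=True)
class LedgerSpec:
    """Mock ledger: WT interface energies per (conformation, state) plus
    per-variant interface offsets; WT offsets are implicitly zero."""

    wt_interface: dict[tuple[str, str], float]
    offsets: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)
    monomer_energy: float = -300.0
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if "WT" in self.offsets and any(v != 0.0 for v in self.offsets["WT"].values()):
            raise ValueError("WT offsets must all be zero")
        if self.noise_sd > 0 and self.seed is None:
            raise ValueError("noisy ledgers require a seed")


#: WT interface energies (REU): open is the primary conformation in both
#: states; the closed form sits 3.0 REU above open when inactive but only
#: 0.5 REU above when active (activation-coupled closed-state stabilization).
_WT_INTERFACE = {
    ("open", "inactive"): -12.0,
    ("closed", "inactive"): -9.0,
    ("open", "active"): -12.0,
    ("closed", "active"): -11.5,
}

LEDGER_PRESETS: dict[str, dict[tuple[str, str], float]] = {
    # L194R-like: strong designed polar contact stabilizes the open interface
    # by 2.4 REU in either state; the closed form is untouched.
    "open-stabilizing": {
        ("open", "inactive"): -2.4,
        ("open", "active"): -2.4,
    },
    # W195L-like conformational switch: a weaker dimer than WT while
    # inactive (open still the majority form), but in the active state the
    # closed conformation drops below the open one and dominates.
    "closed-switch": {
        ("open", "inactive"): +1.5,
        ("closed", "inactive"): -1.0,
        ("open", "active"): +0.5,
        ("closed", "active"): -3.5,
    },
    "wt-like": {},
}

_PRESET_VARIANT_NAMES = {
    "wt-like": "WT",
    "open-stabilizing": "L194R-like",
    "closed-switch": "W195L-like",
}


def preset_ledger_spec(*presets: str) -> LedgerSpec:
    """Ledger spec containing WT plus the named preset variants.

    Available presets: ``wt-like`` (WT alone), ``open-stabilizing``
    (L194R-like), ``closed-switch`` (W195L-like).
    """
    offsets = {}
    for preset in presets or ("wt-like",):
        if preset not in LEDGER_PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(LEDGER_PRESETS)}")
        if preset != "wt-like":
            offsets[_PRESET_VARIANT_NAMES[preset]] = dict(LEDGER_PRESETS[preset])
    return LedgerSpec(wt_interface=dict(_WT_INTERFACE), offsets=offsets)


def make_energy_ledger(spec: LedgerSpec) -> EnergyLedger:
    """Build a complete EnergyLedger from a LedgerSpec.

    Offsets shift the variant's dimer energy (monomer energies equal WT's),
    so E_interface(variant) = E_interface(WT) + offset.  Optional Gaussian
    noise (sd ``noise_sd``) perturbs dimer energies reproducibly by seed.
    """
    rng = np.random.default_rng(spec.seed) if spec.noise_sd > 0 else None
    entries: list[LedgerEntry] = []
    variants = ["WT"] + [v for v in spec.offsets if v != "WT"]
    for variant in variants:
        for conf in CONFORMATIONS:
            for state in STATES:
                key = (conf, state)
                if key not in spec.wt_interface:
                    continue
                e_int = spec.wt_interface[key]
                if variant != "WT":
                    e_int += spec.offsets[variant].get(key, 0.0)
                if rng is not None:
                    e_int += float(rng.normal(0.0, spec.noise_sd))
                e_mono = spec.monomer_energy
                entries.append(
                    LedgerEntry(
                        variant=variant,
                        conformation=conf,
                        state=state,
                        e_dimer=2.0 * e_mono + e_int,
                        e_monomer=e_mono,
                    )
                )
    return EnergyLedger(entries)
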