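"""Dimer-interface geometry.

A TM helix is reduced to a line: the principal axis of its centered Cα
coordinates (total least squares via SVD), sign-fixed to point N→C.  The
relative orientation of two protomers across the dimer interface is then
summarized by two numbers,

* ``theta`` — the signed crossing angle between the two TM5 axes, and
* ``d``    — the distance between the two TM5 centroids (Å),

the feature pair used for conformational clustering.  The membrane-embedding
filter accepts crossing angles within [−50°, +85°] (bounds inclusive); the
antiparallel/over-tilted geometries outside that window cannot insert both
protomers properly into one bilayer.

Sign convention: the unsigned angle is arccos(a·b); its sign is that of
(a × b)·u with u the unit vector from the first to the second helix
centroid.  A signed range necessarily implies *some* convention; this one is
deterministic and can be flipped downstream if a mirrored convention is
preferred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import AnnotationError, DimerModel, Protomer, StructureError

__all__ = [
    "HelixAxis",
    "DimerGeometry",
    "GeometryError",
    "helix_axis",
    "interhelical_angle",
    "dimer_geometry",
    "orientation_filter",
    "ca_rmsd",
]


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class HelixAxis:
    """Fitted helix axis: unit direction (N→C), centroid (Å), and line-fit residual (Å)."""

    direction: np.ndarray
    centroid: np.ndarray
    fit_rms: float


@dataclass(frozen=True)
class DimerGeometry:
    """Interface geometry of one dimer model: (theta, d) plus the raw TM5 crossing angle."""

    theta: float
    d: float
    angle_tm5: float

    def __post_init__(self) -> None:
        if not (-180.0 < self.theta <= 180.0):
            raise GeometryError(f"theta must lie in (-180, 180], got {self.theta}")
        if self.d < 0:
            raise GeometryError("d must be non-negative")


def helix_axis(ca_coords: np.ndarray) -> HelixAxis:
    """Fit the principal line through ordered Cα coordinates (total least squares).

    The direction is the leading right-singular vector of the centered
    coordinates, sign-fixed so that it points from the N- toward the
    C-terminal end; ``fit_rms`` is the RMS perpendicular distance of the
    points from the fitted line (≈ helix radius for an ideal helix).
    """
    X = np.asarray(ca_coords, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise GeometryError("ca_coords must have shape (n, 3)")
    if len(X) < 4:
        raise GeometryError(f"axis fit needs >= 4 Cα positions, got {len(X)}")
    centroid = X.mean(axis=0)
    Xc = X - centroid
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    direction = vt[0]
    if direction @ (X[-1] - X[0]) < 0:
        direction = -direction
    perp = Xc - np.outer(Xc @ direction, direction)
    fit_rms = float(np.sqrt(np.mean(np.sum(perp**2, axis=1))))
    return HelixAxis(direction=direction, centroid=centroid, fit_rms=fit_rms)


def interhelical_angle(a: HelixAxis, b: HelixAxis) -> float:
    """Signed crossing angle between two helix axes, degrees in (−180, 180].

    Antisymmetric under argument swap.  If the two centroids coincide the
    sign is undefined; the unsigned angle is returned with a warning.
    """
    cosang = float(np.clip(a.direction @ b.direction, -1.0, 1.0))
    unsigned = float(np.degrees(np.arccos(cosang)))
    sep = b.centroid - a.centroid
    norm = np.linalg.norm(sep)
    if norm < 1e-9:
        warnings.warn("coincident helix centroids: returning unsigned angle", stacklevel=2)
        return unsigned
    u = sep / norm
    sign = float(np.cross(a.direction, b.direction) @ u)
    if sign < 0:
        return -unsigned
    return unsigned


def dimer_geometry(dimer: DimerModel, tm: int = 5) -> DimerGeometry:
    """Compute (theta, d) for a dimer model from the chosen TM helix (default TM5)."""
    axis_a = helix_axis(dimer.a.helix_ca(tm))
    axis_b = helix_axis(dimer.b.helix_ca(tm))
    theta = interhelical_angle(axis_a, axis_b)
    d = float(np.linalg.norm(axis_b.centroid - axis_a.centroid))
    if tm == 5:
        angle_tm5 = theta
    else:
        try:
            angle_tm5 = interhelical_angle(
                helix_axis(dimer.a.helix_ca(5)), helix_axis(dimer.b.helix_ca(5))
            )
        except (AnnotationError, StructureError):
            angle_tm5 = theta
    return DimerGeometry(theta=theta, d=d, angle_tm5=angle_tm5)


def orientation_filter(theta: float, lo: float = -50.0, hi: float = 85.0) -> bool:
    """Membrane-embedding filter: accept crossing angles with lo <= theta <= hi (inclusive)."""
    if lo > hi:
        raise GeometryError(f"orientation filter bounds inverted: lo={lo} > hi={hi}")
    return lo <= theta <= hi


def ca_rmsd(a: Protomer, b: Protomer, superpose: bool = True) -> float:
    """Cα RMSD between two protomers matched by author seq_id.

    With ``superpose`` the optimal least-squares (Kabsch) superposition is
    applied first, so rigid motions give RMSD 0.
    """
    ca_a = {r.seq_id: r.ca.xyz for r in a.residues if r.ca is not None}
    ca_b = {r.seq_id: r.ca.xyz for r in b.residues if r.ca is not None}
    common = sorted(set(ca_a) & set(ca_b))
    if len(common) < 3:
        raise GeometryError(f"need >= 3 common Cα, found {len(common)}")
    P = np.asarray([ca_a[i] for i in common])
    Q = np.asarray([ca_b[i] for i in common])
    if superpose:
        Pc = P - P.mean(axis=0)
        Qc = Q - Q.mean(axis=0)
        rot, _ = Rotation.align_vectors(Qc, Pc)
        diff = Qc - rot.apply(Pc)
    else:
        diff = Q - P
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
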