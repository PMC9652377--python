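"""Receptor coordinate I/O and annotation.

Reads multi-chain receptor structures (PDB/mmCIF), splits them into
protomers, attaches transmembrane-helix (TM) segment annotations, and
assigns Ballesteros–Weinstein (BW) generic numbers.  BW numbers have the
form ``<TM>.<index>`` where index 50 marks the most conserved residue of
that helix (the "x.50 anchor"); all other positions are numbered by
sequential offset from the anchor, so e.g. the residue sixteen positions
N-terminal of 5.50 is 5.34.

Author residue numbering is authoritative throughout: motifs in the GPCR
literature (W195^5.34, L194^5.33, ...) are quoted in author numbering.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "HelixSegment",
    "Protomer",
    "MembraneFrame",
    "DimerModel",
    "StructureError",
    "FormatError",
    "EmptyInputError",
    "AnnotationError",
    "BWLookupError",
    "read_structure",
    "write_pdb",
    "annotate_helices",
    "bw_lookup",
    "load_helix_config",
]

_BW_PATTERN = re.compile(r"^[1-8]\.\d{2}$")


class StructureError(ValueError):
    """Base class for structure-handling errors."""


class FormatError(StructureError):
    """Raised when a coordinate file cannot be parsed."""


class EmptyInputError(StructureError):
    """Raised when a file contains no polymer chain."""


class AnnotationError(StructureError):
    """Raised when a helix segment cannot be resolved against a protomer."""


class BWLookupError(StructureError):
    """Raised when a Ballesteros–Weinstein code is absent from a protomer."""


@dataclass
class Atom:
    """A single atom: label, chemical element, Cartesian coordinates (Å)."""

    name: str
    element: str
    xyz: np.ndarray

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise StructureError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if not self.element:
            raise StructureError(f"atom {self.name!r}: element must be non-empty")


@dataclass
class Residue:
    """One residue in author numbering, with its atoms and optional BW code."""

    seq_id: int
    chain_id: str
    aa: str
    atoms: list[Atom] = field(default_factory=list)
    bw: str | None = None
    icode: str = ""

    def __post_init__(self) -> None:
        if self.bw is not None and not _BW_PATTERN.match(self.bw):
            raise StructureError(f"invalid BW code {self.bw!r} (expected e.g. '5.34')")
        n_ca = sum(1 for a in self.atoms if a.name == "CA")
        if n_ca > 1:
            raise StructureError(f"residue {self.seq_id}: more than one Cα atom")

    @property
    def ca(self) -> Atom | None:
        for a in self.atoms:
            if a.name == "CA":
                return a
        return None


@dataclass(frozen=True)
class HelixSegment:
    """A TM helix span [start_seq, end_seq] in author numbering (tm_index 1–7, 8 = H8)."""

    tm_index: int
    start_seq: int
    end_seq: int

    def __post_init__(self) -> None:
        if not 1 <= self.tm_index <= 8:
            raise StructureError(f"tm_index must be 1..8, got {self.tm_index}")
        if self.start_seq > self.end_seq:
            raise StructureError("helix segment start_seq must be <= end_seq")


class State(str, Enum):
    inactive = "inactive"
    active = "active"
    unspecified = "unspecified"


@dataclass
class Protomer:
    """One receptor chain: ordered residues plus TM/BW annotation and labels."""

    chain_id: str
    residues: list[Residue]
    helices: list[HelixSegment] = field(default_factory=list)
    state: State = State.unspecified
    variant: str = "WT"

    def __post_init__(self) -> None:
        keys = [(r.seq_id, r.icode) for r in self.residues]
        if any(k2 <= k1 for k1, k2 in zip(keys, keys[1:])):
            raise StructureError(f"chain {self.chain_id}: residues must strictly increase in seq_id")

    def residue(self, seq_id: int) -> Residue:
        for r in self.residues:
            if r.seq_id == seq_id:
                return r
        raise StructureError(f"chain {self.chain_id}: no residue {seq_id}")

    def helix(self, tm_index: int) -> HelixSegment:
        for h in self.helices:
            if h.tm_index == tm_index:
                return h
        raise AnnotationError(f"chain {self.chain_id}: no TM{tm_index} annotation")

    def helix_ca(self, tm_index: int) -> np.ndarray:
        """Ordered Cα coordinates of the given TM helix, shape (n, 3)."""
        h = self.helix(tm_index)
        coords = [
            r.ca.xyz
            for r in self.residues
            if h.start_seq <= r.seq_id <= h.end_seq and r.ca is not None
        ]
        if len(coords) < 4:
            raise AnnotationError(
                f"chain {self.chain_id}: TM{tm_index} resolves to {len(coords)} Cα (need >= 4)"
            )
        return np.asarray(coords)

    def ca_coords(self) -> np.ndarray:
        return np.asarray([r.ca.xyz for r in self.residues if r.ca is not None])

    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]


@dataclass
class MembraneFrame:
    """Membrane coordinate frame: unit normal (default +z) and center (Å)."""

    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise StructureError("membrane normal must be a unit vector")


@dataclass
class DimerModel:
    """An ordered pair of protomers, optionally carrying an interface energy (REU or surrogate)."""

    a: Protomer
    b: Protomer
    interface_energy: float | None = None
    model_id: str = ""


# ---------------------------------------------------------------------------
# reading / writing


def _one_letter(name: str) -> str:
    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


def read_structure(
    path: str | Path,
    fmt: str | None = None,
    keep_hetero: bool = False,
    state: State | str = State.unspecified,
    variant: str = "WT",
) -> list[Protomer]:
    """Read a PDB or mmCIF file into one :class:`Protomer` per polymer chain.

    Heteroatoms (detergent, lipid, ligand, water) are excluded unless
    ``keep_hetero`` is true; alternate locations keep the highest-occupancy
    conformer; chain order follows the file.
    """
    path = Path(path)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyInputError(f"{path}: no models")
    st.setup_entities()
    model = st[0]

    protomers: list[Protomer] = []
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            is_polymer = res.het_flag == "A"
            if not is_polymer and not keep_hetero:
                continue
            if res.is_water():
                continue
            # alternate locations: keep highest occupancy per atom name
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            atoms = [
                Atom(a.name, a.element.name or "X", np.array([a.pos.x, a.pos.y, a.pos.z]))
                for a in best.values()
            ]
            residues.append(
                Residue(
                    seq_id=res.seqid.num,
                    chain_id=chain.name,
                    aa=_one_letter(res.name),
                    atoms=atoms,
                    icode=(res.seqid.icode or "").strip(),
                )
            )
        if residues:
            protomers.append(
                Protomer(chain.name, residues, state=State(state), variant=variant)
            )
    if not protomers:
        raise EmptyInputError(f"{path}: no polymer chains")
    return protomers


_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL", "X": "UNK",
}


def write_pdb(protomers: Iterable[Protomer], path: str | Path) -> None:
    """Write protomers to a PDB file (one chain each, author numbering kept)."""
    st = gemmi.Structure()
    st.name = "quests"
    model = gemmi.Model("1")
    for p in protomers:
        chain = gemmi.Chain(p.chain_id)
        for r in p.residues:
            res = gemmi.Residue()
            res.name = _AA3.get(r.aa, "UNK")
            res.seqid = gemmi.SeqId(r.seq_id, r.icode or " ")
            res.het_flag = "A"
            for a in r.atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.xyz)
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# annotation


def annotate_helices(
    protomer: Protomer,
    segments: Sequence[HelixSegment],
    bw_anchors: dict[int, int] | None = None,
) -> Protomer:
    """Return a copy of ``protomer`` with helices attached and BW codes filled.

    ``bw_anchors`` maps a TM index to the author seq_id of its x.50 anchor
    residue; BW indices follow by linear offset (seq 195 with anchor 211 on
    TM5 becomes 5.34).  Idempotent: re-annotating recomputes the same labels.
    """
    residues = [replace(r, atoms=list(r.atoms)) for r in protomer.residues]
    by_seq = {r.seq_id: r for r in residues}
    for seg in segments:
        span = [r for r in residues if seg.start_seq <= r.seq_id <= seg.end_seq]
        if not span:
            raise AnnotationError(
                f"TM{seg.tm_index} [{seg.start_seq}-{seg.end_seq}] matches no residues "
                f"of chain {protomer.chain_id}"
            )
        n_ca = sum(1 for r in span if r.ca is not None)
        if n_ca < 4:
            raise AnnotationError(
                f"TM{seg.tm_index} resolves to only {n_ca} Cα atoms (need >= 4 for axis fitting)"
            )
        if bw_anchors and seg.tm_index in bw_anchors:
            anchor = bw_anchors[seg.tm_index]
            for r in span:
                idx = 50 + (r.seq_id - anchor)
                if 0 <= idx <= 99:
                    by_seq[r.seq_id].bw = f"{seg.tm_index}.{idx:02d}"
    return replace(protomer, residues=residues, helices=list(segments))


def bw_lookup(protomer: Protomer, code: str) -> Residue:
    """Return the unique residue of ``protomer`` carrying BW code ``code``."""
    if not _BW_PATTERN.match(code):
        raise BWLookupError(f"malformed BW code {code!r}")
    hits = [r for r in protomer.residues if r.bw == code]
    if not hits:
        raise BWLookupError(
            f"chain {protomer.chain_id}: no residue annotated {code} "
            "(is the protomer annotated?)"
        )
    return hits[0]


def load_helix_config(path: str | Path) -> tuple[list[HelixSegment], dict[int, int]]:
    """Load helix/BW annotation from JSON: a list of
    ``{"tm_index": int, "start": int, "end": int, "bw_anchor_seq": int}``."""
    entries = json.loads(Path(path).read_text())
    segments = [HelixSegment(e["tm_index"], e["start"], e["end"]) for e in entries]
    anchors = {
        e["tm_index"]: e["bw_anchor_seq"] for e in entries if "bw_anchor_seq" in e
    }
    return segments, anchors
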