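"""Small assay and conservation computations.

* HTRF ratio — (acceptor emission at 670 nm / donor emission at 612 nm) × 10000.
* net BRET — raw BRET ratio minus background luminescence.
* ΔBRET — agonist-stimulated minus basal BRET.
* MSA column composition — residue frequencies at one alignment column
  (addressed by index or by a Ballesteros–Weinstein code through a reference
  sequence), with the fraction of aromatic residues; used to ask whether a
  position such as 5.34 is enriched in aromatics across a receptor family.
* Pairwise sequence identity — global (Needleman–Wunsch) alignment followed
  by percent identity over mutually aligned positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "PlateReading",
    "MsaColumnProfile",
    "IdentityResult",
    "htrf_ratio",
    "net_bret",
    "delta_bret",
    "read_fasta",
    "column_composition",
    "pairwise_identity",
]

AROMATIC = ("F", "W", "Y")
GAP_CHARS = {"-", "."}


@dataclass(frozen=True)
class PlateReading:
    """One HTRF well: acceptor emission at 670 nm and donor emission at 612 nm (RFU)."""

    a670: float
    d612: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a670) and np.isfinite(self.d612)):
            raise ValueError("plate readings must be finite")


def htrf_ratio(reading: PlateReading) -> float:
    """HTRF ratio = (A670 / D612) × 10000."""
    if reading.d612 <= 0:
        raise ValueError(f"donor emission must be positive, got {reading.d612}")
    return reading.a670 / reading.d612 * 10000.0


def net_bret(ratio, background):
    """Net BRET: raw ratio minus background luminescence (elementwise on arrays)."""
    return np.asarray(ratio) - np.asarray(background) if (
        isinstance(ratio, (list, tuple, np.ndarray))
        or isinstance(background, (list, tuple, np.ndarray))
    ) else ratio - background


def delta_bret(stimulated, basal):
    """ΔBRET: agonist-stimulated minus basal BRET (elementwise on arrays)."""
    return net_bret(stimulated, basal)


# ---------------------------------------------------------------------------
# MSA column composition


@dataclass(frozen=True)
class MsaColumnProfile:
    """Residue composition of one alignment column."""

    key: str
    frequencies: dict[str, float]  # over non-gap symbols, sums to 1
    gap_fraction: float
    aromatic_fraction: float
    n_sequences: int


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly aligned) FASTA file as (id, sequence) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def _resolve_column(
    msa: Sequence[tuple[str, str]],
    key: int | str,
    ref_id: str | None,
    bw_map: dict[str, int] | None,
) -> tuple[int, str]:
    if isinstance(key, int):
        return key, str(key)
    if ref_id is None or bw_map is None or key not in bw_map:
        raise ValueError(
            f"BW key {key!r} needs ref_id and a bw_map entry mapping it to an "
            "ungapped position of the reference sequence"
        )
    ref_seq = dict(msa).get(ref_id)
    if ref_seq is None:
        raise ValueError(f"reference sequence {ref_id!r} not in alignment")
    target = bw_map[key]  # 0-based ungapped index in the reference
    ungapped = -1
    for col, ch in enumerate(ref_seq):
        if ch not in GAP_CHARS:
            ungapped += 1
            if ungapped == target:
                return col, key
    raise ValueError(f"reference sequence has no ungapped position {target}")


def column_composition(
    msa: Sequence[tuple[str, str]] | str | Path,
    key: int | str,
    ref_id: str | None = None,
    bw_map: dict[str, int] | None = None,
    aromatic: Iterable[str] = AROMATIC,
    include_his: bool = False,
) -> MsaColumnProfile:
    """Composition of one MSA column.

    ``key`` is a 0-based column index, or a BW code resolved through
    ``ref_id`` plus ``bw_map`` (BW code → 0-based ungapped position in the
    reference sequence).  Frequencies are over non-gap symbols; gaps are
    tracked separately.  The aromatic set defaults to {F, W, Y}; histidine is
    added with ``include_his``.
    """
    if isinstance(msa, (str, Path)):
        msa = read_fasta(msa)
    if not msa:
        raise ValueError("empty alignment")
    lengths = {len(seq) for _, seq in msa}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    (length,) = lengths
    col, label = _resolve_column(msa, key, ref_id, bw_map)
    if not 0 <= col < length:
        raise ValueError(f"column {col} out of range for alignment of length {length}")
    symbols = [seq[col] for _, seq in msa]
    non_gap = [s for s in symbols if s not in GAP_CHARS]
    counts: dict[str, int] = {}
    for s in non_gap:
        counts[s] = counts.get(s, 0) + 1
    n = len(symbols)
    aromatic_set = set(aromatic) | ({"H"} if include_his else set())
    return MsaColumnProfile(
        key=label,
        frequencies={s: c / len(non_gap) for s, c in sorted(counts.items())} if non_gap else {},
        gap_fraction=(n - len(non_gap)) / n,
        aromatic_fraction=(
            sum(1 for s in non_gap if s in aromatic_set) / len(non_gap) if non_gap else 0.0
        ),
        n_sequences=n,
    )


# ---------------------------------------------------------------------------
# pairwise identity


@dataclass(frozen=True)
class IdentityResult:
    """Percent identity plus the alignment parameters that produced it."""

    percent: float
    n_identical: int
    n_aligned: int
    matrix: str = "BLOSUM62"
    open_gap: float = -11.0
    extend_gap: float = -1.0
    denominator: str = "aligned_pairs"


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    open_gap: float = -11.0,
    extend_gap: float = -1.0,
    denominator: str = "aligned_pairs",
) -> IdentityResult:
    """Global-alignment percent identity between two protein sequences.

    Identity = 100 × identical aligned pairs / denominator, where the
    denominator is either the number of mutually aligned (non-gap) positions
    (default) or the shorter sequence length (``denominator="shorter"``).
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    alignment = aligner.align(seq_a, seq_b)[0]
    n_identical = 0
    n_aligned = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            n_aligned += 1
            if seq_a[i] == seq_b[j]:
                n_identical += 1
    if denominator == "aligned_pairs":
        denom = n_aligned
    elif denominator == "shorter":
        denom = min(len(seq_a), len(seq_b))
    else:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    return IdentityResult(
        percent=100.0 * n_identical / denom if denom else 0.0,
        n_identical=n_identical,
        n_aligned=n_aligned,
        matrix=matrix,
        open_gap=open_gap,
        extend_gap=extend_gap,
        denominator=denominator,
    )
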