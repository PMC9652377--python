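"""Model triage for dimer ensembles.

A docking run produces thousands of candidate dimer models, each with an
interface energy and a (theta, d) interface geometry.  Triage proceeds in
four deterministic stages:

1. **Energy filter** — keep the lowest ``fraction`` (default 10%) of models
   by interface energy; exactly ``ceil(fraction·N)`` survive, ties broken by
   model id.
2. **Orientation filter** — among energy-kept models, keep those whose
   crossing angle lies within the membrane-embedding window
   [−50°, +85°] (inclusive).
3. **Clustering** — density-based hierarchical clustering (the HDBSCAN
   algorithm) on standardized (theta, d); low-density models are labeled
   noise (−1).  Clusters are relabeled 0, 1, ... by decreasing size so labels
   are stable under input shuffling.
4. **Representative selection** — drop clusters holding less than
   ``min_population`` (default 2%) of the kept models, then report each
   surviving cluster's lowest-energy member.

Population fractions use all filter-surviving models as denominator (noise
counts in the denominator, not as a cluster).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN

from .geometry import DimerGeometry, orientation_filter

__all__ = [
    "EnsembleRecord",
    "ClusterSummary",
    "TriageConfig",
    "EnsembleReport",
    "energy_filter",
    "apply_orientation_filter",
    "cluster_models",
    "select_representatives",
    "run_triage",
    "records_from_tsv",
    "records_to_frame",
]


@dataclass
class EnsembleRecord:
    """Bookkeeping row for one dimer model."""

    model_id: str
    geometry: DimerGeometry
    interface_energy: float | None = None
    kept_energy: bool = True
    kept_orientation: bool = True
    cluster: int = -1
    source: str = "synthetic"

    @property
    def theta(self) -> float:
        return self.geometry.theta

    @property
    def d(self) -> float:
        return self.geometry.d


@dataclass(frozen=True)
class ClusterSummary:
    label: int
    size: int
    population_fraction: float
    representative_model_id: str
    representative_energy: float
    centroid_theta: float
    centroid_d: float


@dataclass(frozen=True)
class TriageConfig:
    """Parameters of the full triage pipeline."""

    energy_fraction: float = 0.10
    theta_lo: float = -50.0
    theta_hi: float = 85.0
    min_cluster_size: int | None = None  # default: max(5, 1% of kept records)
    scale: str = "standardize"  # or "none"
    min_population: float = 0.02


@dataclass
class EnsembleReport:
    """Machine-readable result of run_triage."""

    records: list[EnsembleRecord]
    summaries: list[ClusterSummary]
    representatives: list[ClusterSummary]
    kept_fraction: float | None
    config: TriageConfig
    flags: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "config": asdict(self.config),
            "kept_fraction": self.kept_fraction,
            "flags": self.flags,
            "summaries": [asdict(s) for s in self.summaries],
            "representatives": [asdict(s) for s in self.representatives],
            "n_records": len(self.records),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def records_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def energy_filter(records: list[EnsembleRecord], fraction: float = 0.10) -> list[EnsembleRecord]:
    """Set ``kept_energy`` on exactly ceil(fraction·N) lowest-energy records.

    Ties at the threshold are broken by ascending model_id, so the outcome is
    deterministic and independent of input order.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if any(r.interface_energy is None for r in records):
        missing = [r.model_id for r in records if r.interface_energy is None][:5]
        raise ValueError(f"records missing interface energies, e.g. {missing}")
    n_keep = math.ceil(fraction * len(records))
    order = sorted(records, key=lambda r: (r.interface_energy, r.model_id))
    kept_ids = {r.model_id for r in order[:n_keep]}
    for r in records:
        r.kept_energy = r.model_id in kept_ids
    return records


def apply_orientation_filter(
    records: list[EnsembleRecord], lo: float = -50.0, hi: float = 85.0
) -> tuple[list[EnsembleRecord], float | None]:
    """Set ``kept_orientation`` and report the kept fraction among energy-kept records.

    Returns ``(records, kept_fraction)``; kept_fraction is None (with a
    warning) when no record passed the energy filter.
    """
    for r in records:
        r.kept_orientation = orientation_filter(r.theta, lo, hi)
    pool = [r for r in records if r.kept_energy]
    if not pool:
        warnings.warn("no energy-kept records: orientation kept_fraction undefined", stacklevel=2)
        return records, None
    kept_fraction = sum(1 for r in pool if r.kept_orientation) / len(pool)
    return records, kept_fraction


def _kept(records: Sequence[EnsembleRecord]) -> list[EnsembleRecord]:
    return [r for r in records if r.kept_energy and r.kept_orientation]


def _summarize(
    records: Sequence[EnsembleRecord], kept: Sequence[EnsembleRecord]
) -> list[ClusterSummary]:
    n_total = len(kept)
    summaries = []
    for label in sorted({r.cluster for r in kept if r.cluster >= 0}):
        members = [r for r in kept if r.cluster == label]
        rep = min(members, key=lambda r: (r.interface_energy
                                          if r.interface_energy is not None else np.inf,
                                          r.model_id))
        summaries.append(
            ClusterSummary(
                label=label,
                size=len(members),
                population_fraction=len(members) / n_total,
                representative_model_id=rep.model_id,
                representative_energy=(rep.interface_energy
                                       if rep.interface_energy is not None else np.nan),
                centroid_theta=float(np.mean([r.theta for r in members])),
                centroid_d=float(np.mean([r.d for r in members])),
            )
        )
    return summaries


def cluster_models(
    records: list[EnsembleRecord],
    min_cluster_size: int | None = None,
    scale: str = "standardize",
) -> tuple[list[EnsembleRecord], list[ClusterSummary]]:
    """Cluster filter-surviving records on (theta, d) with the HDBSCAN algorithm.

    Features are standardized by default (theta in degrees and d in Å are
    incommensurate).  Clusters are relabeled by decreasing size; noise is −1;
    records that failed a filter keep label −1.  With fewer points than the
    minimum cluster size a single-cluster fallback is used (with a warning).
    """
    kept = _kept(records)
    for r in records:
        r.cluster = -1
    if not kept:
        warnings.warn("no records survive both filters: nothing to cluster", stacklevel=2)
        return records, []
    if min_cluster_size is None:
        min_cluster_size = max(5, math.ceil(0.01 * len(kept)))
    X = np.asarray([[r.theta, r.d] for r in kept], dtype=float)
    if len(kept) < max(min_cluster_size, 2):
        warnings.warn(
            f"only {len(kept)} records for min_cluster_size={min_cluster_size}: "
            "single-cluster fallback", stacklevel=2,
        )
        for r in kept:
            r.cluster = 0
        return records, _summarize(records, kept)
    if scale == "standardize":
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    elif scale != "none":
        raise ValueError(f"unknown scale {scale!r}")
    labels = HDBSCAN(min_cluster_size=min_cluster_size, allow_single_cluster=True).fit_predict(X)
    # relabel by decreasing size (ties by mean theta) for order stability
    sizes: dict[int, int] = {}
    for lab in labels:
        if lab >= 0:
            sizes[lab] = sizes.get(lab, 0) + 1
    order = sorted(
        sizes,
        key=lambda lab: (-sizes[lab], float(np.mean(X[labels == lab, 0]))),
    )
    remap = {old: new for new, old in enumerate(order)}
    for r, lab in zip(kept, labels):
        r.cluster = remap.get(lab, -1)
    return records, _summarize(records, kept)


def select_representatives(
    records: Sequence[EnsembleRecord],
    summaries: Sequence[ClusterSummary],
    min_population: float = 0.02,
) -> list[ClusterSummary]:
    """Keep clusters holding at least ``min_population`` of the kept models;
    each survivor is represented by its lowest-energy member."""
    return [s for s in summaries if s.population_fraction >= min_population]


def run_triage(
    record_sets: Iterable[EnsembleRecord] | Iterable[Iterable[EnsembleRecord]],
    config: TriageConfig = TriageConfig(),
) -> EnsembleReport:
    """Run the full pipeline: energy filter → orientation filter → clustering
    → representative selection.

    Accepts one record list or several (e.g. docking runs started from
    different monomer models); multiple sets are pooled before triage.
    Deterministic: identical inputs give an identical report.
    """
    records_in = list(record_sets)
    if records_in and isinstance(records_in[0], EnsembleRecord):
        records = records_in  # single set
    else:
        records = [r for subset in records_in for r in subset]
    if not records:
        raise ValueError("no records supplied")
    flags: list[str] = []
    energy_filter(records, config.energy_fraction)
    _, kept_fraction = apply_orientation_filter(records, config.theta_lo, config.theta_hi)
    if not _kept(records):
        flags.append("no_models_pass_filters")
        return EnsembleReport(records, [], [], kept_fraction, config, flags)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        _, summaries = cluster_models(records, config.min_cluster_size, config.scale)
    flags.extend(
        str(w.message) for w in caught if issubclass(w.category, UserWarning)
        and not issubclass(w.category, FutureWarning)
    )
    representatives = select_representatives(records, summaries, config.min_population)
    if not representatives:
        flags.append("no_cluster_reaches_min_population")
    return EnsembleReport(records, summaries, representatives, kept_fraction, config, flags)


# ---------------------------------------------------------------------------
# tabular I/O


def records_from_tsv(path: str | Path) -> list[EnsembleRecord]:
    """Load records from TSV with columns model_id, theta, d, energy."""
    df = pd.read_csv(path, sep="\t")
    required = {"model_id", "theta", "d", "energy"}
    if not required.issubset(df.columns):
        raise ValueError(f"TSV must have columns {sorted(required)}, got {list(df.columns)}")
    return [
        EnsembleRecord(
            model_id=str(row.model_id),
            geometry=DimerGeometry(theta=float(row.theta), d=float(row.d),
                                   angle_tm5=float(row.theta)),
            interface_energy=float(row.energy),
            source=str(path),
        )
        for row in df.itertuples()
    ]


def records_to_frame(records: Sequence[EnsembleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "model_id": [r.model_id for r in records],
            "theta": [r.theta for r in records],
            "d": [r.d for r in records],
            "energy": [r.interface_energy for r in records],
            "kept_energy": [r.kept_energy for r in records],
            "kept_orientation": [r.kept_orientation for r in records],
            "cluster": [r.cluster for r in records],
        }
    )
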