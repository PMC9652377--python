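"""Interface-energy bookkeeping, design triage, and dimerization propensity.

The ledger stores, for each (variant, conformation, signaling state), the
dimer and monomer energies in Rosetta Energy Units (REU) and the derived
interface energy

    E_interface = E_dimer − 2·E_monomer,

the association-strength proxy (more negative = stronger dimer).

Design triage compares a variant to WT:

    ΔE_interface = E_interface(design) − E_interface(WT)
    ΔE_monomer   = E_monomer(design)  − E_monomer(WT)

and discards mutations whose interface effect is minimal
(|ΔE_interface| < 1.0 REU) or whose monomer perturbation is significant
(|ΔE_monomer| > 1.0 REU): a useful interface design must rewire the dimer
contact without touching the protomer's own fold.

Dimerization propensity converts interface-energy differences into
Boltzmann factors.  The reference state is the WT receptor's lowest-energy
primary dimer conformation — the open dimer — within the same signaling
state:

    ΔΔE(X, Y, s) = E_interface(X, Y, s) − E_interface(WT, open, s)
    PD(X, Y, s)  = exp(−0.5·ΔΔE / RT),   RT = 0.593 kcal/mol

where the 0.5 factor roughly converts REU to kcal/mol.  PD_open + PD_closed
summed per variant and state indicates whether a variant occupies the dimer
state more or less readily than WT.  These are apparent propensities
relative to WT, not free energies: docking enthalpies neglect conformational
and configurational entropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONFORMATIONS",
    "STATES",
    "RT_KCAL_PER_MOL",
    "REU_TO_KCAL",
    "LedgerEntry",
    "EnergyLedger",
    "DesignVerdict",
    "PropensityResult",
    "interface_energy",
    "delta_interface",
    "design_accept",
    "delta_delta",
    "boltzmann_propensity",
    "propensity_table",
    "propensity_frame",
]

CONFORMATIONS = ("open", "closed")
STATES = ("inactive", "active")

RT_KCAL_PER_MOL = 0.593  #: thermal scaling factor, kcal/mol
REU_TO_KCAL = 0.5  #: rough REU → kcal/mol conversion factor

_EXP_CLIP = 700.0  # exp argument guard


def interface_energy(e_dimer: float, e_monomer: float) -> float:
    """Interface energy of a homodimer: E_dimer − 2·E_monomer (REU)."""
    if not (np.isfinite(e_dimer) and np.isfinite(e_monomer)):
        raise ValueError("energies must be finite")
    return e_dimer - 2.0 * e_monomer


def delta_interface(design_e_interface: float, wt_e_interface: float) -> float:
    """ΔE_interface = design − WT; negative means the design stabilizes the interface."""
    return design_e_interface - wt_e_interface


@dataclass(frozen=True)
class LedgerEntry:
    variant: str
    conformation: str
    state: str
    e_dimer: float | None = None
    e_monomer: float | None = None
    e_interface: float | None = None


class EnergyLedger:
    """Energies indexed by (variant, conformation ∈ {open, closed}, state ∈ {inactive, active})."""

    def __init__(
        self,
        entries: Iterable[LedgerEntry],
        reference_variant: str = "WT",
        reference_conformation: str = "open",
        tol: float = 1e-6,
    ) -> None:
        self.reference_variant = reference_variant
        self.reference_conformation = reference_conformation
        self._entries: dict[tuple[str, str, str], LedgerEntry] = {}
        for e in entries:
            if e.conformation not in CONFORMATIONS:
                raise ValueError(f"conformation must be one of {CONFORMATIONS}: {e.conformation!r}")
            if e.state not in STATES:
                raise ValueError(f"state must be one of {STATES}: {e.state!r}")
            e_int = e.e_interface
            if e.e_dimer is not None and e.e_monomer is not None:
                derived = interface_energy(e.e_dimer, e.e_monomer)
                if e_int is not None and abs(e_int - derived) > tol:
                    raise ValueError(
                        f"{(e.variant, e.conformation, e.state)}: stored E_interface "
                        f"{e_int} inconsistent with E_dimer − 2·E_monomer = {derived}"
                    )
                e_int = derived
            if e_int is None:
                raise ValueError(
                    f"{(e.variant, e.conformation, e.state)}: need E_interface or "
                    "both E_dimer and E_monomer"
                )
            key = (e.variant, e.conformation, e.state)
            if key in self._entries:
                raise ValueError(f"duplicate ledger entry {key}")
            self._entries[key] = LedgerEntry(
                e.variant, e.conformation, e.state, e.e_dimer, e.e_monomer, e_int
            )

    # -- access ------------------------------------------------------------

    def __contains__(self, key: tuple[str, str, str]) -> bool:
        return key in self._entries

    def entry(self, variant: str, conformation: str, state: str) -> LedgerEntry:
        key = (variant, conformation, state)
        if key not in self._entries:
            raise KeyError(f"ledger has no entry {key}")
        return self._entries[key]

    def e_interface(self, variant: str, conformation: str, state: str) -> float:
        return self.entry(variant, conformation, state).e_interface  # type: ignore[return-value]

    @property
    def variants(self) -> list[str]:
        seen: list[str] = []
        for v, _, _ in self._entries:
            if v not in seen:
                seen.append(v)
        return seen

    @property
    def states(self) -> list[str]:
        return [s for s in STATES if any(k[2] == s for k in self._entries)]

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "EnergyLedger":
        cols = set(df.columns)
        entries = []
        for row in df.itertuples():
            entries.append(
                LedgerEntry(
                    variant=str(row.variant),
                    conformation=str(row.conformation),
                    state=str(row.state),
                    e_dimer=float(row.E_dimer) if "E_dimer" in cols else None,
                    e_monomer=float(row.E_monomer) if "E_monomer" in cols else None,
                    e_interface=float(row.E_interface) if "E_interface" in cols else None,
                )
            )
        return cls(entries, **kwargs)

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "EnergyLedger":
        """Read a ledger from TSV/CSV with columns
        (variant, conformation, state, E_dimer, E_monomer) or (..., E_interface)."""
        sep = "," if str(path).endswith(".csv") else "\t"
        return cls.from_frame(pd.read_csv(path, sep=sep), **kwargs)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self._entries.values(),
                      key=lambda e: (e.variant, e.state, e.conformation))
        return pd.DataFrame(
            {
                "variant": [e.variant for e in rows],
                "conformation": [e.conformation for e in rows],
                "state": [e.state for e in rows],
                "E_dimer": [e.e_dimer for e in rows],
                "E_monomer": [e.e_monomer for e in rows],
                "E_interface": [e.e_interface for e in rows],
            }
        )


# ---------------------------------------------------------------------------
# design triage


@dataclass(frozen=True)
class DesignVerdict:
    variant: str
    delta_e_interface: float
    delta_e_monomer: float
    verdict: str  # accepted | discarded_interface | discarded_monomer


def design_accept(
    de_interface: float,
    de_monomer: float,
    t_int: float = 1.0,
    t_mono: float = 1.0,
    variant: str = "",
) -> DesignVerdict:
    """Triage one designed mutation.

    Discarded when the interface effect is minimal (|ΔE_interface| < t_int)
    or the monomer is significantly perturbed (|ΔE_monomer| > t_mono); the
    monomer violation takes reporting priority when both fail.
    """
    if t_int <= 0 or t_mono <= 0:
        raise ValueError("thresholds must be positive")
    if abs(de_monomer) > t_mono:
        verdict = "discarded_monomer"
    elif abs(de_interface) < t_int:
        verdict = "discarded_interface"
    else:
        verdict = "accepted"
    return DesignVerdict(variant, de_interface, de_monomer, verdict)


# ---------------------------------------------------------------------------
# propensity


def delta_delta(
    ledger: EnergyLedger,
    variant: str,
    conformation: str,
    state: str,
    global_reference: bool = False,
) -> float:
    """ΔΔE: interface energy of (variant, conformation) minus the WT-open reference (REU).

    The reference is WT-open in the *same* signaling state, so each state's
    table is internally referenced; with ``global_reference`` a single
    WT-open-inactive reference is used for all states.
    """
    ref_state = STATES[0] if global_reference else state
    try:
        ref = ledger.e_interface(ledger.reference_variant,
                                 ledger.reference_conformation, ref_state)
    except KeyError as exc:
        raise KeyError(
            f"ledger lacks the reference entry "
            f"({ledger.reference_variant}, {ledger.reference_conformation}, {ref_state})"
        ) from exc
    return ledger.e_interface(variant, conformation, state) - ref


def boltzmann_propensity(
    dd: float, rt: float = RT_KCAL_PER_MOL, conv: float = REU_TO_KCAL
) -> float:
    """Boltzmann dimerization propensity exp(−conv·ΔΔE / RT), unitless, relative to WT-open."""
    if rt <= 0:
        raise ValueError("rt must be positive")
    arg = -conv * dd / rt
    if abs(arg) > _EXP_CLIP:
        warnings.warn(f"propensity exponent {arg:.3g} clipped to ±{_EXP_CLIP}", stacklevel=2)
        arg = float(np.clip(arg, -_EXP_CLIP, _EXP_CLIP))
    return float(np.exp(arg))


@dataclass(frozen=True)
class PropensityResult:
    variant: str
    state: str
    dd_open: float
    dd_closed: float
    pd_open: float
    pd_closed: float
    pd_total: float
    open_fraction: float
    exceeds_wt: bool | None  # pd_total above the WT pd_total of the same state


def propensity_table(
    ledger: EnergyLedger,
    variants: Sequence[str] | None = None,
    states: Sequence[str] | None = None,
    global_reference: bool = False,
    rt: float = RT_KCAL_PER_MOL,
    conv: float = REU_TO_KCAL,
) -> list[PropensityResult]:
    """Per-variant, per-state open/closed propensities and their sum.

    Variants with incomplete entries are skipped with a warning.  The result
    order is (variant, state) sorted with WT first; it does not depend on
    ledger row order.
    """
    variants = list(variants) if variants is not None else ledger.variants
    states = list(states) if states is not None else ledger.states
    # WT first, rest alphabetical, for a stable readable table
    ref = ledger.reference_variant
    variants = sorted(variants, key=lambda v: (v != ref, v))
    results: list[PropensityResult] = []
    wt_totals: dict[str, float] = {}
    for variant in variants:
        for state in states:
            try:
                dd_open = delta_delta(ledger, variant, "open", state, global_reference)
                dd_closed = delta_delta(ledger, variant, "closed", state, global_reference)
            except KeyError:
                warnings.warn(
                    f"incomplete ledger for ({variant}, {state}): skipped", stacklevel=2
                )
                continue
            pd_open = boltzmann_propensity(dd_open, rt, conv)
            pd_closed = boltzmann_propensity(dd_closed, rt, conv)
            pd_total = pd_open + pd_closed
            if variant == ref:
                wt_totals[state] = pd_total
                exceeds = None
            elif state in wt_totals:
                exceeds = pd_total > wt_totals[state]
            else:
                exceeds = None
            results.append(
                PropensityResult(
                    variant=variant,
                    state=state,
                    dd_open=dd_open,
                    dd_closed=dd_closed,
                    pd_open=pd_open,
                    pd_closed=pd_closed,
                    pd_total=pd_total,
                    open_fraction=pd_open / pd_total,
                    exceeds_wt=exceeds,
                )
            )
    return results


def propensity_frame(results: Sequence[PropensityResult]) -> pd.DataFrame:
    """Propensity results as a DataFrame (for TSV/JSON export)."""
    return pd.DataFrame([r.__dict__ for r in results])
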