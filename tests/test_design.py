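"""Energy ledger arithmetic, design triage, and Boltzmann propensities."""

import numpy as np
import pytest

from quests import (
    EnergyLedger,
    LedgerEntry,
    boltzmann_propensity,
    delta_delta,
    delta_interface,
    design_accept,
    interface_energy,
    propensity_table,
)
from quests.fixtures import LedgerSpec, make_energy_ledger, preset_ledger_spec


def ledger_from_interfaces(values, monomer=-300.0):
    """Build a ledger from {(variant, conf, state): E_interface}."""
    return EnergyLedger(
        [
            LedgerEntry(v, c, s, e_dimer=2 * monomer + e_int, e_monomer=monomer)
            for (v, c, s), e_int in values.items()
        ]
    )


class TestInterfaceEnergy:
    @pytest.mark.parametrize("ed,em,expected", [(-100.0, -45.0, -10.0), (0.0, 0.0, 0.0)])
    def test_dimer_minus_twice_monomer(self, ed, em, expected):
        assert interface_energy(ed, em) == expected

    def test_random_rows_match_independent_recomputation(self):
        rng = np.random.default_rng(14)
        for _ in range(50):
            ed, em = rng.normal(size=2) * 100
            assert interface_energy(ed, em) == pytest.approx(ed - 2 * em, abs=1e-12)

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            interface_energy(np.inf, 0.0)

    def test_ledger_rejects_inconsistent_stored_interface(self):
        with pytest.raises(ValueError, match="inconsistent"):
            EnergyLedger(
                [LedgerEntry("WT", "open", "inactive",
                             e_dimer=-100.0, e_monomer=-45.0, e_interface=-99.0)]
            )


class TestDesignTriage:
    def test_delta_interface_sign_convention(self):
        # a design that stabilizes the interface by 2.4 REU maps to −2.4
        assert delta_interface(-12.4, -10.0) == pytest.approx(-2.4)
        assert delta_interface(-10.0, -10.0) == 0.0

    @pytest.mark.parametrize(
        "de_int,de_mono,verdict",
        [
            (-2.4, 0.3, "accepted"),
            (-0.5, 0.0, "discarded_interface"),
            (-3.0, 1.5, "discarded_monomer"),
            (0.5, 2.0, "discarded_monomer"),  # monomer violation has priority
            (1.0, 0.0, "accepted"),           # |ΔE_int| = threshold is not "< 1.0"
        ],
    )
    def test_accept_discard_rules(self, de_int, de_mono, verdict):
        assert design_accept(de_int, de_mono).verdict == verdict

    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            design_accept(0.0, 0.0, t_int=0.0)


class TestDeltaDelta:
    def test_wt_open_is_zero_in_every_state(self):
        ledger = make_energy_ledger(preset_ledger_spec("wt-like"))
        for state in ("inactive", "active"):
            assert delta_delta(ledger, "WT", "open", state) == 0.0

    def test_planted_closed_offset_recovered(self):
        ledger = ledger_from_interfaces(
            {
                ("WT", "open", "inactive"): -12.0,
                ("WT", "closed", "inactive"): -10.8,
            }
        )
        assert delta_delta(ledger, "WT", "closed", "inactive") == pytest.approx(1.2)

    def test_missing_wt_reference_raises(self):
        ledger = ledger_from_interfaces({("MUT", "open", "inactive"): -12.0})
        with pytest.raises(KeyError, match="reference"):
            delta_delta(ledger, "MUT", "open", "inactive")

    def test_global_reference_uses_inactive_wt_open(self):
        ledger = ledger_from_interfaces(
            {
                ("WT", "open", "inactive"): -12.0,
                ("WT", "open", "active"): -14.0,
            }
        )
        assert delta_delta(ledger, "WT", "open", "active") == 0.0
        assert delta_delta(ledger, "WT", "open", "active",
                           global_reference=True) == pytest.approx(-2.0)


class TestBoltzmannPropensity:
    def test_zero_difference_gives_exactly_one(self):
        assert boltzmann_propensity(0.0) == 1.0

    def test_known_stabilization_value(self):
        # ΔΔE = −2.4 REU → exp(0.5·2.4/0.593) = exp(1.2/0.593)
        assert boltzmann_propensity(-2.4) == pytest.approx(np.exp(1.2 / 0.593), rel=1e-12)

    def test_reciprocal_symmetry(self):
        for dd in np.linspace(-8, 8, 33):
            assert boltzmann_propensity(dd) * boltzmann_propensity(-dd) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_strictly_decreasing(self):
        grid = np.linspace(-10, 10, 101)
        values = [boltzmann_propensity(d) for d in grid]
        assert all(b < a for a, b in zip(values, values[1:]))

    def test_overflow_guarded(self):
        with pytest.warns(UserWarning, match="clipped"):
            assert np.isfinite(boltzmann_propensity(1e6))


class TestGaugeInvariance:
    def test_monomer_shift_leaves_delta_delta_unchanged(self):
        base = {
            ("WT", "open", "inactive"): (-612.0, -300.0),
            ("WT", "closed", "inactive"): (-609.0, -300.0),
            ("MUT", "open", "inactive"): (-614.4, -300.0),
            ("MUT", "closed", "inactive"): (-608.0, -300.0),
        }
        c = 17.3  # constant added to every monomer energy of the state
        plain = EnergyLedger(
            [LedgerEntry(v, conf, s, e_dimer=ed, e_monomer=em)
             for (v, conf, s), (ed, em) in base.items()]
        )
        shifted = EnergyLedger(
            [LedgerEntry(v, conf, s, e_dimer=ed, e_monomer=em + c)
             for (v, conf, s), (ed, em) in base.items()]
        )
        for (v, conf, s) in base:
            # every interface energy shifts by −2c ...
            assert shifted.e_interface(v, conf, s) == pytest.approx(
                plain.e_interface(v, conf, s) - 2 * c, abs=1e-9
            )
            # ... and ΔΔE (hence the propensity) is untouched
            assert delta_delta(shifted, v, conf, s) == pytest.approx(
                delta_delta(plain, v, conf, s), abs=1e-9
            )


class TestPropensityTable:
    def test_wt_open_reference_arithmetic(self):
        ledger = make_energy_ledger(preset_ledger_spec("wt-like"))
        results = {(r.variant, r.state): r for r in propensity_table(ledger)}
        for state in ("inactive", "active"):
            r = results[("WT", state)]
            assert r.pd_open == 1.0
            assert r.pd_total == pytest.approx(1.0 + r.pd_closed)
            assert r.pd_total > 1.0

    def test_wt_closed_form_stabilized_in_active_state(self):
        ledger = make_energy_ledger(preset_ledger_spec("wt-like"))
        results = {(r.variant, r.state): r for r in propensity_table(ledger)}
        assert results[("WT", "active")].dd_closed < results[("WT", "inactive")].dd_closed
        assert results[("WT", "inactive")].open_fraction > 0.5
        assert results[("WT", "active")].open_fraction > 0.5

    def test_closed_switch_variant_flips_majority_in_active_state(self):
        ledger = make_energy_ledger(preset_ledger_spec("closed-switch"))
        results = {(r.variant, r.state): r for r in propensity_table(ledger)}
        assert results[("W195L-like", "inactive")].open_fraction > 0.5
        assert results[("W195L-like", "active")].open_fraction < 0.5

    def test_open_stabilizing_variant_raises_propensity(self):
        ledger = make_energy_ledger(preset_ledger_spec("open-stabilizing"))
        results = {(r.variant, r.state): r for r in propensity_table(ledger)}
        assert results[("L194R-like", "inactive")].dd_open == pytest.approx(-2.4)
        assert results[("L194R-like", "inactive")].exceeds_wt is True

    def test_zero_offset_variant_matches_wt(self):
        spec = LedgerSpec(
            wt_interface={("open", "inactive"): -12.0, ("closed", "inactive"): -9.0},
            offsets={"NULL": {}},
        )
        results = {(r.variant, r.state): r for r in propensity_table(make_energy_ledger(spec))}
        wt, null = results[("WT", "inactive")], results[("NULL", "inactive")]
        assert (null.pd_open, null.pd_closed) == (wt.pd_open, wt.pd_closed)
        assert null.exceeds_wt is False  # equal, not strictly greater

    def test_row_order_permutation_invariant(self):
        spec = preset_ledger_spec("open-stabilizing", "closed-switch")
        frame = make_energy_ledger(spec).to_frame()
        shuffled = frame.sample(frac=1.0, random_state=5)
        a = propensity_table(EnergyLedger.from_frame(frame))
        b = propensity_table(EnergyLedger.from_frame(shuffled))
        assert a == b

    def test_incomplete_variant_skipped_with_warning(self):
        ledger = ledger_from_interfaces(
            {
                ("WT", "open", "inactive"): -12.0,
                ("WT", "closed", "inactive"): -9.0,
                ("MUT", "open", "inactive"): -13.0,  # closed entry missing
            }
        )
        with pytest.warns(UserWarning, match="skipped"):
            results = propensity_table(ledger)
        assert {r.variant for r in results} == {"WT"}


def test_ledger_tsv_round_trip(tmp_path):
    ledger = make_energy_ledger(preset_ledger_spec("open-stabilizing"))
    path = tmp_path / "ledger.tsv"
    ledger.to_frame().to_csv(path, sep="\t", index=False)
    reread = EnergyLedger.from_tsv(path)
    assert propensity_table(reread) == propensity_table(ledger)
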