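"""Design triage and Boltzmann dimerization propensities.

Builds the preset mock energy ledger — WT plus an open-stabilizing variant
(L194R-like, interface −2.4 REU) and a closed-switch variant (W195L-like) —
screens the designs against the |dE_interface| >= 1.0 / |dE_monomer| <= 1.0
REU rules, and converts interface-energy differences into per-conformation
propensities with exp(−0.5·ddE/RT), RT = 0.593 kcal/mol.
"""

from quests import delta_interface, design_accept, propensity_table
from quests.fixtures import make_energy_ledger, preset_ledger_spec

ledger = make_energy_ledger(
    preset_ledger_spec("wt-like", "open-stabilizing", "closed-switch")
)

print("design screen (open conformation, inactive state):")
wt = ledger.e_interface("WT", "open", "inactive")
for variant in ledger.variants:
    if variant == "WT":
        continue
    de = delta_interface(ledger.e_interface(variant, "open", "inactive"), wt)
    verdict = design_accept(de, 0.0, variant=variant)
    print(f"  {variant:12s} dE_interface = {de:+5.1f} REU -> {verdict.verdict}")

print("\npropensity table (PD relative to WT-open of the same state):")
print(f"{'variant':12s} {'state':9s} {'PD_open':>8s} {'PD_closed':>10s} "
      f"{'PD_total':>9s} {'open_frac':>10s}")
for r in propensity_table(ledger):
    print(f"{r.variant:12s} {r.state:9s} {r.pd_open:8.3f} {r.pd_closed:10.3f} "
          f"{r.pd_total:9.3f} {r.open_fraction:10.3f}")
# the closed-switch variant keeps an open majority while inactive
# (open_frac > 0.5) but flips to a closed majority in the active state
# (open_frac < 0.5) - the signature of an activation-coupled quaternary switch
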