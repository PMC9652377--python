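"""Triage a docking ensemble down to representative dimer conformations.

Generates a synthetic stand-in for a symmetric-docking run: 2,000 dimer
models drawn from two conformations — an open-like state (52°, 12 Å, 70%
weight, lower interface energy) and a closed-like state (−15°, 16 Å, 30%) —
with 20% of models planted outside the membrane-embedding window.  The
pipeline filters by energy and orientation, clusters on (theta, d), and
reports each surviving cluster's lowest-energy member.
"""

from quests import TriageConfig, run_triage
from quests.fixtures import ClusterSpec, EnsembleSpec, make_dimer_ensemble

spec = EnsembleSpec(
    clusters=[
        ClusterSpec(0.7, 52.0, 3.0, 12.0, 0.5, -30.0, 2.0, "open"),
        ClusterSpec(0.3, -15.0, 3.0, 16.0, 0.5, -27.0, 2.0, "closed"),
    ],
    n_models=2000,
    seed=1,
    outside_filter_fraction=0.20,
)
records, _ = make_dimer_ensemble(spec)

report = run_triage(records, TriageConfig(energy_fraction=0.5))
print(f"orientation filter kept {report.kept_fraction:.1%} of energy-kept models")
for s in report.representatives:
    print(
        f"cluster {s.label}: {s.population_fraction:6.1%} of kept models, "
        f"centroid theta {s.centroid_theta:7.1f} deg, d {s.centroid_d:5.1f} A, "
        f"representative {s.representative_model_id} "
        f"(energy {s.representative_energy:.2f})"
    )
# two clusters should emerge near the planted (52, 12) and (-15, 16)
# conformations, the open-like one more populated; each representative is
# that cluster's energy minimum
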