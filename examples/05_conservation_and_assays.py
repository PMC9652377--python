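"""Conservation of an interface hotspot, and plate-assay arithmetic.

A toy alignment of receptor TM5 tips shows how to ask whether a position
(here addressed by its generic number 5.34) is enriched in aromatic
residues across a family; the assay helpers reproduce the HTRF ratio and
the net/delta BRET transformations.
"""

from quests import PlateReading, column_composition, delta_bret, htrf_ratio, net_bret, pairwise_identity

# four family members aligned over a 7-residue TM5 tip; the first sequence
# is the reference whose position 4 (0-based, ungapped) carries code 5.34
msa = [
    ("recA", "GLKWISI"),
    ("recB", "GMRWVTV"),
    ("recC", "AL-WLSI"),
    ("recD", "GIKLISV"),
]
profile = column_composition(msa, "5.34", ref_id="recA", bw_map={"5.34": 3})
print(f"column 5.34 composition: {profile.frequencies}")
print(f"aromatic fraction at 5.34: {profile.aromatic_fraction:.2f}")

identity = pairwise_identity("GLKWISI", "GMRWVTV")
print(f"recA vs recB identity: {identity.percent:.0f}% "
      f"({identity.n_identical}/{identity.n_aligned} aligned positions)")

ratio = htrf_ratio(PlateReading(a670=531.0, d612=612.0))
print(f"HTRF ratio (A670/D612 x 10000): {ratio:.0f}")
print(f"net BRET 0.25 over background 0.10: {net_bret(0.25, 0.10):.2f}")
print(f"delta BRET stimulated 0.30 vs basal 0.25: {delta_bret(0.30, 0.25):.2f}")
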