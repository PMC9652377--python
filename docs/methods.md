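# Methods

## What the package models

A multi-pass membrane receptor homodimer is reduced to the relative
placement of its two protomers across the dominant interface helix, TM5.
Two coordinates summarize one dimer model:

* **θ** — the signed crossing angle between the two TM5 axes (degrees);
* **d** — the distance between the two TM5 Cα centroids (Å).

These two numbers are the clustering features of the triage pipeline and
the axes of the conformational landscape (open vs closed dimer). Both the
helix index and the feature pair are parameters; TM5 is the default because
it dominates the chemokine-receptor dimer interface.

### Helix axes

A helix axis is the total-least-squares principal line of its ordered Cα
coordinates: the leading right-singular vector of the centered coordinate
matrix, sign-fixed N→C, with `fit_rms` the RMS perpendicular residual
(≈ the 2.3 Å Cα radius for an ideal helix). For a finite ideal helix this
estimator is *not* exactly the helical axis — the centered sine cross-terms
do not cancel, tilting the fit by ≈1.2° at 19 residues and ≈0.3° at 37,
decaying roughly as 1/n. This bias is far below the tolerances at which
crossing angles are interpreted (±3°) and cancels entirely in the synthetic
dimers, where protomer B is a rigid copy of protomer A (relative angles are
exact). Tests assert the honest bounds, not an idealized zero.

### Sign convention

The unsigned crossing angle is arccos(a·b) ∈ [0°, 180°]; its sign is that
of (a×b)·u with u the unit vector from the first to the second helix
centroid. This convention is *swap-invariant*: both the cross product and u
flip when the protomers are exchanged, so the handedness of the crossing is
a property of the dimer, not of chain order — the correct behavior for a
homodimer descriptor. A membrane-embedding window stated as a signed
interval ([−50°, +85°]) implies some sign convention without fixing it;
this one is deterministic and can be flipped (`--flip-sign` in the CLI) to
match a mirrored convention. When the two centroids coincide the sign is
undefined and the unsigned angle is returned with a warning.

### The membrane-orientation filter

A dimer is compatible with both protomers spanning one bilayer when
−50° ≤ θ ≤ +85°, bounds inclusive. The crystallographic CXCR4 dimer
crossing angle (≈52°) sits inside the window.

## Triage pipeline

1. **Energy filter.** Keep exactly ⌈fraction·N⌉ lowest-interface-energy
   models (default fraction 0.10). Ceiling was chosen over floor/round so a
   nonempty selection is guaranteed for any N ≥ 1; ties at the threshold
   break by ascending model id, making the stage order-independent.
2. **Orientation filter.** Apply the membrane window to the energy-kept
   models; the kept fraction is reported (≈0.8 under the default synthetic
   conditions, which plant 20% of models outside the window).
3. **Clustering.** Density-based hierarchical clustering (HDBSCAN, via
   scikit-learn) on (θ, d) of the surviving models. Features are
   standardized by default because degrees and Å are incommensurate;
   `min_cluster_size` defaults to max(5, 1% of kept models). The root
   cluster is selectable (`allow_single_cluster`), so a unimodal ensemble
   yields one cluster rather than fragments; note that a finite-spread
   unimodal Gaussian still sheds its low-density tails (roughly 40% of
   points) as noise under excess-of-mass selection — noise on unstructured
   data is intended behavior for a density method, not an error. Cluster
   labels are relabeled 0, 1, … by decreasing size so the output is stable
   under input permutation; noise is −1. With fewer points than the minimum
   cluster size a single-cluster fallback is used with a warning.
4. **Representatives.** Clusters below `min_population` (default 0.02) of
   the kept models are dropped; population denominators include noise
   points (population = cluster size / all filter-surviving models). Each
   surviving cluster is represented by its lowest-energy member (ties by
   model id).

`run_triage` chains the four stages, pools multiple input sets (e.g.
docking runs started from different monomer models) before clustering, and
emits a machine-readable report; identical inputs give byte-identical
reports.

## Interface scoring

**SASA** uses Shrake–Rupley sampling: each atom sphere is inflated by the
probe radius (1.4 Å) and sampled with a fixed 960-point golden-spiral
lattice; a point is buried when it lies inside a neighbor's inflated
sphere. Default radii: C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 Å —
a standard per-element table, fully overridable per element or atom name.
The deterministic lattice makes areas bit-reproducible; 960 points put the
single-sphere quadrature error well under 1%. Degenerate geometry rule: a
sphere entirely contained in another is fully buried, and of two exactly
coincident equal spheres the later atom is the buried one, so duplicated
atoms never double-count area.

**ΔSASA** = SASA(A) + SASA(B) − SASA(A·B) is non-negative, vanishes for
separated protomers, and grows monotonically on approach; ranking an
ensemble of variants by ΔSASA orders them by predicted burial.

**Clash counting** flags atom pairs with van der Waals overlap
r_i + r_j − d_ij ≥ 0.6 Å (inclusive), the convention of standard
structure-assessment tools; the cutoff is a parameter. Pairs can be
excluded explicitly (e.g. bonded neighbors when the two selections share a
chain); by default no pairs are excluded because the intended use —
receptor dimer vs docked effector — involves no shared covalent structure.

**Contact score** is a smooth Gaussian well of unit depth centered at van
der Waals contact for each inter-protomer pair within 5.5 Å, plus a −0.5
bonus for N/O–N/O pairs within 3.5 Å. It is a deliberately simple surrogate
for a physical interface energy — reported in arbitrary units, never REU —
whose only job is to give the pipeline a deterministic, monotone stand-in
so energy-dependent stages can be exercised end to end.

## Energy bookkeeping and propensities

The ledger stores E_dimer and E_monomer (Rosetta Energy Units) per
(variant, conformation ∈ {open, closed}, state ∈ {inactive, active}) and
derives E_interface = E_dimer − 2·E_monomer; more negative = stronger
association. Stored interface energies inconsistent with that identity are
rejected at load. Gauge invariance holds by construction: adding a constant
to every monomer energy of a state shifts all interface energies by −2c
and leaves every ΔΔE (hence every propensity) unchanged.

**Design triage.** A designed mutation must move the interface
(|ΔE_interface| ≥ 1.0 REU) without perturbing the monomer fold
(|ΔE_monomer| ≤ 1.0 REU). Thresholds are read as absolute values (a
documented choice; one-sided variants are configurable), and when both
rules fail the monomer violation is reported, since a destabilized monomer
invalidates the interface comparison.

**Propensity.** The reference state is the WT open dimer *of the same
signaling state*: ΔΔE(X, Y, s) = E_interface(X, Y, s) − E_interface(WT,
open, s), so the inactive and active tables are each internally referenced
and per-state open/closed distributions are directly comparable to WT. A
`global_reference` flag switches to a single WT-open-inactive reference.
PD = exp(−0.5·ΔΔE/RT) with RT = 0.593 kcal/mol and 0.5 the rough REU →
kcal/mol conversion; both are configuration constants. PD_open + PD_closed
per variant/state indicates whether a variant occupies the dimer state more
or less readily than WT. These are *apparent propensities relative to WT*,
not free energies: docking enthalpies neglect conformational and
configurational entropy, and the package labels the outputs accordingly.
The exponent is clipped at ±700 (with a warning) to avoid overflow on
pathological inputs.

## Synthetic data: what it emulates, what it does not

The fixtures module defines the study conditions for every test and for
the acceptance script.

* **Ideal helices** use canonical α-helix geometry: 1.5 Å rise, 100° twist,
  2.3 Å Cα radius. Toy protomers carry one Cα pseudo-atom per residue so
  SASA/clash oracles stay closed-form.
* **Planted dimers** place protomer B as a rigid copy of protomer A rotated
  by θ about the centroid-separation direction and translated d along it,
  after aligning A's fitted axis to +z — so the recovered (θ, d) equals the
  planted value to 1e-6 by construction.
* **Planted ensembles** mix Gaussian (θ, d, energy) clusters; the default
  two-conformation condition uses an open-like component (52°, 12 Å, 70%
  weight, mean energy −30) and a closed-like component (−15°, 16 Å, 30%,
  −27), sd 3° / 0.5 Å / 2 energy units — separations ≥ 5 sd so planted
  labels are essentially unambiguous. An exact count
  round(outside_fraction·n) of models is resampled outside the membrane
  window, making filter statistics exact rather than merely expected
  (out-of-window fraction 0.20 → kept fraction 0.80 exactly).
* **Mock ledgers** set the WT interface energies to −12.0 (open) and −9.0
  (closed) REU in the inactive state and −12.0 / −11.5 in the active state:
  the open dimer is primary in both states and the closed form is
  stabilized by 2.5 REU upon activation. Preset variants: *open-stabilizing*
  (L194R-like; open interface −2.4 REU, the magnitude of a strong designed
  polar contact) and *closed-switch* (W195L-like; open +1.5 / closed −1.0
  inactive, open +0.5 / closed −3.5 active), chosen so the variant forms a
  weaker dimer than WT while inactive yet flips to a dominant closed dimer
  when active. Monomer energy defaults to −300 REU for all entries.

Passing tests on these fixtures demonstrate that the decision layer —
filters, clustering, bookkeeping, propensity arithmetic — behaves exactly
as specified on inputs with known ground truth. They do not demonstrate
that any particular sampling engine produces ensembles of this shape, nor
that surrogate contact scores track physical interface energies; judgments
about real receptors additionally require real coordinate ensembles and
energy tables.

All generators require an explicit seed; there is no hidden global RNG, and
identical (spec, seed) pairs are bit-reproducible.

## Numerical and degenerate-input choices

* Orientation-filter bounds are inclusive; clash overlap at exactly the
  cutoff counts (with a 1e-12 float guard).
* Alternate locations keep the highest-occupancy conformer; author residue
  numbering is authoritative throughout (interface motifs are quoted in
  author numbering); waters are always dropped, other heteroatoms dropped
  by default with a flag to retain ligands.
* Empty filter survivor sets make the kept fraction undefined (None +
  warning) rather than zero; clustering of an empty or sub-minimal set
  falls back explicitly instead of erroring mid-pipeline.
* Pairwise identity uses global alignment (BLOSUM62, gap open −11, extend
  −1) and divides identical pairs by mutually aligned (non-gap) positions;
  the denominator convention and all parameters are recorded in the result,
  and a shorter-sequence denominator is selectable. Printed identity
  figures for homolog pairs are treated as ±2-point checks since alignment
  parameters shift them slightly.
* MSA columns may be addressed by index or by a BW code resolved through a
  reference sequence; frequencies are over non-gap symbols with the gap
  fraction tracked separately; the aromatic set is {F, W, Y} with histidine
  opt-in.

## Problem sizes

Default test and acceptance runs use ensembles of 500–2,000 models,
five-atom SASA oracles, and 100-atom clash clouds — sizes at which every
oracle (brute-force enumeration, dense quadrature, closed forms) is exact
or near-exact and the full suite completes in well under a minute. The
pipeline itself is O(N log N) in ensemble size and has been run unchanged
on 10⁴-model inputs.

## Known limitations

* The (θ, d) parameterization is a documented stand-in: the package
  defaults to the TM5–TM5 signed crossing angle and TM5 centroid distance,
  and both remain configurable precisely because other conventions for the
  same two quantities exist.
* The contact score is not an energy function; REU-valued conclusions
  require an external energy table.
* Whether the 2%-population cutoff applies to every pipeline or only to
  effector-model selection is ambiguous in the source procedure; it is a
  parameter (`min_population`) rather than a constant.
* Chain selection for structures with more than two receptor copies
  defaults to the first two polymer chains, configurable.
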