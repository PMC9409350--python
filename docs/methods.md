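# Methods

## Model

A *trans*-prenyltransferase elongates an allylic diphosphate by C5 units
inside a tunnel formed by helices D, E and F. Three tiers of tunnel-lining
residues ("floors", one helix pitch apart, so one C5 unit apart) decide how
far the chain grows: the first floor that presents enough side-chain bulk
terminates elongation. The predictor abstracts this as a linear score per
floor and a top-down threshold cascade.

For a query sequence the pipeline is: (1) global alignment against each of
eleven reference templates and selection of the highest-identity one;
(2) projection of the template's nine annotated floor positions (3 floors ×
3 sites) through the alignment onto the query; (3) per-floor weighted
blocking score and cascade:

    S_f = sum_s w[f][s] * B(r[f][s]),   sum_s w[f][s] = 1
    S_1 > θ1 → C15;  else S_2 > θ2 → C20;  else S_3 > θ3 → C25;  else ≥C30

Comparisons are strictly greater; equality falls through to the next floor.
The model never emits C10 (the floors sit above FPP length) or an
"inactive" class; both occur only as experimental labels.

### Blocking score table

B(aa) encodes how effectively a side chain occludes the tunnel. The default
table is residue van-der-Waals volume relative to glycine, normalised so
B(Gly) = 0 and B(Trp) = 1, multiplied by a torsion-capacity factor of 0.7
for the long flexible side chains Lys, Arg and Met (many rotatable bonds, no
ring: they can swing out of the chain's path), 1.0 otherwise. The factor
value is a design choice: it is the smallest round discount that places Met
(0.43) clearly below the rigid aromatics of similar volume (Phe 0.77,
Tyr 0.80) while keeping it above the small-residue range (≤ 0.33 for
Gly/Ala/Ser/Cys/Pro/Asp/Asn/Thr). The table is a model component,
overridable in the model file.

### Weights, thresholds, ambiguity band

Default site weights are the published trained contributions: floor 2 =
(0.200, 0.553, 0.247) and floor 3 = (0.365, 0.629, 0.006); floor 1 site_3
is published as 1.1% with sites 1 and 2 "similar", fixed here as (0.494,
0.495, 0.011). Default thresholds are 0.40 per floor — the midpoint of the
gap between the largest all-small floor score achievable under the default
table (Thr/Thr/Thr = 0.334) and the smallest all-bulky one (Met/Met/Met =
0.429) — frozen after checking calibration behaviour on the mutant panel.

Dual calls (`C20/C25`) are produced by an explicit ambiguity band, default
5% of the decisive threshold (relative, so refitted thresholds keep a
proportionate band): a decisive block within the band adds the
next-longer class as secondary; a near-miss pass at the floor directly
above the decisive one adds the next-shorter class. Secondary calls are
therefore always adjacent. A band of exactly zero disables dual calls.
Whether the original tool produced dual calls from a band, twin thresholds
or near-ties is unknown; the band is this package's own device and is
documented as such.

Predictions are flagged low-confidence when the best-template identity is
below 30% or when a floor site maps to an alignment gap (a missing side
chain blocks nothing, so gap sites contribute zero score).

### Alignment

Needleman–Wunsch with affine gaps via Biopython's `PairwiseAligner`
(global mode, BLOSUM62, gap open 11, gap extend 1; a gap run of length L
costs 11 + (L−1)). Identity is counted over both-non-gap columns, which is
robust to terminal overhangs between full-length and truncated entries.
Co-optimal tracebacks are resolved by the aligner's deterministic first
path; equal-identity templates resolve to the earlier one in the fixed
registry order. Tests check score optimality against an independently
written three-state dynamic program, itself validated against literal
enumeration of all alignments on very short pairs.

### Nine sites vs six

The model carries nine floor sites because trained weights exist for three
sites on each floor; the trained contributions of floor-1 and floor-3
site_3 are near zero (1.1% and 0.6%), which is presumably why the floors
are sometimes described by six residues. A `six_site_mode` model flag drops
those two sites and renormalises floors 1 and 3, rather than guessing
either description as the intent.

## Calibration

The loss (misclassification, or a variant charging 0.5 for one-C5 errors)
is a step function of the thresholds and piecewise constant in the weights,
so the fit is exhaustive rather than gradient-based: each floor's weight
triple is searched on a simplex grid (default step 0.01, matching the
three-decimal precision of the published contributions; 5151 points per
floor) with a threshold sweep over midpoints of the observed floor scores,
coordinate descent over floors in fixed order 1→2→3, repeated to
convergence (at most 20 rounds). Ties are broken toward more uniform
weights, then lexicographically, then toward lower thresholds, making
refits bit-identical. Thresholds are initialised above every achievable
score (everything passes), so the first sweep isolates the C15 boundary
cleanly. NA-labeled, C10-labeled and unmappable records are excluded with
warnings and counted in the result. The blocking table and alignment
parameters are inherited from the base model, not refitted: with a
training set of a few dozen examples, 26 extra free parameters invite
overfitting.

Cross-validation is stratified by class with a seed-deterministic shuffle;
classes smaller than the fold count trigger a merged-stratum warning.

## Synthetic data

All fixtures are *model-consistent* constructions: a sequence is built, the
generating model's own predictor labels it, and records whose prediction
misses the intended class are redrawn. The closed loop guarantees that
pipeline and recovery tests are exercising the machinery, not an external
truth; passing them shows internal consistency, identifiability and
determinism — not accuracy on real enzymes, which only curated labeled
sequences can show.

* **Registry.** The shipped registry is generated deterministically: a
  300-residue ancestor, 30% substitution per template outside floor sites
  (pairwise identities ≈ 47–52%, in the range observed across the real
  family), two templates given short N-terminal extensions so annotated
  positions differ, floor residues set saturated-bulky at the decisive
  floor and saturated-small elsewhere. Kingdom and native-class metadata
  follow the curated set (six bacterial, four eukaryotic, one archaeal
  template; classes spanning C15 to ≥C30). It is a labelled synthetic
  stand-in, not PDB-derived data.
* **Floor variants** (`generate_floor_variants`): class-quota variants on a
  backbone, decisive floor drawn from a bulky pool (default W/F/Y/L/M),
  other floors from a small pool (default G/A/S/C/T), plus background
  mutations outside floor sites (default rate 0.02 per residue, within the
  identity range where floor mapping stays exact).
* **Site probes** (`generate_site_probes`): floor triples sampled from the
  full alphabet and kept when the floor score falls within a band (default
  ±0.08) of the threshold. Saturated variants alone cannot identify the
  weights — any simplex point separates all-small from all-bulky floors, so
  a fit would collapse to the uniform tie-break. Boundary probes on both
  sides of the decision are what pins the weight simplex; this mirrors how
  site-directed mutant panels, not wild-type collections, informed the
  original training. The curated 27-mutant panel in
  `dataset1_like_records` was chosen by hand on the same principle, with
  ladder pairs (e.g. Thr/Met/Trp passing vs Thr/Val/Gly blocking) that
  force floor-1/floor-3 site_3 below a 5% share and floor-2 site_2 above
  half, for *any* zero-loss fit.

## Problem sizes and numerics

Defaults throughout are desk-scale choices adopted as the package's study
conditions: recovery experiments use n = 60 (36 probes + 24 quota
variants), the mutant panel n = 38 (11 templates + 27 mutants), the
evaluation-machinery check n = 141 and grid step 0.01. Scores and losses
are rounded to 12 decimals before comparisons in the fit so tie-breaking is
immune to float-sum noise. Report percentages are rounded half-up to
integers with fractions retained at full precision.

## Known limitations

* The shipped registry and blocking table are reconstructions; predictions
  on real sequences require a curated registry and benefit from refitting
  on curated labels.
* The model assumes the homodimeric elongation tunnel. Long-chain enzymes
  that elongate along the dimer interface, heterodimeric enzymes regulated
  by a small subunit, and FARM/SARM-mediated effects are outside the model
  and are known failure modes.
* C10 (GPP) producers cannot be predicted; the floors begin above FPP
  length.
* Identity values depend on the alignment parameterisation and the
  both-non-gap denominator; published per-query identities may differ by a
  few points under other conventions.
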