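# Methods

## Problem setting

Helical reconstruction assigns a 3D-class label to every boxed segment of
every picked fibril.  With two coexisting fibril-protein conformations A
and B, the per-segment labels form, per fibril, an axially ordered sequence
over {A, B, unassigned}.  The package answers two questions about such
data: *how is conformational composition distributed across fibrils?* and
*are same-conformation segments clustered along the fibril axis?*  The
second, answered positively, is the signature of structural breaks —
positions where the conformation of the protein stack switches within one
fibril.

Fibril identity is always the pair (micrograph ID, helical tube ID); tube
IDs are numbered per micrograph by picking software and are never merged
across micrographs.

## Run statistics and their caveat

For one fibril the classified subsequence (unassigned segments removed,
axial order kept) is run-length encoded; `n_switches = n_runs − 1`.  A raw
switch count is *not* evidence of structural breaks on its own:
independent misclassification at rate ε produces spurious switches at rate
`2ε(1−ε)` per adjacent pair even on a conformationally uniform fibril (at
ε = 0.02, about 4 % of adjacent pairs).  This is why the package's central
inference is a permutation test rather than a switch-count threshold, and
the synthetic generator's property tests document the effect explicitly.

Runs deliberately span unassigned gaps: final-reconstruction subsets cover
fibrils sparsely, and breaking a run at every unclassified segment would
conflate sparse coverage with conformational switching.  Where the sparse
subset makes long axial jumps questionable, `break_at_gap` (Å) optionally
forces a new run when consecutive classified segments are further apart
than the given distance; the default is off.

## B-fraction histograms

`fraction_B = n_B / (n_A + n_B)` uses classified segments only.
Histograms stratify fibrils by minimum classified-segment count
(default thresholds 1, 5, 10, 20, inclusive), and each category is
normalized by its own fibril count.  Bins are 10 equal-width bins on
[0, 1] with the last bin right-closed, so pure-B fibrils land in the top
bin; the exact binning of published figures of this kind is typically not
stated, and 10 deciles is the package's choice.  An empty threshold
category is flagged, not an error.

## The axial-clustering permutation test

* Statistic: total switches summed over all fibrils with ≥ 2 classified
  segments.  Pooling by summation weights fibrils by their number of
  adjacent pairs and gives one dataset-level p-value.
* Null: labels shuffled independently within each fibril, preserving each
  fibril's A/B composition.  The test therefore conditions on the
  between-fibril composition distribution and is sensitive only to
  *within-fibril axial arrangement*.
* One-sided toward fewer switches (clustering).  The add-one correction
  `p = (1 + #{null ≤ obs}) / (N + 1)` keeps p-values valid and strictly
  positive; the smallest attainable p is `1/(N+1)`.
* Per-fibril p-values are available (`per_fibril=True`) as an exploratory
  view, unadjusted; a Benjamini–Hochberg helper is provided separately.

This test is the package's formalization of a claim usually made
qualitatively ("segments of the two classes occupy distinct regions"); the
output JSON labels it as such.

Exactness: on a single fibril with 5 A's and 5 B's arranged in one block,
exhaustive enumeration of all C(10,5) = 252 label placements gives
p = 2/252, and the Monte-Carlo p at 100,000 permutations is required (in
the acceptance tests) to lie within 3 binomial SDs of it.  Under
exchangeable (i.i.d.) labels the rejection rate at α = 0.05 stays ≤ 0.06
over 2,000 simulated tables; under the generator's persistent regime
(below) it is ≥ 0.95.

## The synthetic generator

Each fibril's true conformation sequence is a two-state Markov chain:
initial state B with probability `p_B_init`, state change with probability
`p_switch` at each inter-segment step.  Observed labels flip with
probability `epsilon` (symmetric), and are independently replaced by
"unassigned" with probability `p_unassigned`.  Axial positions lie on the
regular extraction grid `0, interbox, 2·interbox, …`.

The symmetric two-state chain is the minimal model compatible with both
plausible break-forming mechanisms — imperfect templating while the fibril
grows, and post-assembly conversion of initially disordered segments —
which are indistinguishable at the label-sequence level.  The generator is
a modelling device for validating the statistics, not a mechanistic claim.

Defaults (chosen once, as the realistic operating point for this kind of
dataset): fibril lengths geometric with mean 9 segments (a dataset of
~10⁵ segments over ~10⁴ fibrils has about 9 segments per fibril),
`p_switch = 0.02` (persistent regions tens of segments long),
`p_B_init = 0.36` (the overall B-share of classified segments),
`epsilon = 0.02` (a few percent misclassification), `p_unassigned = 0`
(a first-classification table in which every retained segment is labeled),
`interbox = 33.6 Å`.  At these defaults, 5,000 fibrils populate every
decile of the B-fraction histogram with mass at both endpoints — the
qualitative structure the analysis is designed to exhibit.

What the generator does **not** emulate: alignment errors correlated along
the axis or with the crossover phase, fibril curvature or crossing,
class-dependent misclassification rates, more than two conformations, and
the image-level origin of labels.  Passing tests on synthetic tables
therefore validate the *statistics*, not the upstream classification.

`estimate_switch_rate` is the pooled MLE `p̂ = switches / adjacent pairs`
with binomial SE `√(p̂(1−p̂)/n_pairs)`.  It estimates the *observed* switch
rate; with noise, its expectation is inflated toward
`p_switch + 2ε(1−ε)` (to first order), so recovery tests run at ε = 0.

## Helical geometry

`pitch = (360 / twist) × rise`; `crossover = pitch / 2` because a C1 helix
repeats in projection every half turn.  Twist is stored as a magnitude
plus a handedness flag, and no derived quantity depends on handedness —
for many fibril maps the hand is assumed, not measured, so geometry
results must not change with it.  Units are Å internally; nm appear only
at reporting boundaries, rounded to the nearest nm.  For the dataset this
package was built around, twist 1.11°/subunit and rise 4.79 Å/subunit give
pitch 1553.5 Å ≈ 155 nm (the printed twist/rise lack units; degrees and Å
are the only reading consistent with the printed pitch and the ~4.8 Å
layer-line spacing).

## Residue annotation

Numbering is 1-based precursor light-chain numbering (first residue after
the cleaved signal peptide); spans are closed intervals and amino-acid
names in labels are annotations, not validated sequence (the full sequence
is not shipped).  The built-in data encode, for each conformation, the
fibril-protein span Ser2–Ser116, two ordered cores (9–49 in both; 60–107
in A, 68–107 in B), the three disordered segments (2–8; 50–59 in A,
50–67 in B; 108–116), twelve shared β-strands plus two A-only strands
(60–62, 64–65), and the seven germline→patient mutations.  Load-time
validation enforces: ordered/disordered spans disjoint and inside the
fibril-protein span, every strand inside an ordered span.

`classify_position` is a three-way rule: outside the fibril-protein span →
cleaved-or-absent; inside an ordered span → ordered-core; else
disordered.  `diff_annotations` compares per residue (ordered/disordered
status and the set of covering strand labels) and merges differing
residues into maximal intervals — for the default A/B pair the difference
is confined to residues 60–67.

## Aggregation consensus

Per-residue hit rules: TANGO value > 5 (percent), PASTA energy < −2.8,
Aggrescan value > −0.02, each elementwise and strict ("above"/"below"
read literally, so boundary values are non-hits); FoldAmyloid flags
residues belonging to a run of ≥ 5 consecutive values > 21.4.  The
consensus is the 0–4 sum of the four indicators.  The predictors are not
reimplemented — tracks arrive as TSV — and PASTA's pairwise-energy → per-
residue projection is assumed done upstream.

`max_scoring_window` returns the longest maximal run of residues whose
consensus equals the track's maximum (ties to the lowest start),
optionally within a restriction span such as a variable-domain boundary.
A "longest window maximizing the summed score" reading would always
return the whole track (scores are non-negative), so the run-at-maximum
semantics is the one consistent with the intended behaviour on e.g.
`[0, 0, 4, 4, 0] → residues 3–4`.  An all-zero track returns an explicit
empty result (`None`).

## Numerical and I/O choices

* STAR I/O uses gemmi's STAR/CIF parser; the helical particle-table
  convention is read (`_rlnMicrographName`, `_rlnHelicalTubeID`,
  `_rlnClassNumber`, optional track length and coordinates).  Class
  numbers map to A/B through a user-supplied class map, since class
  numbering is an artifact of each refinement run; unmapped classes are
  unassigned.  Missing track-length columns fall back to extraction order
  × declared inter-box spacing.
* Axial positions within a fibril must be pairwise distinct; duplicates
  are a validation error.  Coordinates are 0-based pixels; axial positions
  Å; residue numbering 1-based inclusive.
* All stochastic code (generator, permutation test) takes an explicit
  seed and is reproducible bit-for-bit given it; analysis reports echo
  their full configuration.
* Simulation sizes in the test suite (2,000 tables for type-I error and
  power at 200 permutations each; 2,000 × 50-segment fibrils for
  recovery) are the package's chosen operating points for those checks:
  large enough that the binomial Monte-Carlo error on a rejection rate is
  ~0.5 %, small enough to run routinely.

## Known limitations

* Break *positions* are only resolved to the inter-segment spacing; the
  package does not localize breaks within a box or relate them to
  crossover phase.
* The permutation test conditions on per-fibril composition; it has no
  power against heterogeneity expressed purely between fibrils.
* Dataset-scale published figures that require the deposited raw data
  (fibril counts per threshold category, map resolutions) are documented
  but not reproducible at desk scale and are not computed here.
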