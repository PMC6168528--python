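# Methods

## Statistical potentials from solubility-labeled structure sets

`solpot` implements distance-dependent, sequence-separation-stratified
residue-pair potentials of mean force. The structural descriptor is the
distance d between the geometric centers (unweighted means) of the two
residues' side-chain heavy atoms; glycine and residues with no resolved
side-chain heavy atoms use the Cα position instead. The inverse Boltzmann
relation maps observation frequencies to pseudo-energies,

    ΔW(s, s′, d) = −k_B T · ln [ n · n_{ss′d} / ( n_{ss′} · n_d ) ],

where n_{ss′d} counts occurrences of pair (s, s′) in distance bin d,
n_{ss′} and n_d are its marginals and n the total — all within one
sequence-separation class. Distances are binned half-open on [3, 10) Å in
35 bins of 0.2 Å, plus a 36th overflow bin collecting d ≥ 10 Å (a
configuration switch collapses the overflow into the last core bin to test
the alternative reading). Distances below 3 Å — rare steric near-clashes —
are clamped into bin 0 and counted in a diagnostic. Separations
|i − j| = 2…8 each get their own potential; all |i − j| > 8 are pooled
into a single long-range class where chain connectivity no longer
constrains the geometry. |i − j| ≤ 1 is never counted. Sequence positions
are positions in the filtered chain (order of appearance), not author
numbering, which can carry gaps and insertion codes.

The solubility-dependent potentials condition the joint frequency and the
distance marginal on the soluble or the weakly soluble half of the dataset
while keeping the composition frequency from the full set:

    ΔW^sol  = −k_B T · ln [ F(s,s′,d | D^sol)  / ( F(s,s′ | D^tot) · F(d | D^sol) ) ]

and analogously for D^insol. Keeping F(s, s′) from D^tot means that a
composition difference between the halves (e.g. more Trp in insoluble
proteins) shifts the conditioned potential at *all* distances, which is
the intended behaviour: the potentials absorb the dataset biases, and the
significance analysis then asks whether a pair's profile difference is
larger than random-split noise. With joint = composition set, the
expression reduces exactly to the classical total potential
(regression-tested bit for bit).

k_B T defaults to 0.593 kcal/mol (298.15 K) and is configurable. All
energies — and hence M, V and the protein scores — scale linearly in it;
rankings are invariant.

## Small-sample repair layers

Two layers compensate for the limited size of solubility-labeled sets:

* **Smoothing.** Each bin count is replaced by the weighted sum of itself
  and its four nearest neighbours with weights 1/α², 1/α, 1, 1/α, 1/α²
  (α = 4/3), zero-padded at both ends; the overflow bin participates as an
  ordinary last neighbour. Marginals are recomputed from the smoothed
  joint counts; raw marginals are never mixed with smoothed joints.
* **Occurrence threshold.** Bins whose count does not *strictly exceed*
  10 are masked and their potential forced to exactly 0 (20 for group
  potentials).

The order of the two layers is genuinely ambiguous in the formalism's
usual presentation (a threshold "first layer" and a smoothing "second
layer"). Thresholding raw counts and then smoothing would re-inject mass
into just-emptied bins, so the package defaults to **smooth first, then
threshold on the smoothed counts**; the alternative order is available
behind the `layer_order` configuration switch for sensitivity analysis.

## Sign convention of the pair difference statistics

Per pair, over the N_d distance bins of one separation class (the
long-range class by default),

    M = (1/N_d) Σ_d (ΔW^insol − ΔW^sol),    V = (1/N_d) Σ_d (ΔW^insol − ΔW^sol)².

The package orients the difference as insoluble-minus-soluble so that
**M > 0 ⇔ solubilizing** (the interaction is more favourable, i.e. lower
in energy, in soluble proteins) and M < 0 ⇔ insolubilizing. This matches
the printed convention of the field's reference results (Lys-salt bridges
positive, aromatic pairs negative); note that V and |M| — everything the
significance test consumes — are orientation-invariant. Masked bins carry
their stored value 0 and enter the sums as such; a `shared_support` mode
restricts the sums to bins unmasked in both tables (N_d replaced by their
count) for sensitivity analysis. V ≥ M² (Cauchy–Schwarz for a mean and
mean-square over the same bins) is asserted on every classification call.

## Randomized-split null

The null model re-splits the full dataset into two random halves of equal
size (odd sizes give the first half the extra protein), re-runs the entire
derivation — pooling cached per-protein count tensors, smoothing,
thresholding, conditioned potentials — and records per-pair (|M|, V).
Default 100 shuffles, driven by a single integer seed. Sig M is the
fraction of null |M| *strictly* below the actual |M| (ties count against
significance — conservative); Sig V analogously. Strict criterion:
Sig M ≥ 0.95 and Sig V ≥ 0.95; relaxed: or. No multiple-testing
correction is applied across the 210 pairs, deliberately: the analysis is
exploratory and the reference convention applies none; users comparing
flag counts across configurations should keep this in mind. Because the
null has 100 samples and the criterion is a joint one on two correlated
statistics, the strict flag rate under exchangeable classes is not a
calibrated 5%; the test suite checks a loose ≤ 10% median band across
generator seeds.

Reported pair tables are grouped by interaction category (π-π, His-π,
cation-π, amino-π, anion-π, Lys salt bridges, aliphatic, miscellaneous)
from an editable TSV shipped as package data, and sorted by |M| within
category.

## Group potentials

Pairs sharing one physical mechanism (e.g. the aromatic pairs
Phe/Tyr/Trp × Phe/Tyr/Trp) can be pooled into a single long-range
profile. Before pooling, each observed distance is shifted towards
smaller values by the radius excess of both partners over the group's
smallest member, aligning contact minima of differently sized side
chains. No canonical residue-radius table exists for this purpose, so the
default is computed empirically from the input structures as each type's
mean centroid-to-farthest-side-chain-heavy-atom distance; a user table can
override it. The pooled profile is smoothed, thresholded at 20
occurrences, and normalized with the subset's ordinary distance marginal
and the summed member-pair composition frequency (a per-pair-normalize-
then-average mode is the natural alternative; the pooled mode is the
default because it weights members by their abundance).

## Folding free energies and the solubility score

A protein's energy under a table is Σ_{i, j ≥ i+2} ΔW(s_i, s_j, |i−j|,
d_ij) over same-chain pairs; since the potential is piecewise constant in
d, this is computed exactly as the contraction of the protein's raw count
tensor with the table values. The solubility score is
ΔW^insol_{S,C} − ΔW^sol_{S,C}: soluble proteins sit deeper in the
soluble-derived potential, so larger scores predict higher solubility.
Scores of dataset members are computed with strict leave-one-out: the
target's raw counts are subtracted from its subset's and the total pooled
counts before smoothing, thresholding and derivation. Counts are
integer-valued, so subtraction is exact and the result is bit-identical
to a from-scratch re-derivation without the target (regression-tested).

Sequence features for comparison: length; isoelectric point by bisection
of the Henderson–Hasselbalch net charge with the EMBOSS pKa set (N-term
8.6, C-term 3.6, Lys 10.8, Arg 12.5, His 6.5, Asp 3.9, Glu 4.1, Cys 8.5,
Tyr 10.1) — pI conventions differ across tools, so cross-tool agreement
is expected only to a few tenths of a pH unit; the aliphatic index
AI = 100·(X_Ala + 2.9·X_Val + 3.9·(X_Ile + X_Leu)); and the Val+Ile+Leu
fraction, compared between sets with a two-sample Kolmogorov–Smirnov
test.

## Structure parsing policies

PDB and mmCIF are read with gemmi. Model 1 of multi-model (NMR) entries
is used. Only the 20 standard residue types are kept; MSE is mapped to
MET; other modified amino acids are dropped with a warning; waters,
ligands and nucleic residues are excluded silently. Altloc conflicts
resolve to the highest-occupancy conformer, ties broken by altloc
identifier order. Only chains named in the annotation row are used, and
residue pairs are only counted within a chain — inter-chain pairs never
enter the statistics. The 64% solubility split sends the threshold value
itself to the soluble side (≥).

## Synthetic data

The generator emulates exactly the statistical structure the method
consumes: residue types (drawn from an average globular composition),
sequence separations, and side-chain centroid distances. Chains are
self-avoiding random walks of Cα positions with a fixed 3.8 Å step (steps
closer than 2 Å to an earlier Cα are resampled, up to 100 times), and
centroids are displaced from Cα by a random offset of 2.4 ± 0.6 Å (zero
for glycine). Class-conditional signal is planted as contacts: residue
pairs at |i−j| > 8 are mutated to the target types and moved to the
center of the distance bin containing the target distance (bin-center
placement keeps the contact in its bin after coordinates round to PDB
precision). Solubility pseudo-labels are drawn uniformly inside the class
ranges ([64, 100] soluble, [0, 64) insoluble) so the 64% split recovers
the generating classes exactly. Datasets are a pure function of the
parameter set including its seed.

Default study conditions: 30+30 proteins of 80–120 residues;
`RECOVERY_BIASES` plants eight Lys-Glu contacts per soluble protein at
4 Å and eight Trp-Trp contacts per insoluble protein at 6.3 Å — strong,
unambiguous signal at the two distances where salt bridges and aromatic
stacking have their minima.

What the surrogates do *not* emulate: real fold topology, secondary
structure, packing density, residue-environment correlations, or
realistic radial distribution functions at short range. Passing tests
therefore demonstrate the correctness and statistical behaviour of the
pipeline (counting, derivation identities, null calibration, signal
recovery), not biological conclusions about real proteins — those require
a real structure set with experimental solubility labels, supplied as an
annotation table.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at the
generator's default study conditions (60 proteins, 100 shuffles); the
calibration and recovery checks repeat this over 10–20 generator seeds.
Tolerances: exact identities (label swap, leave-one-out, reduction to the
classical potential) are asserted bit-for-bit — they hold exactly because
integer count arithmetic is exact in double precision; oracle comparisons
use 1e−12 relative tolerance; statistical bands are stated per test.
Degenerate inputs: pairs with zero composition frequency are masked
rather than given infinite energies; an empty derivation subset is an
error; correlations on zero-variance inputs are errors rather than NaN.

## Known limitations

* The per-pair significance test is exploratory (no multiplicity
  control); strict-flag counts should not be read as a calibrated family
  error rate.
* The empirical residue-radius table for group potentials is an
  interpretation; published radius sets can be supplied instead.
* The isoelectric point depends on the chosen pKa set; only orderings and
  rough magnitudes are robust.
* No solubility predictor is included: the score is a relative,
  temperature-scaled quantity, not a calibrated solubility estimate.
* Buried-core composition statistics are out of scope (no solvent
  accessibility computation).
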