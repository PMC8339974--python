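# Methods

## Read-across model

For a query compound the engine searches a training database for neighbors
above a similarity threshold and predicts by a similarity-weighted
majority vote over the neighbors' experimental outcomes,
p_c = Σ sim_{n,c} / Σ sim_n. The assumptions are those of any local QSAR:
structurally similar compounds act through similar mechanisms, and the
training database samples the query's chemical neighborhood densely
enough for the vote to be informative. The engine makes no parametric
assumption about the similarity–activity relationship; its reliability is
controlled entirely by the applicability-domain tiers.

Two kernels are supported. The set kernel (Tanimoto/Jaccard over
atom-environment features) measures shared substructure; the cosine
kernel over preprocessed numeric descriptors measures physicochemical
proximity. Cosine values are used raw — centering can legitimately
produce negative similarities, and the tier thresholds are compared
against the uncorrected value.

### Tier policy

| kernel | high tier | low tier |
|---|---|---|
| fingerprint / Tanimoto | 0.5 | 0.2 |
| descriptor / cosine | 0.9 | 0.7 |

Neighbors are first collected at the high threshold; success yields a
high-confidence prediction. On failure — no neighbors, or a degenerate
vote — the search repeats at the low threshold and the result carries a
low-confidence (out-of-domain) warning. If both tiers fail the engine
abstains rather than guess. A vote tied at exactly p = 0.5 is treated as
a failure of the current tier: the wider tier may break the tie with
additional neighbors, and a tie persisting at the low tier abstains with
reason "tie". Abstention is the conservative choice for a read-across
tool — an undefined argmax is not evidence for either class.

Database entries whose canonical structure equals the query's are
excluded from its neighbor list, so predicting a training compound is
leave-one-out by construction. Contradictory training compounds (kept as
two measurements) contribute one vote per measurement at the same
similarity; the minimum neighbor count defaults to 1 and is configurable.

## Dataset compilation

Source tables are normalized to (source, SMILES, outcome) records;
strain-wise tables are first reduced to a binary call: mutagenic iff at
least one positive in the seven *S. typhimurium* tester strains
(TA97, TA98, TA100, TA102, TA1535, TA1537, TA1538), with or without S9;
non-mutagenic if listed-strain results exist and none is positive;
excluded (with a reason) when only other organisms were tested.
Structures are keyed by RDKit canonical SMILES with aromaticity
perception; no salt stripping, charge neutralization or stereochemistry
normalization is applied beyond canonicalization, so absolute unique
counts can shift by a few structures relative to pipelines built on a
different canonicalizer. Same-key same-outcome records collapse to one
measurement (their sources are pooled); opposite outcomes are retained as
two measurements and flag the compound contradictory. The merge result is
independent of input order. The numeric-descriptor path additionally
drops contradictory compounds and compounds without a descriptor row
(failed external descriptor calculations); descriptor computation itself
is out of scope — matrices are consumed as CSV.

## Fingerprints

One feature per heavy atom: the atom's type plus the counted types at
topological distances 1 and 2 (`root;d1:TxN,...;d2:...`, types sorted —
canonical and diffable). Default typing is element symbol + aromaticity
flag; the typing function is pluggable. Depth is fixed at 2 layers by
default, matching the published atom-environment definition. Features are
collected as a set, so similarity reduces to set algebra; hydrogens are
excluded; the representation depends only on the molecular graph.
Bit-exact compatibility with OpenBabel's MolPrint2D files is a non-goal.

## Descriptor preprocessing

Two fit-on-train-only modes, both serializable to JSON:

* `nzv_corr_scale` (read-across path): drop near-zero-variance features
  (top/second frequency ratio > 95/5 *and* percent-unique < 10 — the
  documented defaults of caret's `preProcess` filters; constant columns
  always drop), then greedily resolve feature pairs with |r| > 0.90 by
  visiting pairs in descending |r| and dropping the member with the
  larger mean absolute correlation (ties: the later column), then center
  and scale survivors (sd with n−1, the R convention). Pearson
  correlation is scale-invariant, so filtering before or after scaling is
  equivalent.
* `quantile_uniform` (global-model path): per-feature monotone map onto
  [0, 1] through the training empirical CDF, tabulated at
  min(1000, n_rows) evenly spaced quantiles with linear interpolation;
  out-of-range values clip to [0, 1]; constant training columns map to
  0.5.

For external prediction sets only the intersection of training and
prediction features is used, in training order; an empty intersection is
an error.

## Global baselines

Five families behind one train/predict contract, all thresholded at 0.5:

| family | configuration |
|---|---|
| random forest | 1,000 trees, max_leaf_nodes 200 |
| logistic (SGD) | 5-model ensemble, log-loss SGD, 50 epochs each |
| logistic (default) | library defaults |
| neural net | 5-model ensemble, 4 hidden layers × 64 ReLU, Adam, batch 64, 50 epochs |
| SVM | RBF kernel, gamma = "scale", Platt-scaled probabilities |

Ensembles differ only by random initialization (seed + member index) and
average member probabilities. The SGD logistic family performs per-sample
stochastic gradient descent over 50 epochs (scikit-learn's SGDClassifier);
all remaining hyperparameters are the implementing library's defaults and
are exportable to the run manifest for audit. Determinism given the spec
seed is part of the contract and is tested.

## Crossvalidation

Folds (default k = 10, near-equal sizes, seeded shuffle) are drawn over
unique structures, so a contradictory compound's two measurements never
straddle folds; folds are unstratified with the seed recorded. Per fold,
every data-dependent transformation — descriptor preprocessing, the
fingerprint vocabulary for matrix expansion — is fit on the training
partition only. The read-across engine scores every held-out measurement
and may abstain; abstentions count toward n_total but not n_predictions.
Global models require one label per structure, so contradictory compounds
are excluded from their crossvalidation entirely. One lazar run yields
two report views: high-confidence predictions only (lazar-HC) and all
predictions (lazar-all).

Metrics (accuracy, TPR, TNR, PPV, NPV) are computed from the pooled
confusion matrix, reported as percentages, rounded only at rendering;
zero-denominator metrics are reported as undefined, never as 0. ROC
coordinates are (1 − TNR, TPR). McNemar's test of classifier-vs-assay
concordance uses the discordant counts b, c: exact two-sided binomial
when b + c < 25, continuity-corrected χ² otherwise, p = 1 when b + c = 0.

## Pyrrolizidine-alkaloid grouping

Each structure is classified along three independent axes with an
explicit SMARTS rule bank (the accepted structural definitions of the PA
subtypes; unit-tested on named alkaloids with hand-verified structures):

* necine base: otonecine (N-methyl azacyclooctanone core), retronecine
  type (1,2-unsaturated pyrrolizidine), platynecine type (saturated),
  else unassigned;
* modification: N-oxide (ring N⁺–O⁻), dehydropyrrolizidine (pyrrolic
  core), else tertiary;
* necic acid: ester arms anchored on the core (alkoxy carbon in or
  adjacent to it) — one: monoester; two or more with both ester oxygens
  in a common ring of ≥ 10 atoms: macrocyclic diester; otherwise open
  diester; none: unassigned.

Compounds without a recognizable core stay in the summary with
`unassigned` labels so totals reconcile. Group summaries report, per
model and group, the predicted count, positive count and positive
fraction (abstentions excluded from denominators; empty groups report an
undefined fraction), plus per-axis rank orders pooled over models.

## Synthetic study conditions

The generator emulates what the pipeline needs from a curated Ames
database: congeneric series with a substructure-driven endpoint. Each of
20 drug-like aromatic scaffolds yields one series of 10 congeners; the
first substitution slot carries the aromatic-nitro toxicophore in
positives (a methyl in negatives) and one peripheral slot takes a benign
decoration drawn *without replacement* within the series. Three
construction choices make the labels recoverable by design, which is the
point of the fixture: benign fragments are capped at two heavy atoms so
the three-atom nitro group dominates any cross-class environment
difference; the benign grammar contains no nitro mimic under
element+aromaticity typing (an aromatic amine would differ from a
nitroarene only at distance-2 oxygens); and without-replacement
decoration sampling guarantees no cross-class twin shares a rare
substituent. Classes are balanced per series (configurable positive
fraction), labels are optionally flipped at a noise rate in [0, 0.5), and
everything is reproducible from one seed with uniqueness verified by
canonical-SMILES recount.

The companion descriptor matrix carries simple computed properties
(atom/ring counts, heteroatom fraction, MolWt, logP, TPSA, H-bond counts,
nitro-group count) plus, deliberately, 2 constant, 3 duplicated and 3
Gaussian-noise columns so the preprocessing filters always have work to
do.

What the fixture does **not** emulate: real mutagenicity SAR (one alert,
no activity cliffs, no mechanism diversity), the class imbalance and
heterogeneous provenance of public Ames data, descriptor-calculation
failures, or measurement error beyond symmetric label flips. Passing the
recovery tests therefore demonstrates that the pipeline's machinery is
correct — neighbors found, votes weighted, folds leak-free — not that any
particular accuracy will transfer to real chemistry.

## Problem sizes and numerical choices

Tests and the acceptance script run at 200 training structures (20 × 10),
k = 10, with 1,000-instance brute-force kernel checks at 1e-12 and
100-compound exhaustive read-across equivalence checks — sizes chosen so
the whole pipeline, including the 1,000-tree forest and the five-member
neural ensembles, completes in well under a minute per run while leaving
every code path exercised. Seeds are explicit everywhere; fold assignment,
generator output and model fits are bit-reproducible given the seed.

## Known limitations

* Canonicalization is delegated to RDKit; pipelines using another
  canonicalizer will disagree on a small number of tautomer/aromaticity
  edge cases, shifting absolute unique-structure counts.
* The cosine kernel on centered descriptors can go negative; tier
  thresholds assume strongly positive similarity regimes and are not
  meaningful near zero.
* The PA rule bank encodes the classical subtype definitions; exotic
  necine variants (e.g., seco bases, rearranged cores) fall back to
  `unassigned` rather than being forced into a group.
* The SVM family's probabilities come from Platt scaling, which is known
  to be poorly calibrated on tiny folds; only the 0.5 decision threshold
  is consumed downstream.
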