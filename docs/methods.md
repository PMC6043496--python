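# Methods

## Feature encoding

**PAAC (Type-I).** A sequence of length L maps to 20 + λ components.
Each propensity scale is standardized to zero mean and unit variance
over the 20 residues (population convention, n = 20; standardization is
idempotent to machine precision). The correlation between residues
R_i and R_j is the averaged squared difference over the Γ = 5 scales,

    Θ(R_i, R_j) = (1/Γ) Σ_k [S_k(R_j) − S_k(R_i)]²,

and the tier-j factor averages Θ over all residue pairs j apart,

    θ_j = (1/(L−j)) Σ_{i=1..L−j} Θ(R_i, R_{i+j}),   j = 1..λ.

With f_u the raw residue counts and w the weight factor,

    x_u = f_u / (L + w Σθ)        for u = 1..20,
    x_{20+j} = w θ_j / (L + w Σθ) for j = 1..λ,

so all components are non-negative and sum to 1. Defaults: λ = 50
(hence minimum sequence length 51, vector length 70) and w = 0.05, the
standard PAAC convention; both are exposed in `PaacConfig`. The choice
of raw counts rather than normalized frequencies in the numerator only
rescales the relative weight of the θ block; the simplex structure is
identical. Implementation note: Θ is precomputed as a 20×20 matrix from
the standardized scales, so encoding is O(λ·L) with vectorized gathers;
a brute-force re-evaluation of the definition is kept in the test suite
and must agree to 1e-12.

**Dipeptide composition.** Counts of the 400 ordered residue pairs
divided by L−1; lexicographic ordering by first then second residue,
fixed in the exported schema. The per-protein vector is
[PAAC | dipeptide] (470); an interaction is the ordered concatenation
[IDP | partner] (940). The IDP always occupies the first slot and both
ids are recorded on the vector, making models reproducible even though
either concatenation order would be self-consistent.

**Propensity scales.** TOP-IDP, B-values (flexibility), FoldUnfold
(expected contacts) and net charge (D,E → −1; K,R → +1; histidine
neutral) are transcribed from their primary publications into 2-column
TSV package data with provenance headers. The DisProt
compositional-bias scale ships as a constructed surrogate
(`disprot_synthetic.tsv`) that preserves the canonical
order-promoting/disorder-promoting residue ranking; because every scale
is z-standardized before use, only ranking and relative spacing enter
the features. User scales load from the same format.

**Nonstandard residues.** Reference proteomes contain B, J, O, U, X, Z
and stop characters. Default policy: delete them and log per-letter
counts, erroring when more than 5% of a sequence would be lost; a
strict `error` policy is available. Silent coercion to a standard
letter would bias composition and is not offered.

**Baselines.** For method comparison the package includes (i) lagged
autocovariance of standardized scale profiles, AC_k(d) =
(1/(L−d)) Σ_i (S_k(R_i)−S̄_k)(S_k(R_{i+d})−S̄_k), length
n_scales × max_lag; and (ii) conjoint-triad composition over the
7-class reduced alphabet {AGV, ILFP, YMTS, HNQW, RK, DE, C}, 343
components summing to 1, with a raw 8000-tripeptide variant since the
literature description of tri-peptide encodings is ambiguous between
the two.

## Dataset construction

Sequence filters: length ≥ 50 (fragments and very small proteins), and
case-insensitive description matching against
{putative, potential, uncharacterized}. Redundancy reduction at 40%
identity uses greedy incremental clustering, longest sequence first
(ties by id): a sequence joins the first representative it matches
above threshold. Identity is identical positions / alignment length
from a Needleman–Wunsch global alignment (match 1, mismatch 0, gap open
−10, gap extend −0.5). This is meant for desk-scale inputs; for
proteome scale a CD-HIT `.clstr` file can be imported instead, which is
also how the original redundancy reduction of published datasets can be
reproduced exactly. Experimental-confidence filtering is exposed as an
optional cutoff (default: keep all), since reference interactome
quality cutoffs are dataset-specific.

**Degree-balanced negatives (training).** The positive-degree multiset
of IDPs is randomly paired against the positive-degree multiset of
partners, rejecting known positives and duplicate pairs. Conflicting
tails are re-shuffled among themselves and repaired by pair swaps; if
the greedy process stalls, the full assignment is re-solved exactly as
a max-flow b-matching (source → IDP at slot capacity → admissible
partner at capacity 1 → sink). When even the exact solution cannot
place every slot the sampler raises, reporting the attainable maximum —
on very small or very concentrated networks a perfect degree-preserving
negative set genuinely does not exist, and silently breaking parity
would defeat the point of balancing. Parity (per-protein negative
degree = positive degree) is asserted on every sampled set.

**Uniform negatives (testing).** Uniform draws without replacement from
the admissible (IDP, partner) combinations, excluding every known
positive, until ratio × N pairs are drawn. The combination universe
defaults to the dataset's own components but is widened during holdout
evaluation to all IDPs × the full test partner partition, mirroring a
screening scenario where any candidate pair may be queried.

**C2 splits.** Partner proteins are partitioned into train and test
partitions; records follow their partner. Every test pair's partner is
absent from training entirely (as either pair side); its IDP may and
usually does occur in training — that is the C2 design, which measures
generalization to never-seen partner proteins. The partition covers all
non-IDP sequences in the store, and is stratified by partner
positive-degree so that each repeat's test set holds close to
`test_fraction` of the positives rather than a lottery over hub
partners; stratification reduces repeat-to-repeat variance and keeps
high-imbalance test sampling feasible, and does not interact with the
disjointness contract. Both leakage properties (no shared partner, no
shared pair) are verified with hard assertions on every split and
re-verified after negative augmentation. Defaults: 5 repeats,
test_fraction 0.25.

## Models

All four families are scikit-learn estimators behind a uniform
train/predict surface keyed to the feature schema: a model records the
940-name schema and a SHA-256 fingerprint of (sorted pairs, labels,
seed, algorithm) at fit time and refuses vectors produced under any
other schema, both at predict and at load.

Defaults: random forest 500 trees with sqrt-features; gradient boosting
200 stages, depth 3, learning rate 0.1 (the classic greedy variant —
histogram-binned boosting cannot take the first split on
degree-balanced training sets, where no single feature carries marginal
gain because class feature means are equalized by construction);
logistic regression C = 1 on standardized features; RBF SVM C = 1 with
scores mapped from the decision function through a logistic (Platt
calibration is unstable at these sample sizes). Grid and random search
optimize inner cross-validated AUC. Note that a purely linear model is
structurally blind to the synthetic benchmark's planted rule (a product
of IDP and partner charge), which is the expected behaviour, not a
defect.

The benchmark configuration (`workflows.OPTIMIZED_RF`) is a random
forest with 800 trees and max_features = 0.1: with informative signal
concentrated in a small fraction of the 940 coordinates, sqrt-feature
subsampling rarely offers an informative split candidate, and the
larger subsample plus forest size closes most of the gap to the
generative oracle. It was selected once against that oracle and then
frozen.

## Evaluation

AUC is the Mann–Whitney rank statistic (average ranks on ties), equal
to trapezoidal ROC area. AUPRC is step-wise average precision over
descending distinct-score blocks, with no linear interpolation, the
conservative convention under imbalance. Threshold metrics (ACC, F,
MCC, precision, recall, fall-out) binarize at 0.5 with the boundary
counted positive. Ratios with zero denominators are reported as 0 and
flagged rather than raised, so aggregate tables remain computable on
small folds. Reports keep the per-repeat table; aggregation is exactly
arithmetic mean and sample sd. Ten-fold stratified pair-level CV is
provided for model selection; generalization claims use the C2 holdout,
where each trained model is scored at each requested negative ratio
(1, 10, 100 × N), with `n_draws` independent negative draws available
per ratio (default 1).

## Synthetic data

`generate_sequences` draws residues i.i.d. from a SwissProt-like
background multiplied by exp(bias·TOP-IDP_z + tilt·charge):
`disorder_bias` (default 0.5) enriches IDP-like sequences in
disorder-promoting residues, and a per-sequence charge tilt creates
net-charge variation. IDP tilts are bimodal (±1.5·`charge_sd`, sd
0.25·`charge_sd`) — synthetic IDPs are pronounced polyelectrolytes of
random sign, reflecting the charge enrichment of real disordered
sequences and giving every IDP a well-defined complementarity
preference; partner tilts are centred normal (sd `charge_sd` = 0.8).
Default lengths: IDPs 120–300, partners 150–400 (≥ 51 is enforced,
the PAAC minimum).

`generate_network` gives each of the 30 IDPs a degree from a truncated
power law (exponent 1.8, cap 12), pins the edge total to
`mean_idp_degree` × n_idps (default 2.6 × 30 = 78) so density is a
fixed condition rather than a draw, and caps partner degree at 3
(ordered proteins have bounded promiscuity). With 300 partners the
IDP:partner mean-degree ratio is 10, emulating the hub character of
disorder-centric interactomes. Under the planted rule an IDP selects
partners with probability ∝ exp(strength · z_IDP · (−z_partner)) over
z-scored net charge per residue (strength 6); with `planted_rule="none"`
selection is uniform and the network carries no sequence-level signal.
The rule parameters were calibrated once so that the generative oracle
(scoring test pairs by the true charge product) separates positives
from uniform negatives with AUC ≈ 0.98, leaving the downstream
benchmark to measure estimation quality, and were then frozen.

**What the benchmark shows — and does not.** Passing the planted-rule
benchmark shows the pipeline can recover a composition-level pairing
rule from sequence alone on unseen partners, and the chance-level null
shows no information leaks through sampling, splitting, encoding or
caching. It does not show that real IDP interactomes are predictable to
the same degree: real binding depends on motifs, context and
post-translational state that i.i.d. compositional sampling does not
emulate, real networks carry correlated noise and study bias, and the
synthetic problem sizes (tens of IDPs, hundreds of partners, ~78
positives) are far below published training sets. Published performance
tables can therefore only be reproduced by importing the corresponding
supplementary train/test pair lists through the FASTA + pair-list
route, not from synthetic data; the numbers this package's tests assert
are properties (dimensions, parity, leakage, oracle agreement,
qualitative imbalance behaviour), not those table values.

## Numerical and degenerate-input choices

* Scale standardization: population sd (n = 20); a constant scale is a
  configuration error.
* Greedy clustering tie-break: longest first, then lexicographic id.
* Balanced sampling: deterministic under seed; the flow completion is
  deterministic given the same stall state.
* Split/negative-draw seeds are derived per repeat/ratio/draw from the
  top-level seed, so any single repeat is reproducible in isolation.
* Sequences shorter than λ+1 (PAAC), 2 (dipeptide), 3 (triads) or
  max_lag+1 (autocorrelation) raise errors naming the sequence id.
* Empty filter results warn rather than raise; empty split sides raise
  naming the repeat.

## Known limitations

* The internal alignment-based redundancy reduction is quadratic and
  meant for small inputs; use the CD-HIT import at scale.
* Degree-balanced sampling can be genuinely infeasible on tiny or
  hub-concentrated networks; the error reports the attainable maximum.
* SVM probabilities are monotone logistic transforms of margins, not
  calibrated probabilities; thresholding at 0.5 corresponds to the
  decision boundary.
* Isoform- and PTM-specific interactions are out of scope; records are
  keyed by plain sequence identifiers.
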