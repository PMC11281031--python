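# Methods

This note documents the models, conventions, and numerical choices behind
`mixtox`, and what the synthetic benchmarks do and do not demonstrate.

## Concentration-addition model

Concentration addition (CA) assumes the mixture components act through a
common mode, so doses are interchangeable after scaling by potency. For a
binary mixture with mass fractions `p_A + p_B = 1` at the median effect,

    EC50_mix = 1 / (p_A / EC50_A + p_B / EC50_B)       (mg/L)

the `p`-weighted harmonic mean, always bounded by the component EC50s. The
toxic-unit sum `TU = C_A/EC50_A + C_B/EC50_B` measures joint action at the
observed concentrations; the mixture concentration producing the median
effect is `C_M = TU × EC50_mix`, and within the additive band each
component's required concentration lies in `(0.8 p_i EC50_mix,
1.2 p_i EC50_mix)`.

Interaction bands are implemented exactly as the framework defines them:
TU ∈ [0.8, 1.2] additive (edges included), TU > 1.2 synergistic,
TU ≤ 0.8 antagonistic, and TU ≥ 0.8 additionally flags independent action.
**Caveat:** this orientation is the reverse of the more common CA reading
(where needing *less* material than predicted, TU < 1, indicates synergy);
we follow the framework's convention and document it here. Because the
additive and independent bands overlap, the primary label uses the
precedence antagonistic/additive/synergistic and independence is a separate
boolean. The additive band (0.8, 1.2) is the default but any `(lo, hi)` band
can be supplied to model other interaction regimes.

Mass fractions from toxic-unit ratios use
`w_i = tu_i·EC50_i / Σ_j tu_j·EC50_j` — the source material states the
inputs but not the algebra; this is the unique normalisation for which
concentrations `p_i × EC50_mix` carry exactly one toxic unit (the round-trip
invariant is property-tested to 1e−10). Mole fractions renormalise
`w_i / M_i`.

## Units and labelling

Potencies always carry explicit units; conversions (`pEC50 → EC50` via
`10^(−p)`, mol/L → g/L via the mole-fraction-weighted mean molar mass) are
explicit operations. Binary labels use the EPA 100 mg/L cutoff for
EC50/LC50 (exactly 100 mg/L is non-toxic) or 500 mg/kg for LD50 (500
non-toxic, by the same boundary convention); custom LD50 thresholds
{50, 250, 500, 750, 1500} mg/kg are supported. The five-category scale
(<0.1 → very highly toxic … >100 → practically nontoxic) uses half-open
bands closed at the listed upper bound so every positive concentration maps
to exactly one class.

## Featurization

The mixture descriptor is `D = x1·d1 + x2·d2` with an explicit weight basis
tag (`mole`, `mass_conc`, or `equal`; default `mass_conc`, with `equal`
matching equal-concentration runs). The `diff` (|x1·d1 − x2·d2|) and `norm`
(elementwise Euclidean) variants are reconstructions and excluded from
headline checks; only `sum` is used there. Descriptor matrices are
median-imputed per column; all-NaN columns are dropped with a warning.
Binary-mixture component order is normalised lexicographically by chem_id
before concatenation and mixing, so mixtures are order-invariant end to end.

SMILES vocabularies index characters in first-appearance order over the
training corpus and are serialized with models, so prediction-time encoding
is bit-identical; unseen characters and over-length strings are rejected
rather than truncated. One-hot tensors zero-pad short strings at the tail
(no pad token).

## Hybrid neural network

The HNN merges a convolutional branch over the K×L×M one-hot SMILES tensor
(two valid-padding conv blocks, 32 and 64 filters, kernel 3, ReLU, max-pool
2, then dense 64) with a feed-forward branch over the mixture descriptors
(z-scored with training statistics; dense 128 → 64), into a merged dense 64
layer and a task head: sigmoid + binary cross-entropy, softmax + categorical
cross-entropy over the five toxicity classes, or linear + MSE for the
regression target log10(1/EC50 in mol/L). Optimisation is mini-batch Adam
(lr 1e−3, batch 32, 50 epochs by default; all exposed in `HNNConfig`).

The implementation is plain numpy (im2col convolution, explicit backprop),
which keeps training bit-deterministic for a fixed seed: initialisation and
batch shuffling derive from `cfg.seed`, and two runs with the same seed and
data produce identical predictions. Conv blocks that would shrink the
sequence below the pool width are skipped automatically for very short
inputs. These hyperparameters are sensible defaults, not tuned values; the
verification suite relies on properties (determinism, head contracts,
separation benchmarks), never on a specific accuracy of these defaults.

Baselines are scikit-learn: RF/bagging/AdaBoost classifiers and the six
regressors (RF, SVR, GB, kernel ridge, AdaBoost-DT, k-neighbors) that join
the HNN in the seven-model consensus (arithmetic mean). Scale-sensitive
regressors are pipelined behind a training-fold z-score; tree models consume
raw descriptors. The binary ensemble is soft voting — the mean of the four
member probabilities thresholded at 0.5 (a mean of exactly 0.5 is toxic) —
chosen over hard majority because four voters tie; hard voting is available
as an option.

## Virtual mixtures

`disjoint_pairing` shuffles a pool with the seed and pairs consecutive ids:
floor(n/2) pairs, each chemical used at most once. `sample_combinations`
draws unordered pairs uniformly without replacement by vectorised rejection
sampling (pairs are normalised lexicographically; an exclusion set is
honoured and the available-pair count is reported when a request is
infeasible). The stratified dataset builder draws toxic+toxic,
nontoxic+nontoxic, and mixed strata with per-stratum seeds derived from the
base seed; labels follow the case hypothesis (only nontoxic+nontoxic is 0).
Tanimoto filtering keeps chemicals whose maximum similarity
`|a∧b|/|a∨b|` to any reference strictly exceeds the threshold (0.6 default);
zero fingerprints get similarity 0 with a warning. The fingerprint backend
is configurable (2048-bit Morgan radius 2 via RDKit for real chemistry;
random bit vectors from the synthetic generator otherwise).

## Combined scoring

The total score is the exact sum of four components each normalised to 1:
the binary call (0/1), the categorical score for the hazard group
(1 → 1, 2A → 0.75, 2B → 0.5, 3 → 0.25, 4 → 0), the potency score for the
daily dose (<100 mg/kg/day → 1; then 0.75/0.5/0.25 down to 0 at
≥1500 mg/kg/day; boundary doses join the more-toxic band, a choice made
because the printed bands leave exact boundaries unassigned), and the
externally supplied pathophysiology Z score. With Z ≤ 1 the total is
bounded by 4. Z scores are consumed as given; optional normalisation is
min–max over the scored batch. The single-addend workflow (binary
prediction adds 1 to Z) is the same code path with categorical = potency
= 0. Ranking is by descending total with deterministic id tie-breaks;
top-k retrieval is the percentage of known-toxic items among the k
highest-ranked.

## Evaluation protocols

Random hold-out uses floor(0.2 n) test items, reseeded per iteration from
the base seed (30 iterations by default; the reported mean is the plain
arithmetic mean of per-iteration metrics). Stratified k-fold keeps per-fold
class counts within ±1 of proportional. Compound-out splits place every
mixture containing a held-out chemical in the test set, so the training
mixtures' chemical set is disjoint from the held-out set by construction.
Metrics are confusion-matrix definitions plus a rank-based (Mann–Whitney)
AUC with ties counted 0.5 — cross-checked in tests against an independent
scipy Mann–Whitney oracle; multiclass metrics pool one-vs-rest decisions
over all (item, class) pairs (micro-averaging). Undefined quantities
(single-class AUC, zero-variance R²) are reported as missing with warnings,
never silently imputed. Agreement percentages are emitted exact, to one
decimal, and as half-up integers.

The packaged 37-row zebrafish validation table is transcribed verbatim from
the source experiments; recomputing agreement between its combined-score
column and the experimental column gives 30/37 = 81.1% → 81%.

## Zebrafish phenotype scoring

Fish are scored 0 (dead) to 4 (normal); a five-fish well sums to 0–20 and
replicate wells average to the condition score. Wells with fewer fish scale
to 4×n_fish; dead fish are genuine zeros, never imputed. The interaction
call compares the combined condition score `c` with the singles
(`m = min(s1, s2)`, additive expectation `E = max(0, s1 + s2 − scale_max)`):
within `margin` (default 1.0) of `m` → no interaction; above → antagonistic;
below, synergistic if `c < E − margin`, additive otherwise — except that
when `E` itself lies within the no-interaction band the drop cannot be
attributed and the call is inconclusive. Only the label set and the worked
example (singles 17 and 15, combined 15 → no interaction) are fixed by the
source; the numeric boundaries are this package's reconstruction, the
margin is configurable, and calls other than the worked example are not
asserted against external data. The developmental-toxicity EC50 utility
returns the dose at which the monotone score curve crosses 5, linearly
interpolated between tested doses.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, not
chemistry: toxic and non-toxic chemicals draw descriptors from Gaussians
with means ±effect_size/2 (unit variance per descriptor; optional
equicorrelation adds collinearity), potencies are log-normal per class
(log10 mg/L means 0.5 toxic / 3.0 non-toxic, σ 0.4 — chosen so labels agree
with the 100 mg/L rule for ≥99% of draws by the normal tail bound, and
verified empirically over 10,000 draws), SMILES are random tokenizable
strings over a fixed alphabet, and fingerprints are random bits. Mixture
sets are labelled by the case hypothesis or through the CA model (equal
mass fractions, harmonic EC50_mix, 100 mg/L cutoff), the latter giving
regression a recoverable ground truth.

Passing the synthetic benchmarks therefore shows that the pipeline learns a
planted descriptor signal, is seed-reproducible, and behaves at chance when
no signal exists (accuracy within 3 SE of 0.5 at effect size 0). It does
not show generalisation to real chemical structure–toxicity relationships:
synthetic SMILES carry no signal, descriptor distributions are idealised
Gaussians, and real mixture data exhibit class imbalance, measurement noise,
and applicability-domain effects the generator does not model.

## Problem sizes

The verification suite trains the neural model on 400-chemical pools with
10 descriptors at 20 epochs and exercises the full-scale dataset
construction (22,682-chemical pools, 150,000 sampled pairs); the whole
suite runs in well under a minute on one CPU, and the reproduction script
in a few seconds. Larger corpora and the 50-epoch default are supported
unchanged; sizes here were picked as the smallest that make the statistical
assertions (≥0.9 separable accuracy, ±3 SE null band) well-powered.

## Known limitations

* Only binary mixtures are validated; the CA formulas accept more
  components but >2-component behaviour is untested against external data.
* Independent action is a flag, not a full response-addition model.
* The descriptor backend ships with RDKit 2D descriptors; 3D/ADME
  descriptors are out of scope (the interface accepts any per-chemical
  matrix).
* The pathophysiology Z score is an input, not computed here.
* Published full-scale model accuracies depend on a literature mixture
  corpus and hyperparameters that are not distributable with this package;
  they are deliberately not asserted.
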