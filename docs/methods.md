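# Methods

## Problem setting

The package operates on weekly surveillance series: eight weather factors
(MaxT, MinT in °C; RH1, RH2 in %; RF in mm; WS in km/h; SSH in hours; EVP in
mm) and a non-negative pest value per week. Occurrence is the binary event
`pest_value > 0`; this thresholding convention is applied uniformly (the
generator, the CSV loader and the windowing all derive occurrence from the
value, never store it separately). Forecasting is posed as binary
classification of next week's occurrence from the preceding weeks' records;
rule mining is posed over the same weeks discretized into interval labels.

## Discretization

Each feature is clustered on its own with Lloyd's algorithm
(`kmeans_1d`). Initialization is deterministic — centroid *j* starts at the
(j+½)/k quantile — because for one-dimensional data this is reproducible and
close to optimal, making random restarts unnecessary; the tests confirm the
result attains the exact contiguous-partition optimum (computed by dynamic
programming) on band-structured data. Ties in assignment go to the lower
centroid. A cluster left empty — possible only when k exceeds the number of
natural plateaus — is refilled deterministically with the point farthest
from its current centroid, so every interval of the resulting scheme is
non-empty.

A clustering becomes a scheme of k left-open/right-closed intervals whose
interior boundaries are the *maximum observed value of the lower cluster*;
this guarantees that adjacent intervals share endpoints exactly and every
training value maps back into its own cluster's interval. The covered range
starts at 0 (all factors are non-negative) and ends at the observed maximum.
Values at a boundary belong to the lower interval; values outside the fitted
range are clamped to the extreme intervals rather than rejected, since only
synthetic or held-out data can fall there.

The number of intervals is chosen by `select_k`: for each candidate k, the
pooled transactions are mined and the rules whose consequent is `{P}` are
counted; the k with the most such rules wins, ties to the smallest k. The
package also ships `reference_scheme()`, the fixed k=3 scheme reported for
the pooled Crop Pest DSS cotton corpus, used as a known-good fixture. Its
printed SSH top interval is non-monotone (an evident typo); the corrected
boundary 8.03 shared with the middle interval is used.

## Association rule mining

`apriori_frequent_itemsets` is a textbook level-wise Apriori: frequent
(k−1)-itemsets sharing a (k−2)-prefix under lexicographic item order are
joined, candidates with an infrequent subset are pruned
(anti-monotonicity), and supports are counted exactly — transactions are
encoded as integer bitmasks so a subset test is one AND. The alphabet is at
most 24 interval labels plus `P`, so exact counting is cheap.
`generate_rules` emits every antecedent/consequent split of every frequent
itemset with confidence ≥ minconfidence; a rule's reported support is the
joint support n_AB/n. `filter_pest_rules` then keeps exactly the rules with
consequent `{P}` — the two-step contract keeps the miner generic.
`item_probabilities` summarises the antecedents of a rule list as relative
item frequencies (each antecedent slot counts once, so they sum to 1).
Defaults are minsupport 0.05 and minconfidence 0.5.

## The forecaster

Windows of `timesteps = 4` consecutive weeks predict occurrence at the week
immediately after the window — strictly future, so the pest-value feature
can never leak the label. Features (8 weather, plus the pest value as a 9th
unless the ablation flag drops it) are standardized per feature using
statistics of the rows feeding the chronological training windows only.

The recurrent cell computes, with σ the logistic function and ⊙ elementwise
product over the concatenation z = [h_{t−1}, x_t]:

    i = σ(W_i z + b_i),  f = σ(W_f z + b_f),  o = σ(W_o z + b_o),
    g = tanh(W_c z + b_c),  C_t = f ⊙ C_{t−1} + i ⊙ g,  h_t = o ⊙ tanh(C_t).

The last hidden vector passes through dropout (rate 0.1, inverted scaling,
applied in training only), a 5-unit ReLU layer and a single sigmoid unit.
The ReLU choice for the hidden head layer is the package's own; only the
final sigmoid is dictated by the binary target. The loss is the full
two-term binary cross-entropy −mean[y log p + (1−y) log(1−p)] with
predictions clipped at 1e−7 for evaluation; gradients are computed
analytically through the unrolled cell (BPTT) and checked against central
finite differences to better than 1e−5 relative error per parameter block.

Optimizers: plain SGD (θ ← θ − ηg) and RMSProp
(v ← γv + (1−γ)g², θ ← θ − ηg/(√v + ε)). RMSProp is the default with
η = 0.001, γ = 0.9, ε = 1e−8 (the ε stabiliser is required to avoid
division by zero at v = 0 and is the package's choice). Training uses
seeded uniform(−0.1, 0.1) initialization with the forget-gate bias at 1.0
(a standard stabiliser for short sequences), mini-batches of 32, up to 200
epochs with early stopping after 20 epochs without training-loss
improvement. One seed drives initialization, shuffling and dropout masks,
so runs are bit-reproducible. The architecture defaults — one recurrent
layer, 5 units, [5, 1] head — are the reference configuration; layer count,
unit counts and optimizer are configurable.

## Evaluation

`chronological_split` takes the first ⌊0.75·n⌋ items for training with no
shuffling (for n = 1196 this gives 897/299; floor is only visible when
0.75·n is not integral). ACC = (TP+TN)/(P+N); F1 = 2TP/(P+P′) with
P = TP+FN, P′ = TP+FP, algebraically the harmonic mean of precision and
recall (tested as an identity); when P+P′ = 0, F1 is defined as 0 with a
warning. AUC is the rank statistic (Σ_{i∈pos} rank_i − M(M+1)/2)/(M·N) with
average ranks for ties, which equals the Mann–Whitney concordance
probability crediting half a win per tie — verified against a pairwise
counting oracle to 1e−12. The ROC curve places a point at every distinct
score threshold, anchored at (0,0) and (1,1); its trapezoidal area equals
the rank AUC exactly. Hard labels use the `score ≥ 0.5` convention.

## Synthetic data: what it emulates, and what it does not

The generator produces the *statistical shape* the pipeline assumes, not any
real climate or pest biology:

* **Weather** — each factor is an annual sinusoid (period 52 weeks) plus
  Gaussian noise, clipped to the factor's plausible range. Means and
  amplitudes are fixed so that each factor populates three bands (making a
  k=3 clustering recoverable); MaxT and MinT share amplitude and phase so
  their difference is constant absent noise, humidity and rainfall lag
  temperature by a quarter year, and wind/evaporation run in anti-phase.
* **Occurrence** — the latent probability at week t is
  clamp(base_rate + max matching rule confidence + persistence·y_{t−1}, 0, 1),
  where a planted rule matches when its antecedent labels are a subset of
  the week's discretized weather. The clamp is simple truncation, not a
  logistic link — sufficient for planted-rate recovery and easier to reason
  about. Persistence is applied to the latent chain; the independent
  label-flip noise corrupts the final labels (and hence the pest values the
  model later sees). Pest magnitude on occurrence weeks is 1 + Poisson(3);
  the model consumes it as a numeric feature, so only positivity matters.
* **Baskets** — for isolated mining tests, transactions carry a planted
  antecedent with probability support/confidence and, conditionally, `P`
  with probability confidence; items outside every rule fill in
  independently at a background rate (default 0.1), so the planted rule's
  empirical support and confidence concentrate on their targets (within ~3
  binomial standard errors at n = 20,000).

Passing tests therefore demonstrate *recovery of planted structure under
the model's own assumptions* — they do not establish performance on real
surveillance data, whose weather is not sinusoidal, whose outbreak dynamics
are richer than a first-order persistence term, and whose measurement error
is not independent label flipping.

A consequence worth stating explicitly: symmetric label-flip noise at rate
ρ bounds the achievable AUC, because flipped labels are independent of every
feature. Even a scorer using the exact generative probabilities attains
roughly (1−ρ)² + ρ(1−ρ) ≈ 0.95 at ρ = 0.05 under class balance, and less
when genuinely stochastic intermediate states exist. On the default
strong-signal series (rule confidence 0.9, persistence 0.8, 5% noise) the
trained network's held-out AUC (~0.91) matches the generative-probability
scorer's (~0.90) on the same split; with the noise removed it exceeds 0.96.

## Problem sizes and numerical choices

Experiments in the tests and the acceptance script use 520–1,200-week
series and 20,000-transaction basket sets — the same order as real weekly
corpora (decades of records per site) — with up to 200 training epochs;
each complete experiment runs in seconds on one CPU core. Floating point is
float64 throughout. K-means stops when centroid movement falls below 1e−9
or after 300 iterations. Support/confidence thresholds are compared with
`>=` on the exact ratio evaluated in floating point. Finite-difference
gradient checks keep biases away from the ReLU kink, where one-sided
derivatives make central differences invalid.

## Known limitations

* Single-site, single-pest series; no pooling across locations beyond
  concatenating transactions for rule mining.
* No calibration of predicted probabilities; the 0.5 threshold is a
  convention, not an optimum.
* The miner enumerates all antecedent splits, which is exponential in
  itemset size — fine for ≤ 25 items, unsuitable for open-ended alphabets.
* `kmeans_1d` is Lloyd's algorithm: globally optimal on well-separated 1-D
  bands (verified against the DP optimum) but not guaranteed so in general.
* Baseline classifiers (nearest-neighbour, SVM, random forests) are out of
  scope; the package evaluates only the LSTM forecaster.
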