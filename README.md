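# pestcast

Weather-driven analysis and forecasting of crop pest and disease occurrence
from weekly surveillance records.

Crop protection programmes collect weekly tables of weather factors —
maximum/minimum temperature (MaxT, MinT, °C), morning/evening relative
humidity (RH1, RH2, %), rainfall (RF, mm), wind speed (WS, km/h), sunshine
hours (SSH) and evaporation (EVP, mm) — alongside a pest count or incidence
value. `pestcast` answers two questions a plant-protection analyst asks of
such data:

1. **Which weather conditions accompany outbreaks?**  Each weather factor is
   discretized into *k* ordered intervals by one-dimensional K-means
   (labelled `A1..A3` for MaxT through `H1..H3` for EVP), each week becomes a
   transaction of interval labels plus the occurrence marker `P`, and a
   from-scratch Apriori miner extracts association rules `A → P` measured by

   * support(A→P) = n_AP / n (joint frequency), and
   * confidence(A→P) = n_AP / n_A (conditional frequency),

   keeping rules above a minimum support (default 0.05) and confidence
   (default 0.5) whose consequent is pest occurrence.

2. **Will pests occur next week?**  A small LSTM — one recurrent layer of 5
   units with the standard input/forget/output gates and memory vector C_t,
   followed by a [5, 1] fully-connected head with dropout 0.1 — reads sliding
   windows of 4 consecutive weeks (8 weather features plus the pest value as
   a 9th) and outputs P(occurrence in the following week). Training minimises
   binary cross-entropy with exact backpropagation-through-time gradients and
   RMSProp (v ← γv + (1−γ)g²; θ ← θ − ηg/(√v + ε)). Evaluation uses a strict
   chronological split (first 75% train, last 25% test) and reports
   ACC = (TP+TN)/(P+N), F1 = 2TP/(P+P′), and the rank-statistic AUC
   (Σ ranks of positives − M(M+1)/2)/(M·N) — the Mann–Whitney concordance
   probability, with average ranks for ties.

Everything scientific — the 1-D K-means, the Apriori miner, the LSTM with
its gradients and optimizers, the rank AUC — is implemented from first
principles in numpy and validated in the test suite against independent
oracles (exhaustive enumeration, dynamic programming, finite differences,
pairwise concordance counting). Because real surveillance corpora are not
redistributable, the package ships a synthetic generator that emulates their
statistical shape with *known planted structure* (seasonal sinusoidal
weather, rule-driven occurrence with configurable confidence, outbreak
persistence and label noise), so every stage can be tested for recovery of
ground truth.

## Worked example

Recover a planted rule with the mining stage
(`python examples/mine_association_rules.py`):

```
mined 180 rules, 15 with consequent {P}
...
planted rule recovery: confidence 0.8677 (truth 0.8592), support 0.0915 (truth 0.0927)
```

20,000 transactions were generated so that the antecedent {A2, B3, D3, F1}
(warm days, warm nights, humid evenings, low wind) appears in 10.79% of
weeks and, when it does, pests follow 85.92% of the time. The miner reports
the rule at confidence 0.8677 and support 0.0915 — both within sampling
error of the planted truth.

Forecast occurrence end-to-end (`python examples/forecast_occurrence.py`):

```
test windows: 299 (154 with pest occurrence)
confusion: TP=130 TN=125 FP=20 FN=24
ACC = 0.8528   F1 = 0.8553   AUC = 0.9060
```

The 1,200-week series plants a weather rule at confidence 0.9 with outbreak
persistence 0.8 and 5% label-flip noise; the LSTM, trained on the first 897
windows, ranks a random pest week above a random pest-free week 90.6% of the
time on the held-out final quarter. (The label noise alone caps the
attainable AUC: a scorer with perfect knowledge of the generative
probabilities reaches 0.904 on the same split.)

Quantify the value of pest history (`python examples/pest_history_ablation.py`):

```
9 features (with pest history): ACC=0.9138 F1=0.9438 AUC=0.9085
8 features (weather only)  : ACC=0.6322 F1=0.7009 AUC=0.6716
```

A command-line interface mirrors the library:
`pestcast simulate|rules|forecast|evaluate --config cfg.yaml --seed N --out PATH`.

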