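"""Synthetic weather-pest series and transaction sets with planted structure.

The generator emulates the statistical shape of weekly crop-pest surveillance
data (such as the Crop Pest Decision Support System cotton records) without
imitating any real regional climate:

* each weather factor follows an annual sinusoid (period 52 weeks) plus
  Gaussian noise, clipped to the value range observed for that factor in the
  pooled corpus, with means and amplitudes chosen so that a k=3 per-feature
  clustering finds three populated bands;
* pest occurrence is driven by *planted* association rules over the
  discretized weather — when a rule's antecedent labels are all present in a
  week's transaction, occurrence fires with the rule's confidence — plus a
  persistence term carrying over the previous week's state (outbreaks are
  self-sustaining) and an optional symmetric label-flip noise;
* independent "basket" transaction sets carry a planted rule at an exact
  target support/confidence for testing the mining stage in isolation.

Because the planted structure is known, every downstream stage (clustering,
mining, forecasting) can be tested for recovery of ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (CSV_COLUMNS, PEST_ITEM, PEST_VALUE_COLUMN,
                        WEATHER_FEATURES, WEEK_COLUMN, PestDataset,
                        PlantedRule)
from .discretize import DiscretizationScheme, discretize_dataset
from .errors import ConfigurationError, InvalidArgumentError

__all__ = [
    "FEATURE_UPPER", "SEASONAL_PROFILE", "EXAMPLE_CPDSS_RULE",
    "default_item_universe", "generate_weather_series",
    "generate_pest_labels", "generate_basket_data",
]

#: Upper end of the observed value range per feature (pooled corpus).
FEATURE_UPPER: dict[str, float] = {
    "MaxT": 46.60, "MinT": 32.20, "RH1": 97.30, "RH2": 90.40,
    "RF": 602.00, "WS": 71.40, "SSH": 12.70, "EVP": 72.00,
}

#: (mean, amplitude, phase in weeks, default noise SD) of the annual
#: sinusoid per feature.  MaxT and MinT share amplitude and phase so their
#: difference is constant in the noise-free case; humidity/rainfall peak a
#: quarter-year after temperature (a monsoon-like lag); wind, sunshine and
#: evaporation run in anti-phase with humidity.
SEASONAL_PROFILE: dict[str, tuple[float, float, float, float]] = {
    "MaxT": (30.0, 10.0, 0.0, 1.5),
    "MinT": (17.0, 10.0, 0.0, 1.5),
    "RH1": (70.0, 18.0, 13.0, 4.0),
    "RH2": (52.0, 24.0, 13.0, 5.0),
    "RF": (30.0, 55.0, 13.0, 12.0),
    "WS": (14.0, 9.0, 26.0, 2.0),
    "SSH": (7.0, 3.5, 39.0, 0.7),
    "EVP": (14.0, 9.0, 26.0, 2.5),
}

#: The published pooled-corpus rule "A2,B3,D3,F1 -> P" (warm days, warm
#: nights, humid evenings, low wind) with its reported joint support and
#: confidence; used as planted ground truth in recovery experiments.
EXAMPLE_CPDSS_RULE = PlantedRule(
    frozenset({"A2", "B3", "D3", "F1"}),
    target_support=0.0927, target_confidence=0.8592)

_PERIOD_WEEKS = 52.0


def default_item_universe(k: int = 3) -> frozenset[str]:
    """All interval labels for the eight features plus the occurrence item."""
    labels = {f"{letter}{i + 1}"
              for letter in "ABCDEFGH" for i in range(k)}
    labels.add(PEST_ITEM)
    return frozenset(labels)


def _resolve_noise(noise_sd) -> dict[str, float]:
    if noise_sd is None:
        return {f: SEASONAL_PROFILE[f][3] for f in WEATHER_FEATURES}
    if np.isscalar(noise_sd):
        return {f: float(noise_sd) for f in WEATHER_FEATURES}
    missing = [f for f in WEATHER_FEATURES if f not in noise_sd]
    if missing:
        raise InvalidArgumentError(f"noise_sd missing features {missing}")
    return {f: float(noise_sd[f]) for f in WEATHER_FEATURES}


def generate_weather_series(n_weeks: int, seed: int = 0, noise_sd=None,
                            *, location: str = "synthetic",
                            pest_name: str = "synthetic") -> PestDataset:
    """Generate a weekly weather series with zeroed pest columns.

    Parameters
    ----------
    n_weeks : number of weekly records (>= 1).
    seed : RNG seed; the output is byte-identical for equal seeds.
    noise_sd : None for the per-feature defaults, a scalar applied to every
        feature, or a mapping feature name -> SD.  0 gives pure sinusoids.
    """
    if n_weeks < 1:
        raise InvalidArgumentError(f"n_weeks must be >= 1, got {n_weeks}")
    sds = _resolve_noise(noise_sd)
    rng = np.random.default_rng(seed)
    weeks = np.arange(n_weeks)
    data = {WEEK_COLUMN: weeks}
    for name in WEATHER_FEATURES:
        mean, amp, phase, _ = SEASONAL_PROFILE[name]
        signal = mean + amp * np.sin(2.0 * np.pi * (weeks + phase) / _PERIOD_WEEKS)
        signal = signal + rng.normal(0.0, sds[name], size=n_weeks)
        data[name] = np.clip(signal, 0.0, FEATURE_UPPER[name])
    # noise can cross the two temperature series; restore max_t >= min_t
    data["MinT"] = np.minimum(data["MinT"], data["MaxT"])
    data[PEST_VALUE_COLUMN] = np.zeros(n_weeks)
    frame = pd.DataFrame(data, columns=list(CSV_COLUMNS))
    ds = PestDataset(frame, location, pest_name)
    ds.validate()
    return ds


def generate_pest_labels(ds: PestDataset, scheme: DiscretizationScheme,
                         rules, persistence: float = 0.0,
                         base_rate: float = 0.0, label_noise: float = 0.0,
                         seed: int = 0, *, outbreak_mean: float = 3.0
                         ) -> PestDataset:
    """Attach pest occurrence driven by planted rules over discretized weather.

    The latent occurrence probability at week t is

        clamp(base_rate + max matching rule confidence
              + persistence * occurrence(t-1), 0, 1)

    where a rule matches when its antecedent labels are a subset of the
    week's discretized weather.  After the latent chain is drawn, every label
    is flipped independently with probability ``label_noise``, and the pest
    value for occurrence weeks is ``1 + Poisson(outbreak_mean)`` (any
    positive magnitude marks occurrence).
    """
    for name, p in (("persistence", persistence), ("base_rate", base_rate),
                    ("label_noise", label_noise)):
        if not 0.0 <= p <= 1.0:
            raise InvalidArgumentError(f"{name} must be in [0, 1], got {p}")
    scheme.require()  # raises ConfigurationError when a feature is missing
    rules = list(rules)
    for r in rules:
        if not isinstance(r, PlantedRule):
            raise InvalidArgumentError("rules must be PlantedRule instances")

    transactions = discretize_dataset(ds, scheme, include_pest=False)
    match_conf = np.zeros(len(ds))
    for i, t in enumerate(transactions):
        confs = [r.target_confidence for r in rules
                 if r.antecedent_items <= t]
        if confs:
            match_conf[i] = max(confs)

    rng = np.random.default_rng(seed)
    n = len(ds)
    latent = np.zeros(n, dtype=int)
    u = rng.random(n)
    prev = 0
    for t in range(n):
        p = min(1.0, max(0.0, base_rate + match_conf[t] + persistence * prev))
        latent[t] = int(u[t] < p)
        prev = latent[t]
    occurrence = latent.copy()
    if label_noise > 0.0:
        flips = rng.random(n) < label_noise
        occurrence = np.where(flips, 1 - occurrence, occurrence)
    magnitude = 1.0 + rng.poisson(outbreak_mean, size=n)
    pest_value = np.where(occurrence == 1, magnitude, 0.0)
    return ds.with_pest(pest_value)


def generate_basket_data(n: int, rules, item_universe=None, seed: int = 0,
                         *, background_rate: float = 0.1
                         ) -> list[frozenset[str]]:
    """Generate transactions carrying planted rules at exact target rates.

    Each transaction contains a rule's full antecedent with probability
    ``target_support / target_confidence`` and, conditional on the antecedent
    being present, the occurrence item ``P`` with probability
    ``target_confidence`` — so the empirical support and confidence of the
    planted rule concentrate on their targets.  Items outside every rule
    (and not ``P``) are filled in independently at ``background_rate``.
    """
    if n < 1:
        raise InvalidArgumentError(f"n must be >= 1, got {n}")
    if not 0.0 <= background_rate <= 1.0:
        raise InvalidArgumentError("background_rate must be in [0, 1]")
    rules = list(rules)
    universe = frozenset(item_universe) if item_universe is not None \
        else default_item_universe()
    rule_items: set[str] = set()
    for r in rules:
        if not isinstance(r, PlantedRule):
            raise InvalidArgumentError("rules must be PlantedRule instances")
        if not r.antecedent_items <= universe:
            raise InvalidArgumentError(
                f"antecedent {sorted(r.antecedent_items)} not in item universe")
        rule_items |= r.antecedent_items

    background = sorted(universe - rule_items - {PEST_ITEM})
    rng = np.random.default_rng(seed)
    transactions = [set() for _ in range(n)]

    pest = np.zeros(n, dtype=bool)
    for r in rules:
        present = rng.random(n) < (r.target_support / r.target_confidence)
        fires = rng.random(n) < r.target_confidence
        pest |= present & fires
        ante = sorted(r.antecedent_items)
        for i in np.nonzero(present)[0]:
            transactions[i].update(ante)
    if background:
        bg = rng.random((n, len(background))) < background_rate
        for i in range(n):
            row = bg[i]
            if row.any():
                transactions[i].update(
                    item for item, hit in zip(background, row) if hit)
    for i in np.nonzero(pest)[0]:
        transactions[i].add(PEST_ITEM)
    return [frozenset(t) for t in transactions]
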