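"""Configuration, CSV I/O and the two end-to-end experiments.

``run_association_analysis`` chains discretize -> mine -> filter -> report;
``run_forecast_experiment`` chains window -> chronological split -> train ->
evaluate.  Both are driven by a single :class:`PipelineConfig` whose defaults
reproduce the reference settings used throughout the package (k=3 intervals,
minsupport 0.05, minconfidence 0.5, timesteps 4, one 5-unit LSTM layer with a
[5, 1] head, dropout 0.1, RMSProp, 3/4-1/4 chronological split), and both
write a machine-readable provenance record next to their outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import numpy as np

from .datatypes import (CSV_COLUMNS, PEST_VALUE_COLUMN, WEATHER_FEATURES,
                        WEEK_COLUMN, PestDataset, PlantedRule)
from .discretize import discretize_dataset, fit_scheme, select_k
from .errors import DataError, SchemaError
from .lstm import TrainingConfig, make_windows, predict, train
from .metrics import EvaluationReport, chronological_split, \
    evaluate_predictions
from .mining import (filter_pest_rules, item_probabilities, mine_rules,
                     write_rule_report)
from .synthetic import generate_pest_labels, generate_weather_series

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticBlock", "DiscretizationBlock", "ModelBlock", "EvaluationBlock",
    "PipelineConfig", "load_cpdss_csv", "synthesize_dataset",
    "run_association_analysis", "run_forecast_experiment",
]

_PEST_ALIASES = ("pestvalue", "pest value", "pest_value")


@dataclass
class SyntheticBlock:
    """Parameters of the synthetic weather-pest generator.

    The defaults plant a single seasonal rule — hot weeks (top temperature
    bands A3, B3) breed pests with confidence 0.9 — on a 10-year weekly
    series, with outbreak persistence 0.8, a 2% background occurrence rate
    and 5% label noise.
    """

    n_weeks: int = 520
    rules: list[dict] = field(default_factory=lambda: [
        {"antecedent": ["A3", "B3"], "support": 0.25, "confidence": 0.9}])
    persistence: float = 0.8
    base_rate: float = 0.02
    label_noise: float = 0.05
    noise_sd: float | None = None

    def planted_rules(self) -> list[PlantedRule]:
        return [PlantedRule(frozenset(r["antecedent"]), r["support"],
                            r["confidence"]) for r in self.rules]


@dataclass
class DiscretizationBlock:
    k: int = 3
    k_candidates: list[int] | None = None
    minsupport: float = 0.05
    minconfidence: float = 0.5


@dataclass
class ModelBlock:
    timesteps: int = 4
    units: int = 5
    n_layers: int = 1
    fc_hidden: int = 5
    dropout: float = 0.1
    optimizer: str = "rmsprop"
    learning_rate: float = 0.001
    gamma: float = 0.9
    epochs: int = 200
    batch_size: int = 32
    include_pest_history: bool = True


@dataclass
class EvaluationBlock:
    train_fraction: float = 0.75
    threshold: float = 0.5


@dataclass
class PipelineConfig:
    input_csv: str | None = None
    seed: int = 0
    synthetic: SyntheticBlock = field(default_factory=SyntheticBlock)
    discretization: DiscretizationBlock = field(
        default_factory=DiscretizationBlock)
    model: ModelBlock = field(default_factory=ModelBlock)
    evaluation: EvaluationBlock = field(default_factory=EvaluationBlock)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc or {})
        blocks = {
            "synthetic": SyntheticBlock,
            "discretization": DiscretizationBlock,
            "model": ModelBlock,
            "evaluation": EvaluationBlock,
        }
        kwargs = {}
        for key, klass in blocks.items():
            kwargs[key] = klass(**doc.pop(key, {}))
        kwargs["input_csv"] = doc.pop("input_csv", None)
        kwargs["seed"] = int(doc.pop("seed", 0))
        if doc:
            raise DataError(f"unknown config keys {sorted(doc)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_cpdss_csv(path, *, location: str | None = None,
                   pest_name: str | None = None) -> PestDataset:
    """Load a weekly weather-pest CSV.

    The header must contain the eight weather columns and a pest-value
    column, matched case-insensitively (``PestValue``, ``pest value`` and
    ``pest_value`` are accepted).  Rows are taken in file order as
    consecutive weeks; rows with any non-numeric field are dropped with a
    logged count.
    """
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: file is empty") from None
    lower = {c.lower().strip(): c for c in raw.columns}
    mapping = {}
    for feature in WEATHER_FEATURES:
        if feature.lower() not in lower:
            raise SchemaError(f"{path}: missing required column {feature!r}")
        mapping[lower[feature.lower()]] = feature
    pest_col = next((lower[a] for a in _PEST_ALIASES if a in lower), None)
    if pest_col is None:
        raise SchemaError(f"{path}: missing required pest value column "
                          f"(one of {_PEST_ALIASES})")
    mapping[pest_col] = PEST_VALUE_COLUMN
    frame = raw.rename(columns=mapping).loc[:, [*WEATHER_FEATURES,
                                                PEST_VALUE_COLUMN]]
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        logger.warning("%s: dropped %d row(s) with non-numeric fields",
                       path, int(bad.sum()))
    numeric = numeric.loc[~bad].reset_index(drop=True)
    if numeric.empty:
        raise DataError(f"{path}: no valid data rows")
    numeric.insert(0, WEEK_COLUMN, np.arange(len(numeric)))
    return PestDataset(numeric[list(CSV_COLUMNS)],
                       location or str(path), pest_name or "unknown")


def synthesize_dataset(config: PipelineConfig) -> PestDataset:
    """Generate weather, fit a scheme on it, then plant pest labels."""
    syn = config.synthetic
    weather = generate_weather_series(syn.n_weeks, seed=config.seed,
                                      noise_sd=syn.noise_sd)
    scheme = fit_scheme(weather, k=config.discretization.k)
    return generate_pest_labels(
        weather, scheme, syn.planted_rules(), persistence=syn.persistence,
        base_rate=syn.base_rate, label_noise=syn.label_noise,
        seed=config.seed + 1)


def _load_or_synthesize(config: PipelineConfig) -> PestDataset:
    if config.input_csv:
        return load_cpdss_csv(config.input_csv)
    return synthesize_dataset(config)


def _write_provenance(out_dir: Path, config: PipelineConfig,
                      stages: dict) -> None:
    doc = {"config": config.to_dict(), "seed": config.seed, "stages": stages}
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(doc, fh, indent=2)


def run_association_analysis(config: PipelineConfig, out_dir):
    """Discretize -> mine -> filter to pest-consequent rules -> report.

    Writes ``rules.csv``, ``item_probabilities.json`` and
    ``provenance.json`` into ``out_dir`` and returns the pest rules.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    disc = config.discretization
    ds = _load_or_synthesize(config)
    logger.info("association analysis on %d weekly records", len(ds))

    if disc.minsupport > 1.0:
        logger.warning("minsupport %.3f > 1: no itemset can qualify; "
                       "writing an empty report", disc.minsupport)
        pest_rules = []
        chosen_k = disc.k
    else:
        if disc.k_candidates:
            by_k = {k: discretize_dataset(ds, fit_scheme(ds, k))
                    for k in disc.k_candidates}
            chosen_k = select_k(by_k, disc.minsupport, disc.minconfidence)
            logger.info("select_k chose k=%d from %s", chosen_k,
                        disc.k_candidates)
        else:
            chosen_k = disc.k
        scheme = fit_scheme(ds, chosen_k)
        with open(out_dir / "scheme.json", "w") as fh:
            fh.write(scheme.to_json())
        transactions = discretize_dataset(ds, scheme)
        rules = mine_rules(transactions, disc.minsupport, disc.minconfidence)
        pest_rules = filter_pest_rules(rules)
        logger.info("mined %d rules, %d with pest consequent",
                    len(rules), len(pest_rules))

    write_rule_report(pest_rules, out_dir / "rules.csv")
    probs = item_probabilities(pest_rules) if pest_rules else {}
    with open(out_dir / "item_probabilities.json", "w") as fh:
        json.dump(probs, fh, indent=2)
    _write_provenance(out_dir, config, {
        "n_records": len(ds), "k": chosen_k,
        "n_pest_rules": len(pest_rules)})
    return pest_rules


def run_forecast_experiment(config: PipelineConfig, out_dir
                            ) -> EvaluationReport:
    """Window -> chronological split -> train -> evaluate on the test tail.

    Writes ``metrics.json``, ``checkpoint.json`` and ``provenance.json``
    into ``out_dir`` and returns the evaluation report.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = config.model
    ev = config.evaluation
    ds = _load_or_synthesize(config)
    windowed = make_windows(ds, timesteps=model.timesteps,
                            include_pest_history=model.include_pest_history,
                            standardize_fraction=ev.train_fraction)
    logger.info("windowed %d records into %d samples with %d features",
                len(ds), len(windowed), windowed.n_features)
    train_w, test_w = chronological_split(windowed, ev.train_fraction)
    tc = TrainingConfig(
        learning_rate=model.learning_rate, gamma=model.gamma,
        batch_size=model.batch_size, epochs=model.epochs,
        dropout=model.dropout, optimizer=model.optimizer, seed=config.seed,
        units=model.units, n_layers=model.n_layers,
        fc_hidden=model.fc_hidden)
    params, history = train(train_w, tc)
    _, scores = predict(params, test_w, ev.threshold)
    report = evaluate_predictions(test_w.labels, scores, ev.threshold)
    logger.info("test metrics: acc=%.4f f1=%.4f auc=%.4f",
                report.acc, report.f1, report.auc)

    report.to_json(out_dir / "metrics.json")
    params.save(out_dir / "checkpoint.json")
    _write_provenance(out_dir, config, {
        "n_records": len(ds), "n_windows": len(windowed),
        "n_features": windowed.n_features,
        "n_train": len(train_w), "n_test": len(test_w),
        "epochs_run": len(history),
        "final_train_loss": history[-1] if history else None})
    return report
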