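"""Core containers for weekly weather-pest records.

A record is one week of field observations: eight weather factors (maximum and
minimum temperature, morning and evening relative humidity, rainfall, wind
speed, sunshine hours, evaporation) plus a non-negative pest value (count or
incidence).  Pest *occurrence* is the binary event ``pest_value > 0`` and is
always derived from the value, never stored independently, so the two can
never disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import DataError, InvalidArgumentError

#: Canonical order of the eight weather features.
WEATHER_FEATURES: tuple[str, ...] = (
    "MaxT", "MinT", "RH1", "RH2", "RF", "WS", "SSH", "EVP",
)

#: Single-letter code used for interval labels (A1..H3) in transactions.
FEATURE_LETTERS: dict[str, str] = dict(zip(WEATHER_FEATURES, "ABCDEFGH"))
LETTER_TO_FEATURE: dict[str, str] = {v: k for k, v in FEATURE_LETTERS.items()}

#: Item marking pest occurrence in a transaction.
PEST_ITEM = "P"

PEST_VALUE_COLUMN = "PestValue"
WEEK_COLUMN = "week"
CSV_COLUMNS: tuple[str, ...] = (WEEK_COLUMN, *WEATHER_FEATURES, PEST_VALUE_COLUMN)

_FIELD_BY_FEATURE = {
    "MaxT": "max_t", "MinT": "min_t", "RH1": "rh1", "RH2": "rh2",
    "RF": "rf", "WS": "ws", "SSH": "ssh", "EVP": "evp",
}


@dataclass(frozen=True)
class WeatherPestRecord:
    """One week of weather observations plus the pest value."""

    week: int
    max_t: float
    min_t: float
    rh1: float
    rh2: float
    rf: float
    ws: float
    ssh: float
    evp: float
    pest_value: float = 0.0

    @property
    def pest_occurrence(self) -> int:
        """Binary occurrence indicator, 1 iff ``pest_value > 0``."""
        return int(self.pest_value > 0)

    def feature(self, name: str) -> float:
        """Return a weather feature by its canonical name (e.g. ``"MaxT"``)."""
        try:
            return getattr(self, _FIELD_BY_FEATURE[name])
        except KeyError:
            raise InvalidArgumentError(f"unknown weather feature {name!r}") from None

    def validate(self) -> None:
        values = [self.feature(f) for f in WEATHER_FEATURES] + [self.pest_value]
        if not all(np.isfinite(v) for v in values):
            raise DataError(f"non-finite value in record for week {self.week}")
        if self.week < 0:
            raise DataError(f"negative week index {self.week}")
        if self.max_t < self.min_t:
            raise DataError(
                f"week {self.week}: max_t {self.max_t} < min_t {self.min_t}")
        for name in ("RH1", "RH2"):
            v = self.feature(name)
            if not 0.0 <= v <= 100.0:
                raise DataError(f"week {self.week}: {name}={v} outside [0, 100]")
        for name in ("RF", "WS", "SSH", "EVP"):
            if self.feature(name) < 0.0:
                raise DataError(f"week {self.week}: negative {name}")
        if self.pest_value < 0.0:
            raise DataError(f"week {self.week}: negative pest value")


@dataclass
class PestDataset:
    """An ordered weekly weather-pest series for one location/pest pair.

    Thin wrapper around a :class:`pandas.DataFrame` with columns
    ``week, MaxT, MinT, RH1, RH2, RF, WS, SSH, EVP, PestValue``, rows in
    strictly increasing week order.
    """

    frame: pd.DataFrame
    location: str = "synthetic"
    pest_name: str = "synthetic"

    def __post_init__(self) -> None:
        missing = [c for c in CSV_COLUMNS if c not in self.frame.columns]
        if missing:
            raise DataError(f"PestDataset frame missing columns {missing}")
        self.frame = self.frame.loc[:, list(CSV_COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def __getitem__(self, key: slice) -> "PestDataset":
        if not isinstance(key, slice):
            raise InvalidArgumentError("PestDataset supports slice indexing only")
        return PestDataset(self.frame.iloc[key].reset_index(drop=True),
                           self.location, self.pest_name)

    @property
    def weather(self) -> np.ndarray:
        """Weather matrix of shape (n_weeks, 8) in canonical feature order."""
        return self.frame.loc[:, list(WEATHER_FEATURES)].to_numpy(float)

    @property
    def pest_value(self) -> np.ndarray:
        return self.frame[PEST_VALUE_COLUMN].to_numpy(float)

    @property
    def occurrence(self) -> np.ndarray:
        """Binary occurrence vector, 1 iff pest_value > 0."""
        return (self.pest_value > 0).astype(int)

    @property
    def weeks(self) -> np.ndarray:
        return self.frame[WEEK_COLUMN].to_numpy(int)

    def records(self) -> Iterator[WeatherPestRecord]:
        for row in self.frame.itertuples(index=False):
            yield WeatherPestRecord(
                week=int(row.week), max_t=row.MaxT, min_t=row.MinT,
                rh1=row.RH1, rh2=row.RH2, rf=row.RF, ws=row.WS,
                ssh=row.SSH, evp=row.EVP, pest_value=row.PestValue)

    def validate(self) -> None:
        weeks = self.weeks
        if len(weeks) and not np.all(np.diff(weeks) > 0):
            raise DataError("week indices are not strictly increasing")
        for rec in self.records():
            rec.validate()

    def with_pest(self, pest_value: np.ndarray) -> "PestDataset":
        """Return a copy with the pest-value column replaced."""
        if len(pest_value) != len(self):
            raise InvalidArgumentError("pest_value length mismatch")
        frame = self.frame.copy()
        frame[PEST_VALUE_COLUMN] = np.asarray(pest_value, float)
        return PestDataset(frame, self.location, self.pest_name)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_records(cls, records: list[WeatherPestRecord],
                     location: str = "synthetic",
                     pest_name: str = "synthetic") -> "PestDataset":
        frame = pd.DataFrame(
            [{WEEK_COLUMN: r.week,
              **{f: r.feature(f) for f in WEATHER_FEATURES},
              PEST_VALUE_COLUMN: r.pest_value} for r in records])
        return cls(frame, location, pest_name)


@dataclass(frozen=True)
class PlantedRule:
    """Ground-truth association rule planted by the synthetic generator.

    ``antecedent_items`` is a set of interval labels (e.g. ``{"A2", "F1"}``);
    the rule's consequent is always the pest-occurrence item ``P``.
    """

    antecedent_items: frozenset[str]
    target_support: float
    target_confidence: float

    def __post_init__(self) -> None:
        items = frozenset(self.antecedent_items)
        object.__setattr__(self, "antecedent_items", items)
        if not items:
            raise InvalidArgumentError("planted rule needs a non-empty antecedent")
        if not 0.0 < self.target_support < 1.0:
            raise InvalidArgumentError("target_support must lie in (0, 1)")
        if not 0.0 < self.target_confidence <= 1.0:
            raise InvalidArgumentError("target_confidence must lie in (0, 1]")
        if self.target_support > self.target_confidence:
            raise InvalidArgumentError(
                "target_support cannot exceed target_confidence "
                "(support = P(antecedent) * confidence)")
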