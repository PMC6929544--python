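"""Per-feature 1-D K-means discretization of weather factors.

Each continuous weather factor is clustered on its own with Lloyd's
algorithm and the clustering is converted into a contiguous interval scheme:
k ordered left-open/right-closed intervals labelled ``<letter>1 .. <letter>k``
(A for MaxT through H for EVP).  A weekly record then becomes a *transaction*
— the set of its eight interval labels, plus the item ``P`` when pests
occurred that week — ready for association-rule mining.

The cut point between two adjacent clusters is the maximum observed value of
the lower cluster, so every training value maps back into its own cluster's
interval and adjacent intervals share their endpoint exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import (FEATURE_LETTERS, PEST_ITEM, WEATHER_FEATURES,
                        PestDataset, WeatherPestRecord)
from .errors import (ConfigurationError, DataError, DegenerateInputError,
                     InternalError, InvalidArgumentError)

logger = logging.getLogger(__name__)

__all__ = [
    "kmeans_1d", "within_cluster_sse", "FeatureIntervals",
    "DiscretizationScheme", "scheme_from_clustering", "fit_scheme",
    "discretize_record", "discretize_dataset", "select_k",
    "reference_scheme",
]


def kmeans_1d(values, k: int, *, max_iter: int = 300, tol: float = 1e-9):
    """Cluster 1-D data with Lloyd's algorithm.

    Initialization is deterministic: centroid ``j`` starts at the
    ``(j + 1/2)/k`` quantile of the data, which for one-dimensional input is
    reproducible and close to the optimum, so no random restarts are needed.
    Ties in the nearest-centroid assignment go to the lower centroid.

    Returns
    -------
    centroids : ndarray of shape (k,), sorted ascending
    assignments : ndarray of shape (n,), index of each value's centroid
    """
    x = np.asarray(values, float).ravel()
    if x.size == 0:
        raise InvalidArgumentError("kmeans_1d needs at least one value")
    if not np.all(np.isfinite(x)):
        raise DataError("kmeans_1d input contains non-finite values")
    if k < 1:
        raise InvalidArgumentError(f"k must be >= 1, got {k}")
    distinct = np.unique(x)
    if distinct.size < k:
        raise DegenerateInputError(
            f"need at least k={k} distinct values, got {distinct.size}")

    centroids = np.quantile(x, (np.arange(k) + 0.5) / k)
    if np.unique(centroids).size < k:
        # heavy ties can collapse quantiles; fall back to spread distinct values
        idx = np.round(np.linspace(0, distinct.size - 1, k)).astype(int)
        centroids = distinct[idx].astype(float)

    for _ in range(max_iter):
        assign = _assign_nearest(x, centroids)
        new = np.array([x[assign == j].mean() for j in range(k)])
        new.sort()
        if np.max(np.abs(new - centroids)) < tol:
            centroids = new
            break
        centroids = new
    return centroids, _assign_nearest(x, centroids)


def _assign_nearest(x: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest-centroid assignment, ties to the lower centroid.

    A cluster left empty (possible when k exceeds the number of natural
    plateaus in the data) is deterministically refilled with the point
    farthest from its current centroid, so every cluster stays non-empty.
    """
    d = np.abs(x[:, None] - centroids[None, :])
    assign = np.argmin(d, axis=1)
    for j in range(len(centroids)):
        if not np.any(assign == j):
            far = int(np.argmax(np.abs(x - centroids[assign])))
            assign[far] = j
    return assign


def within_cluster_sse(values, centroids, assignments) -> float:
    """Sum of squared distances of each value to its assigned centroid."""
    x = np.asarray(values, float).ravel()
    c = np.asarray(centroids, float)
    return float(np.sum((x - c[np.asarray(assignments)]) ** 2))


@dataclass(frozen=True)
class FeatureIntervals:
    """Interval scheme for a single feature: k contiguous (lo, hi] intervals.

    ``cut_points`` are the k-1 interior boundaries; interval ``i`` (0-based)
    is ``(cut[i-1], cut[i]]`` with the outer bounds filled in by
    ``lower``/``upper``.  Values at a cut point belong to the lower interval;
    values outside ``(lower, upper]`` are clamped to the extreme intervals.
    """

    letter: str
    cut_points: tuple[float, ...]
    lower: float
    upper: float

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in self.cut_points)
        object.__setattr__(self, "cut_points", cuts)
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise InvalidArgumentError(f"{self.letter}: cut points not increasing")
        if cuts and not (self.lower < cuts[0] and cuts[-1] < self.upper):
            raise InvalidArgumentError(
                f"{self.letter}: cut points must lie strictly inside "
                f"({self.lower}, {self.upper})")

    @property
    def k(self) -> int:
        return len(self.cut_points) + 1

    def labels(self) -> list[str]:
        return [f"{self.letter}{i + 1}" for i in range(self.k)]

    def interval_index(self, value: float) -> int:
        if not np.isfinite(value):
            raise DataError(f"non-finite value for feature {self.letter}")
        # side='left': a value equal to a cut goes to the lower interval
        return int(np.searchsorted(self.cut_points, value, side="left"))

    def label(self, value: float) -> str:
        return f"{self.letter}{self.interval_index(value) + 1}"

    def interval_indices(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, float)
        if not np.all(np.isfinite(v)):
            raise DataError(f"non-finite values for feature {self.letter}")
        return np.searchsorted(self.cut_points, v, side="left")


@dataclass(frozen=True)
class DiscretizationScheme:
    """Interval schemes for all eight weather features, keyed by name."""

    features: dict[str, FeatureIntervals]

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", dict(self.features))

    def require(self, feature_names=WEATHER_FEATURES) -> None:
        missing = [f for f in feature_names if f not in self.features]
        if missing:
            raise ConfigurationError(f"scheme missing features {missing}")

    def label(self, feature: str, value: float) -> str:
        if feature not in self.features:
            raise ConfigurationError(f"scheme missing feature {feature!r}")
        return self.features[feature].label(value)

    def to_json(self) -> str:
        doc = {
            name: {
                "letter": fi.letter,
                "cut_points": list(fi.cut_points),
                "lower": fi.lower,
                "upper": fi.upper,
            }
            for name, fi in self.features.items()
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DiscretizationScheme":
        doc = json.loads(text)
        return cls({
            name: FeatureIntervals(d["letter"], tuple(d["cut_points"]),
                                   d["lower"], d["upper"])
            for name, d in doc.items()
        })


def scheme_from_clustering(values, centroids, assignments, feature_letter: str,
                           *, lower: float = 0.0) -> FeatureIntervals:
    """Convert a 1-D clustering into contiguous intervals.

    The boundary between adjacent clusters is the maximum observed value of
    the lower cluster, so interval endpoints are actual data values and each
    training value maps back into its own cluster's interval.  The covered
    range starts at ``lower`` (0 by convention for these non-negative weather
    factors) and ends at the maximum observed value.
    """
    x = np.asarray(values, float).ravel()
    c = np.asarray(centroids, float)
    a = np.asarray(assignments)
    if np.any(np.diff(c) < 0):
        raise InternalError("centroids must be sorted ascending")
    k = c.size
    cuts = []
    for j in range(k - 1):
        members = x[a == j]
        if members.size == 0:
            raise InternalError(f"cluster {j} is empty")
        cuts.append(float(members.max()))
    if x[a == k - 1].size == 0:
        raise InternalError(f"cluster {k - 1} is empty")
    return FeatureIntervals(feature_letter, tuple(cuts), lower, float(x.max()))


def fit_scheme(ds: PestDataset, k: int = 3, *,
               features=WEATHER_FEATURES) -> DiscretizationScheme:
    """Fit a per-feature k-interval scheme to a dataset's weather columns."""
    out = {}
    weather = ds.weather
    for i, name in enumerate(WEATHER_FEATURES):
        if name not in features:
            continue
        col = weather[:, i]
        centroids, assign = kmeans_1d(col, k)
        out[name] = scheme_from_clustering(col, centroids, assign,
                                           FEATURE_LETTERS[name])
    return DiscretizationScheme(out)


def discretize_record(rec: WeatherPestRecord,
                      scheme: DiscretizationScheme) -> frozenset[str]:
    """Map one record to its transaction: 8 interval labels (+ ``P``)."""
    scheme.require()
    items = {scheme.features[f].label(rec.feature(f)) for f in WEATHER_FEATURES}
    if rec.pest_occurrence:
        items.add(PEST_ITEM)
    return frozenset(items)


def discretize_dataset(ds: PestDataset, scheme: DiscretizationScheme, *,
                       include_pest: bool = True) -> list[frozenset[str]]:
    """Vectorized :func:`discretize_record` over a whole dataset."""
    scheme.require()
    weather = ds.weather
    label_cols = []
    for i, name in enumerate(WEATHER_FEATURES):
        fi = scheme.features[name]
        idx = fi.interval_indices(weather[:, i])
        labels = np.asarray(fi.labels())
        label_cols.append(labels[idx])
    occ = ds.occurrence if include_pest else np.zeros(len(ds), int)
    out = []
    for row, p in zip(zip(*label_cols), occ):
        items = set(row)
        if p:
            items.add(PEST_ITEM)
        out.append(frozenset(items))
    return out


def select_k(transactions_by_k: dict[int, list[frozenset[str]]],
             minsupport: float = 0.05, minconfidence: float = 0.5,
             k_candidates=None) -> int:
    """Choose k by the number of mined rules whose consequent is ``{P}``.

    For each candidate the pre-discretized transactions are mined and the
    pest-consequent rules counted; the k with the most such rules wins, ties
    going to the smallest k.  If no candidate yields any rule, the smallest
    candidate is returned with a warning.
    """
    from .mining import filter_pest_rules, mine_rules

    candidates = sorted(k_candidates if k_candidates is not None
                        else transactions_by_k)
    if not candidates:
        raise InvalidArgumentError("no k candidates supplied")
    counts = {}
    for k in candidates:
        if k not in transactions_by_k:
            raise ConfigurationError(f"no transactions supplied for k={k}")
        rules = mine_rules(transactions_by_k[k], minsupport, minconfidence)
        counts[k] = len(filter_pest_rules(rules))
        logger.info("select_k: k=%d -> %d pest-consequent rules", k, counts[k])
    best = max(candidates, key=lambda k: (counts[k], -k))
    if counts[best] == 0:
        logger.warning("select_k: no pest-consequent rules for any candidate; "
                       "returning smallest k=%d", candidates[0])
        return candidates[0]
    return best


def reference_scheme() -> DiscretizationScheme:
    """The k=3 interval scheme reported for the pooled Crop Pest DSS cotton
    corpus (15,343 weekly records), usable as a fixed, known-good
    discretization when no data is available to fit one.

    The published SSH (G) top interval is non-monotone as printed (a typo);
    this version uses the corrected boundary 8.03 shared with G2.
    """
    spec = {
        "MaxT": (27.79, 35.63, 46.60),
        "MinT": (13.68, 21.05, 32.20),
        "RH1": (57.50, 78.58, 97.30),
        "RH2": (36.37, 57.89, 90.40),
        "RF": (29.12, 103.52, 602.00),
        "WS": (5.73, 25.52, 71.40),
        "SSH": (4.97, 8.03, 12.70),
        "EVP": (10.16, 23.09, 72.00),
    }
    return DiscretizationScheme({
        name: FeatureIntervals(FEATURE_LETTERS[name], (c1, c2), 0.0, hi)
        for name, (c1, c2, hi) in spec.items()
    })
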