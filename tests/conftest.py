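import numpy as np
import pytest

import pestcast as pc


@pytest.fixture(scope="session")
def weather_520():
    """A 10-year synthetic weather series (pest columns zeroed)."""
    return pc.generate_weather_series(520, seed=11)


@pytest.fixture(scope="session")
def scheme_520(weather_520):
    return pc.fit_scheme(weather_520, 3)


@pytest.fixture(scope="session")
def ref_scheme():
    return pc.reference_scheme()


@pytest.fixture(scope="session")
def labeled_520(weather_520, scheme_520):
    rules = [pc.PlantedRule(frozenset({"A3", "B3"}), 0.25, 0.9)]
    return pc.generate_pest_labels(
        weather_520, scheme_520, rules, persistence=0.8, base_rate=0.02,
        label_noise=0.05, seed=12)


def random_transactions(rng, n_items=8, n_transactions=50, density=0.3):
    """Random basket sets over items a..; used by the brute-force checks."""
    items = [chr(ord("a") + i) for i in range(n_items)]
    out = []
    for _ in range(n_transactions):
        mask = rng.random(n_items) < density
        out.append(frozenset(i for i, m in zip(items, mask) if m))
    return out
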