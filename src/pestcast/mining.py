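"""From-scratch Apriori frequent-itemset mining and rule generation.

Support and confidence of a rule A -> B over n transactions are

    support(A -> B)    = n_AB / n        (joint frequency)
    confidence(A -> B) = n_AB / n_A      (conditional frequency)

Mining is level-wise: frequent (k-1)-itemsets sharing a (k-2)-prefix under
the canonical lexicographic item order are joined into k-candidates, pruned
by the subset-closure (anti-monotonicity) property, and counted exactly
against the transaction list.  Transactions are encoded as bitmasks so a
subset test is a single integer AND.

The alphabet here is small by construction — at most 24 interval labels plus
the occurrence item ``P`` — which keeps exact counting cheap.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .datatypes import PEST_ITEM
from .errors import InternalError, InvalidArgumentError

logger = logging.getLogger(__name__)

__all__ = [
    "FrequentItemset", "AssociationRule", "apriori_frequent_itemsets",
    "generate_rules", "filter_pest_rules", "item_probabilities",
    "mine_rules", "rules_to_frame", "write_rule_report",
]


@dataclass(frozen=True)
class FrequentItemset:
    items: frozenset[str]
    support: float


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset[str]
    consequent: frozenset[str]
    support: float       # joint support n_AB / n
    confidence: float    # n_AB / n_A

    def __str__(self) -> str:
        lhs = ",".join(sorted(self.antecedent))
        rhs = ",".join(sorted(self.consequent))
        return (f"{lhs} -> {rhs} "
                f"(support={self.support:.4f}, confidence={self.confidence:.4f})")


def apriori_frequent_itemsets(transactions, minsupport: float
                              ) -> list[FrequentItemset]:
    """Return exactly the itemsets with support >= ``minsupport``.

    Output is sorted by (size, lexicographic items) and is therefore
    deterministic for a given input.
    """
    transactions = list(transactions)
    if not transactions:
        raise InvalidArgumentError("transaction list is empty")
    if not 0.0 < minsupport <= 1.0:
        raise InvalidArgumentError(f"minsupport must be in (0, 1], got {minsupport}")
    n = len(transactions)

    items = sorted({i for t in transactions for i in t})
    bit = {item: 1 << j for j, item in enumerate(items)}
    tmasks = [sum(bit[i] for i in t) for t in transactions]

    singles = Counter()
    for t in transactions:
        singles.update(t)

    frequent: dict[tuple[str, ...], float] = {}
    level = []
    for item in items:
        sup = singles[item] / n
        if sup >= minsupport:
            frequent[(item,)] = sup
            level.append((item,))

    size = 2
    while level:
        prev = set(level)
        candidates = []
        for a, b in combinations(level, 2):
            if a[:-1] == b[:-1]:          # shared (size-2)-prefix join
                cand = a + (b[-1],) if a[-1] < b[-1] else b + (a[-1],)
                # prune by closure: every (size-1)-subset must be frequent
                if all(cand[:i] + cand[i + 1:] in prev for i in range(size)):
                    candidates.append(cand)
        level = []
        for cand in candidates:
            mask = 0
            for item in cand:
                mask |= bit[item]
            count = sum(1 for t in tmasks if t & mask == mask)
            sup = count / n
            if sup >= minsupport:
                frequent[cand] = sup
                level.append(cand)
        level.sort()
        size += 1

    return [FrequentItemset(frozenset(k), v)
            for k, v in sorted(frequent.items(), key=lambda kv: (len(kv[0]), kv[0]))]


def generate_rules(frequent, minconfidence: float) -> list[AssociationRule]:
    """Emit every rule with confidence >= ``minconfidence``.

    ``frequent`` must be closed under subsets (Apriori output).  For every
    frequent itemset of size >= 2, each non-empty proper subset is tried as
    antecedent; the rule's support is the joint support of the full itemset.
    """
    if not 0.0 < minconfidence <= 1.0:
        raise InvalidArgumentError(
            f"minconfidence must be in (0, 1], got {minconfidence}")
    support = {fs.items: fs.support for fs in frequent}
    rules = []
    for itemset, sup in support.items():
        if len(itemset) < 2:
            continue
        ordered = sorted(itemset)
        for r in range(1, len(ordered)):
            for ante in combinations(ordered, r):
                ante_set = frozenset(ante)
                if ante_set not in support:
                    raise InternalError(
                        f"support of antecedent {sorted(ante_set)} missing; "
                        "input is not subset-closed")
                conf = sup / support[ante_set]
                if conf >= minconfidence:
                    rules.append(AssociationRule(
                        ante_set, itemset - ante_set, sup, conf))
    rules.sort(key=lambda r: (-r.confidence, -r.support,
                              sorted(r.antecedent), sorted(r.consequent)))
    return rules


def mine_rules(transactions, minsupport: float = 0.05,
               minconfidence: float = 0.5) -> list[AssociationRule]:
    """Frequent-itemset mining followed by rule generation in one call."""
    return generate_rules(apriori_frequent_itemsets(transactions, minsupport),
                          minconfidence)


def filter_pest_rules(rules, pest_item: str = PEST_ITEM) -> list[AssociationRule]:
    """Keep exactly the rules whose consequent is the single item ``P``."""
    target = frozenset([pest_item])
    return [r for r in rules if r.consequent == target]


def item_probabilities(rules) -> dict[str, float]:
    """Relative frequency of each item across all rule antecedents.

    Each antecedent slot counts once, so the probabilities sum to 1.
    """
    rules = list(rules)
    if not rules:
        raise InvalidArgumentError("item_probabilities needs at least one rule")
    counts = Counter()
    for r in rules:
        counts.update(r.antecedent)
    total = sum(counts.values())
    return {item: counts[item] / total for item in sorted(counts)}


def rules_to_frame(rules) -> pd.DataFrame:
    """Tabulate rules sorted by confidence then support, both descending."""
    rows = [{
        "antecedent": ",".join(sorted(r.antecedent)),
        "consequent": ",".join(sorted(r.consequent)),
        "support": r.support,
        "confidence": r.confidence,
    } for r in rules]
    frame = pd.DataFrame(rows, columns=["antecedent", "consequent",
                                        "support", "confidence"])
    if len(frame):
        frame = frame.sort_values(["confidence", "support"],
                                  ascending=False, kind="mergesort")
    return frame.reset_index(drop=True)


def write_rule_report(rules, path) -> None:
    """Write the rule table as CSV or JSON depending on the file suffix."""
    frame = rules_to_frame(rules)
    path = str(path)
    if path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump(frame.to_dict(orient="records"), fh, indent=2)
    else:
        frame.to_csv(path, index=False)
    logger.info("wrote %d rules to %s", len(frame), path)
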