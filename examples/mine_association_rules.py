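"""Recover a planted association rule with the from-scratch Apriori miner.

Plants the reference rule A2,B3,D3,F1 -> P (warm days and nights, humid
evenings, low wind imply pest occurrence) at joint support 0.0927 and
confidence 0.8592 in 20,000 synthetic transactions, mines with minsupport
0.05 / minconfidence 0.5, and compares the recovered numbers to the truth.
"""

import pestcast as pc
from pestcast.synthetic import EXAMPLE_CPDSS_RULE

transactions = pc.generate_basket_data(20000, [EXAMPLE_CPDSS_RULE], seed=7)
rules = pc.mine_rules(transactions, minsupport=0.05, minconfidence=0.5)
pest_rules = pc.filter_pest_rules(rules)

print(f"mined {len(rules)} rules, {len(pest_rules)} with consequent {{P}}")
print("\ntop pest-consequent rules (confidence desc):")
for rule in pest_rules[:5]:
    print("  ", rule)

planted = next(r for r in pest_rules
               if r.antecedent == EXAMPLE_CPDSS_RULE.antecedent_items)
print(f"\nplanted rule recovery: confidence {planted.confidence:.4f} "
      f"(truth 0.8592), support {planted.support:.4f} (truth 0.0927)")

probs = pc.item_probabilities(pest_rules)
print("\nantecedent item probabilities (how often each weather condition "
      "appears\namong the mined pest rules):")
for item, p in sorted(probs.items(), key=lambda kv: -kv[1]):
    print(f"  {item}: {p:.3f}")
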