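"""Mine cancer-miRNA modules by association-rule mining on synthetic data.

A module is an association rule over miRNAs: {X} -> {Y} means that in
cancer types where every miRNA in X is dysregulated, those in Y tend to be
dysregulated too.  Support is the fraction of cancer types carrying the
whole itemset; confidence the conditional frequency of Y given X.  The
generator plants a 3-miRNA module shared by 10 of 30 cancers, which mining
should recover at the canonical thresholds (support 0.3, confidence 0.8).
"""

from cminet import (
    PlantedModule,
    SyntheticSpec,
    apriori,
    generate_network,
    generate_rules,
    to_transactions,
    top_rules,
)
from cminet.mining import rules_frame

spec = SyntheticSpec(
    planted_modules=(PlantedModule(size=3, k=10),),
    seed=11,
)
network, truth = generate_network(spec)
print("planted module:", truth.modules[0]["mirnas"])

db = to_transactions(network)
frequent = apriori(db, min_support=0.3)
rules = generate_rules(frequent, db, min_confidence=0.8)
print(f"{len(frequent)} frequent itemsets, {len(rules)} rules; top 5:")
print(rules_frame(top_rules(rules, 5)).to_string(index=False))
# Every top rule drawn from the planted miRNAs has high confidence: whenever
# its antecedent miRNAs are jointly dysregulated, the consequent is too.
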