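"""Classify colony breeding systems from worker genotypes.

A colony is 'mixed' if some locus shows more than four alleles (more than
two unrelated reproductives), 'extended' if worker genotypes or their
frequencies are inconsistent with a single parental pair (inbred neotenic
breeding), and 'simple' otherwise.  Compares the calls against the
simulator's pedigree truth.
"""

import numpy as np

import colonystruct as cs

dataset, truth = cs.sim_dataset(cs.SimConfig(seed=42))
calls, summary = cs.classify_dataset(dataset, alpha=0.05)

true_type = {t.colony_id: t.family_type for t in truth}
agreement = np.mean([c.verdict == true_type[c.colony_id] for c in calls])

print("verdict proportions:", {k: f"{100 * v:.1f}%" for k, v in summary["overall"].items()})
print(f"agreement with pedigree truth: {100 * agreement:.1f}%")
print("\nfirst five calls:")
for call in calls[:5]:
    detail = f"G={call.G:.2f} df={call.df} p={call.p_value:.3f}" if call.G is not None else \
             "; ".join(call.rules)
    print(f"  {call.colony_id}: {call.verdict:9s} [{detail}] (truth: {true_type[call.colony_id]})")
# G is the combined-locus goodness-of-fit statistic against the best
# single-pair Mendelian expectations; small p flags a colony whose worker
# genotype frequencies a single outbred pair cannot explain.
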