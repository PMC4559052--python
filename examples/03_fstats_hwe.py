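"""Classical population-genetic statistics on one-per-colony resamples.

Reproduces the analysis pattern for colony-structured data: pick one
worker per colony (sibship would otherwise masquerade as structure),
then estimate heterozygosities, Weir-Cockerham F_IS, exact heterozygote-
deficiency tests per locus, and an AMOVA over all workers.
"""

import numpy as np

import colonystruct as cs

dataset, _ = cs.sim_dataset(cs.SimConfig(seed=42))
plan = cs.make_resample_plan(dataset, n_replicates=20, seed=7)
resamples = cs.make_resamples(dataset, plan)

fis = []
hwe_frac = {locus.name: 0 for locus in dataset.loci}
for rep in resamples:
    fis.append(cs.wc_fstats(rep, np.zeros(rep.n_individuals)).overall["F_IS"])
    for l, locus in enumerate(dataset.loci):
        p = cs.hwe_deficiency_test(rep, l, mc_reps=2000, seed=l).p_value
        hwe_frac[locus.name] += (p < 0.05) / len(resamples)

het = cs.observed_expected_het(resamples[0])
print(f"mean H_O = {het['mean_H_O']:.3f}, mean H_E (Nei unbiased) = {het['mean_H_E']:.3f}")
print(f"pooled F_IS over 20 resamples: mean {np.mean(fis):.3f} "
      f"(range {np.min(fis):.3f}..{np.max(fis):.3f})")
print("fraction of resamples with significant heterozygote deficiency per locus:")
for name, frac in hwe_frac.items():
    print(f"  {name}: {frac:.2f}")

amova = cs.amova(dataset, n_perm=199, seed=1)
print("AMOVA (all workers): " + ", ".join(
    f"{k} {v:.1f}%" for k, v in amova.percent.items()))
# Positive pooled F_IS reflects both the Wahlund effect of the two clusters
# and neotenic inbreeding; the large among-colony AMOVA share is the
# family-structure signal.
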