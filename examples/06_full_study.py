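"""The whole workflow in one call: simulate, analyze, report.

run_study() sequences resampling, pooled statistics, AMOVA, isolation by
distance, spatial PCA, Bayesian clustering with delta-K, per-cluster
statistics and breeding-system classification, and returns a single
JSON-serializable report.
"""

import json
from pathlib import Path

import colonystruct as cs

config = cs.StudyConfig(
    sim=cs.SimConfig(seed=42),
    n_resamples=10,
    mantel_perm=499,
    spca_perm=999,
    fst_perm=500,
    hwe_mc=2000,
    ld_mc=500,
    amova_perm=99,
    k_min=1,
    k_max=3,
    cluster_replicates=2,
    burn_in=2000,
    sweeps=5000,
    seed=7,
)
report = cs.run_study(config)

Path("scratch").mkdir(exist_ok=True)
Path("scratch/report.json").write_text(report.to_json())

s = report.sections
print(f"stages with errors: {list(report.errors) or 'none'}")
print(f"pooled F_IS (mean over resamples): {s['replicates']['fis_mean']:.3f}")
print(f"AMOVA among colonies: {s['amova']['percent']['among_colonies']:.1f}%")
print(f"Mantel r (mean): {s['replicates']['mantel_r_mean']:.3f}")
print(f"sPCA lambda_1 = {s['spca']['lambda'][0]:.3f}, global p = {s['spca']['global_p']:.4f}")
print(f"clustering: selected K = {s['clustering']['selected_k']}, "
      f"sizes {s['clustering']['cluster_sizes']}")
print("family proportions:", {k: f"{100 * v:.0f}%"
                              for k, v in s["families"]["summary"]["overall"].items()})
print("full report written to scratch/report.json")
# Every number above is recomputed from the seeded simulation; rerunning
# with the same seeds reproduces the report byte for byte.
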