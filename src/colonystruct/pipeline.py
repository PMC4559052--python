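"""End-to-end study orchestration.

Sequences the full analysis workflow on a colony-structured dataset:

1. one-individual-per-colony resampling (default 20 replicates) so
   within-colony sibship does not masquerade as population-level signal;
2. per-replicate pooled statistics (heterozygosities, W&C F_IS,
   heterozygote-deficiency tests, genotypic LD scan) and their aggregation
   across replicates;
3. AMOVA on all workers (colony / individual / gene-copy levels);
4. isolation by distance (Edwards vs geographic distances, Mantel test,
   kernel density of the scatter) per replicate;
5. spatial PCA on colony allele frequencies with global/local tests;
6. Bayesian clustering across a K range with Evanno delta-K selection and
   a consensus assignment;
7. per-cluster statistics (F_IS, heterozygote-deficiency, pairwise F_ST
   with permutation significance, within-cluster Mantel);
8. colony breeding-system classification with per-cluster proportions.

Every stage draws its randomness from a child of the root seed, so a
report is reproducible end to end; stage failures are caught and recorded
by stage name, preserving the partial report.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from . import __version__
from .clustering import align_and_summarize, evanno_deltak, gibbs_admixture
from .families import classify_dataset
from .fstats import (
    amova,
    hwe_deficiency_test,
    ld_scan,
    observed_expected_het,
    pairwise_fst,
    wc_fstats,
)
from .model import GenotypeDataset, colony_allele_frequencies, frequency_matrix
from .simulate import SimConfig, sim_dataset
from .spatial import (
    edwards_distance_matrix,
    geographic_distance_matrix,
    ibd_density,
    knn_graph,
    mantel_test,
    spca,
    spca_tests,
)


# ----------------------------------------------------------------------
# resampling


@dataclass
class ResamplePlan:
    """Which individual represents each colony in each replicate."""

    n_replicates: int
    seed: int
    chosen: np.ndarray = field(repr=False)  # (n_replicates, n_colonies) row indices


def make_resample_plan(
    dataset: GenotypeDataset, n_replicates: int = 20, seed: int = 0
) -> ResamplePlan:
    """Seeded uniform choice of one individual per colony per replicate."""
    rng = np.random.default_rng(seed)
    chosen = np.empty((n_replicates, dataset.n_colonies), dtype=np.int64)
    for j, colony in enumerate(dataset.colonies):
        members = dataset.colony_members(colony)
        if len(members) == 0:
            raise ValueError(f"colony {colony!r} has no individuals")
        chosen[:, j] = rng.choice(members, size=n_replicates, replace=True)
    return ResamplePlan(n_replicates, seed, chosen)


def make_resamples(dataset: GenotypeDataset, plan: ResamplePlan) -> list[GenotypeDataset]:
    """Materialize the one-per-colony datasets of a resample plan."""
    return [dataset.subset(rows) for rows in plan.chosen]


def aggregate_replicates(per_replicate: Sequence[dict]) -> dict:
    """Aggregate per-replicate test results.

    Expects each entry to carry ``hwe_p`` (locus -> p), ``fis`` (overall
    F_IS) and optionally ``mantel`` (r, p).  Returns per-locus significant
    fractions at alpha = 0.05 and the spread of estimates.
    """
    if not per_replicate:
        raise ValueError("no replicate results to aggregate")
    loci = list(per_replicate[0]["hwe_p"])
    frac = {
        loc: float(np.mean([rep["hwe_p"][loc] < 0.05 for rep in per_replicate]))
        for loc in loci
    }
    fis = np.array([rep["fis"] for rep in per_replicate], dtype=float)
    out = {
        "hwe_significant_fraction": frac,
        "fis_mean": float(np.nanmean(fis)),
        "fis_range": [float(np.nanmin(fis)), float(np.nanmax(fis))],
        "n_replicates": len(per_replicate),
    }
    if all("mantel" in rep for rep in per_replicate):
        rs = np.array([rep["mantel"][0] for rep in per_replicate])
        ps = np.array([rep["mantel"][1] for rep in per_replicate])
        out["mantel_r_mean"] = float(rs.mean())
        out["mantel_significant_fraction"] = float((ps < 0.05).mean())
    return out


# ----------------------------------------------------------------------
# configuration


@dataclass
class StudyConfig:
    """One study run: input, permutation counts and MCMC settings.

    Defaults are desk-scale; :func:`study_preset` switches every knob to
    the reference study's settings (20 resamples, K = 10 network,
    999 / 9999 / 1000 permutations, 50,000 + 100,000 MCMC).
    """

    sim: SimConfig | None = None
    n_resamples: int = 20
    alpha: float = 0.05
    knn_k: int = 10
    mantel_perm: int = 999
    spca_perm: int = 999
    fst_perm: int = 1000
    hwe_mc: int = 5_000
    ld_mc: int = 2_000
    ld_replicates: int = 3  # LD scan on the first few replicates only
    amova_perm: int = 199
    k_min: int = 1
    k_max: int = 4
    cluster_replicates: int = 2
    burn_in: int = 2_000
    sweeps: int = 4_000
    seed: int = 0
    run_clustering: bool = True


def study_preset(sim: SimConfig | None = None, seed: int = 0) -> StudyConfig:
    """The reference study's analysis settings."""
    return StudyConfig(
        sim=sim,
        n_resamples=20,
        knn_k=10,
        mantel_perm=999,
        spca_perm=9999,
        fst_perm=1000,
        hwe_mc=10_000,
        ld_mc=10_000,
        k_min=1,
        k_max=10,
        cluster_replicates=5,
        burn_in=50_000,
        sweeps=100_000,
        seed=seed,
    )


# ----------------------------------------------------------------------
# report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


@dataclass
class StudyReport:
    """Consolidated, JSON-serializable study output."""

    sections: dict
    errors: dict
    provenance: dict

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            _jsonable(
                {
                    "provenance": self.provenance,
                    "sections": self.sections,
                    "errors": self.errors,
                }
            ),
            indent=indent,
            sort_keys=True,
        )


# ----------------------------------------------------------------------
# the study


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def run_study(config: StudyConfig, dataset: GenotypeDataset | None = None) -> StudyReport:
    """Run the full workflow on a provided or simulated dataset.

    AMOVA uses all workers; heterozygosity / HWE / F_IS / LD / IBD /
    clustering use the one-per-colony resamples.  Stage failures are
    recorded under ``errors`` and later stages still run where possible.
    """
    if dataset is None:
        if config.sim is None:
            raise ValueError("either a dataset or a SimConfig is required")
        dataset, _truth = sim_dataset(config.sim)

    ss = np.random.SeedSequence(config.seed)
    seeds = {
        name: child
        for name, child in zip(
            ("resample", "hwe", "ld", "amova", "mantel", "spca", "cluster", "cluster_stats"),
            ss.spawn(8),
        )
    }
    sections: dict = {}
    errors: dict = {}

    plan = make_resample_plan(dataset, config.n_resamples, _child_seed(seeds["resample"]))
    resamples = make_resamples(dataset, plan)
    geo_ok = bool(dataset.geo)

    # ---- per-replicate pooled statistics -----------------------------
    try:
        hwe_seeds = seeds["hwe"].spawn(len(resamples))
        per_rep = []
        d_geo = geographic_distance_matrix(dataset.coords()) if geo_ok else None
        mantel_seeds = seeds["mantel"].spawn(len(resamples))
        for r, rep in enumerate(resamples):
            locus_seeds = hwe_seeds[r].spawn(dataset.n_loci)
            hwe_p = {
                dataset.loci[l].name: hwe_deficiency_test(
                    rep, l, mc_reps=config.hwe_mc, seed=_child_seed(locus_seeds[l])
                ).p_value
                for l in range(dataset.n_loci)
            }
            fis = wc_fstats(rep, np.zeros(rep.n_individuals)).overall["F_IS"]
            entry = {"hwe_p": hwe_p, "fis": fis}
            if geo_ok:
                d_gen = edwards_distance_matrix(colony_allele_frequencies(rep))
                entry["mantel"] = mantel_test(
                    d_gen, d_geo, config.mantel_perm, _child_seed(mantel_seeds[r])
                )
                if r == 0:
                    kde = ibd_density(d_gen, d_geo)
                    sections["ibd_density_grid"] = {
                        "shape": list(kde["density"].shape),
                        "integral": float(
                            kde["density"].sum()
                            * (kde["x"][1] - kde["x"][0])
                            * (kde["y"][1] - kde["y"][0])
                        ),
                    }
            per_rep.append(entry)
        sections["replicates"] = aggregate_replicates(per_rep)
        sections["heterozygosity"] = observed_expected_het(resamples[0])
    except Exception as e:  # noqa: BLE001 - stage isolation by design
        errors["replicates"] = repr(e)

    # ---- LD scan on a few replicates ---------------------------------
    try:
        ld_seeds = seeds["ld"].spawn(max(config.ld_replicates, 1))
        ld = [
            ld_scan(rep, mc_reps=config.ld_mc, alpha=config.alpha, seed=_child_seed(ld_seeds[r]))
            for r, rep in enumerate(resamples[: config.ld_replicates])
        ]
        sections["linkage"] = {
            "n_pairs": ld[0]["n_pairs"],
            "bonferroni_alpha": ld[0]["bonferroni_alpha"],
            "significant_pairs_per_replicate": [
                sum(v["significant"] for v in scan["pairs"].values()) for scan in ld
            ],
        }
    except Exception as e:  # noqa: BLE001
        errors["linkage"] = repr(e)

    # ---- AMOVA on all workers ----------------------------------------
    try:
        am = amova(dataset, n_perm=config.amova_perm, seed=_child_seed(seeds["amova"]))
        sections["amova"] = {
            "percent": am.percent,
            "phi": am.phi,
            "p_among_colonies": am.p_among_colonies,
            "p_within_individuals": am.p_within_individuals,
        }
    except Exception as e:  # noqa: BLE001
        errors["amova"] = repr(e)

    # ---- spatial PCA --------------------------------------------------
    if geo_ok:
        try:
            freqs = colony_allele_frequencies(dataset)
            X, labels = frequency_matrix(freqs, dataset.loci)
            net = knn_graph(dataset.coords(), dataset.colonies, min(config.knn_k, dataset.n_colonies - 1))
            res = spca(X, net, labels)
            tests = spca_tests(X, net, config.spca_perm, _child_seed(seeds["spca"]))
            lead = res.scores[:, 0]
            sections["spca"] = {
                "lambda": res.eigenvalues[:5],
                "axis_variance": res.axis_variance[:5],
                "moran_i": res.axis_moran[:5],
                "global_p": tests["global_p"],
                "local_p": tests["local_p"],
                "top_loadings_axis1": sorted(
                    zip(labels, res.loadings[:, 0]), key=lambda t: -t[1]
                )[:5],
                "score_sign_split": {
                    c: bool(lead[i] > 0) for i, c in enumerate(dataset.colonies)
                },
            }
        except Exception as e:  # noqa: BLE001
            errors["spca"] = repr(e)

    # ---- Bayesian clustering -----------------------------------------
    cluster_of = None
    if config.run_clustering:
        try:
            ks = list(range(config.k_min, config.k_max + 1))
            run_seeds = seeds["cluster"].spawn(len(ks) * config.cluster_replicates)
            l_hat: dict[int, list[float]] = {k: [] for k in ks}
            runs_by_k: dict[int, list] = {k: [] for k in ks}
            si = 0
            for k in ks:
                for r in range(config.cluster_replicates):
                    rep = resamples[r % len(resamples)]
                    run = gibbs_admixture(
                        rep,
                        k,
                        burn_in=config.burn_in,
                        sweeps=config.sweeps,
                        seed=_child_seed(run_seeds[si]),
                    )
                    si += 1
                    l_hat[k].append(run.l_hat)
                    runs_by_k[k].append(run)
            table = evanno_deltak(l_hat)
            k_sel = table.selected_k or max(l_hat, key=lambda k: np.mean(l_hat[k]))
            consensus = align_and_summarize(runs_by_k[k_sel])
            cluster_of = {
                dataset.colonies[i]: int(c)
                for i, c in enumerate(consensus["modal_cluster"])
            }
            sections["clustering"] = {
                "mean_l_hat": table.mean_l,
                "delta_k": table.delta_k,
                "selected_k": table.selected_k,
                "consensus_k": k_sel,
                "cluster_sizes": {
                    str(k): int(np.sum(consensus["modal_cluster"] == k))
                    for k in range(k_sel)
                },
            }
        except Exception as e:  # noqa: BLE001
            errors["clustering"] = repr(e)

    # ---- per-cluster statistics --------------------------------------
    if cluster_of is not None and len(set(cluster_of.values())) > 1:
        try:
            css = seeds["cluster_stats"].spawn(3)
            rep0 = resamples[0]
            fis_by_cluster = {}
            for lab in sorted(set(cluster_of.values())):
                rows = [
                    i
                    for i, c in enumerate(rep0.colony_ids)
                    if cluster_of.get(c) == lab
                ]
                if len(rows) < 2:
                    continue
                sub = rep0.subset(rows)
                fis_by_cluster[str(lab)] = wc_fstats(
                    sub, np.zeros(sub.n_individuals)
                ).overall["F_IS"]
            fst = pairwise_fst(rep0, cluster_of, config.fst_perm, _child_seed(css[0]))
            within_mantel = {}
            if geo_ok:
                for lab in sorted(set(cluster_of.values())):
                    cols = [c for c in rep0.colonies if cluster_of.get(c) == lab]
                    if len(cols) < 4:
                        continue
                    rows = [i for i, c in enumerate(rep0.colony_ids) if c in cols]
                    sub = rep0.subset(rows)
                    dgen = edwards_distance_matrix(colony_allele_frequencies(sub))
                    dgeo = geographic_distance_matrix(sub.coords())
                    within_mantel[str(lab)] = mantel_test(
                        dgen, dgeo, config.mantel_perm, _child_seed(css[1])
                    )
            sections["per_cluster"] = {
                "fis": fis_by_cluster,
                "pairwise_fst": {f"{a}-{b}": v for (a, b), v in fst.items()},
                "within_cluster_mantel": within_mantel,
            }
        except Exception as e:  # noqa: BLE001
            errors["per_cluster"] = repr(e)

    # ---- breeding systems --------------------------------------------
    try:
        calls, summary = classify_dataset(dataset, config.alpha, cluster_of=cluster_of)
        sections["families"] = {
            "summary": summary,
            "calls": {c.colony_id: c.verdict for c in calls},
        }
    except Exception as e:  # noqa: BLE001
        errors["families"] = repr(e)

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items() if k != "sim"},
        "simulated": config.sim is not None,
        "n_colonies": dataset.n_colonies,
        "n_individuals": dataset.n_individuals,
        "n_loci": dataset.n_loci,
    }
    return StudyReport(sections, errors, provenance)
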