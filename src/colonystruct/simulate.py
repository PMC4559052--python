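"""Synthetic colony-pedigree generator.

Generates microsatellite datasets with the statistical structure the
downstream analyses assume, so the whole pipeline is testable without any
external data:

* **Clustered allele frequencies.**  Ancestral frequencies are perturbed
  per spatial cluster under the Balding–Nichols construction — each
  cluster's frequency vector is a Dirichlet draw with mean equal to the
  ancestral vector and concentration ``(1 - theta) / theta`` — so the
  expected divergence among clusters is the target F_ST-like ``theta``.
* **Colony pedigrees.**  A *simple-family* colony holds the Mendelian
  offspring of one outbred pair drawn from the local gene pool under
  Hardy–Weinberg proportions.  An *extended-family* colony is produced by
  ``g`` rounds of neotenic succession: in each round two full-sib offspring
  of the current pair become the next breeding pair, so worker inbreeding
  follows the full-sib recurrence F_t = (1 + 2 F_{t-1} + F_{t-2}) / 4
  (0.25, 0.375, 0.5, ... for g = 1, 2, 3).  A *mixed-family* colony draws
  each worker from a distinct pair among ``m >= 3`` unrelated founders.
* **Identity-by-descent tags.**  Every founder gene copy carries a unique
  tag propagated through the pedigree; a worker's realized autozygosity is
  the fraction of loci whose two tags coincide, giving an exact
  pedigree-level check of the F recurrence.
* **Spatial layout and mtDNA.**  Colonies are scattered around cluster
  centers (default) or placed on a 1-D gradient with stepping-stone
  interpolated frequencies (for isolation-by-distance power checks); each
  colony gets a maternally inherited haplotype label drawn from its
  cluster's haplotype distribution.

Loci are simulated independently (no linkage) and without mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import ColonyGeo, GenotypeDataset, LocusDef

FAMILY_TYPES = ("simple", "extended", "mixed")

#: allele counts per locus patterned on a six-locus microsatellite panel
#: (one highly polymorphic locus, the rest with 2-4 alleles; mean 4.67)
DEFAULT_ALLELE_TEMPLATE = (13, 3, 3, 2, 3, 4)


def default_haplotype_freqs(n_clusters: int) -> list[dict[str, float]]:
    """Cluster-specific mtDNA haplotype frequencies.

    Two widespread haplotypes plus one restricted to the last (southern)
    cluster, echoing the common pattern of a locally confined maternal
    lineage.
    """
    base = [
        {"HT1": 0.75, "HT2": 0.25},
        {"HT1": 0.40, "HT2": 0.25, "HT3": 0.35},
        {"HT1": 0.20, "HT3": 0.80},
    ]
    if n_clusters <= len(base):
        return base[:n_clusters]
    return base + [base[-1]] * (n_clusters - len(base))


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic dataset.

    Defaults emulate the reference sampling design: 52 colonies of 10
    workers genotyped at 6 loci, two spatial clusters at divergence
    ``theta = 0.14``, and a simple/extended family mixture of 38.5 / 61.5 %
    with three rounds of neotenic succession in extended colonies.
    """

    n_clusters: int = 2
    colonies_per_cluster: int = 26
    workers_per_colony: int = 10
    allele_template: tuple[int, ...] = DEFAULT_ALLELE_TEMPLATE
    theta: float = 0.14
    family_mix: tuple[float, float, float] = (0.385, 0.615, 0.0)  # simple, extended, mixed
    neotenic_generations: int = 3
    neotenic_pairs: int = 3
    founders_m: int = 3
    divergence_tol: float | None = 0.01  # calibrate realized cluster divergence
    layout: str = "clusters"  # or "gradient"
    cluster_spread: float = 40_000.0  # meters
    area: tuple[float, float] = (200_000.0, 395_000.0)  # east-west, north-south extent
    haplotype_freqs: list[dict[str, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must lie in (0, 1)")
        if abs(sum(self.family_mix) - 1.0) > 1e-9 or min(self.family_mix) < 0:
            raise ValueError("family_mix proportions must be nonnegative and sum to 1")
        if self.neotenic_generations < 0:
            raise ValueError("neotenic_generations must be >= 0")
        if self.neotenic_pairs < 1:
            raise ValueError("neotenic_pairs must be >= 1")
        if self.founders_m < 3:
            raise ValueError("founders_m must be >= 3")
        if self.layout not in ("clusters", "gradient"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if min(self.allele_template) < 1:
            raise ValueError("every locus needs at least one allele")

    @property
    def n_loci(self) -> int:
        return len(self.allele_template)

    @property
    def n_colonies(self) -> int:
        return self.n_clusters * self.colonies_per_cluster


@dataclass
class PedigreeTruth:
    """Ground truth for one simulated colony."""

    colony_id: str
    family_type: str
    cluster: int
    g: int
    expected_f: float
    realized_f: np.ndarray = field(repr=False)  # per-worker autozygosity from IBD tags
    founder_genotypes: np.ndarray = field(repr=False)  # (n_founders, L, 2) allele codes


def fullsib_inbreeding(g: int) -> float:
    """Pedigree inbreeding of offspring after ``g`` rounds of full-sib mating.

    F_t = (1 + 2 F_{t-1} + F_{t-2}) / 4 with F_0 = 0 (offspring of the
    unrelated founder pair): 0.25, 0.375, 0.5, ...
    """
    if g < 0:
        raise ValueError("g must be >= 0")
    f_prev2, f_prev1 = 0.0, 0.0
    for _ in range(g):
        f_prev2, f_prev1 = f_prev1, (1.0 + 2.0 * f_prev1 + f_prev2) / 4.0
    return f_prev1


def parametric_fst(cluster_freqs: Sequence[Sequence[np.ndarray]]) -> float:
    """Realized divergence of a set of cluster frequency vectors.

    The large-sample limit of the Weir–Cockerham multi-locus estimator for
    r equally weighted demes with known frequencies:
    theta = sum s2 / sum (pbar(1-pbar) + s2 / r), summed over loci and
    alleles, with s2 the (r-1)-divisor variance of p across demes.
    """
    r = len(cluster_freqs)
    if r < 2:
        raise ValueError("need at least 2 clusters")
    num = den = 0.0
    for l in range(len(cluster_freqs[0])):
        P = np.stack([cluster_freqs[k][l] for k in range(r)])  # r x alleles
        pbar = P.mean(axis=0)
        s2 = P.var(axis=0, ddof=1)
        num += s2.sum()
        den += (pbar * (1 - pbar) + s2 / r).sum()
    return float(num / den) if den > 0 else np.nan


def sim_cluster_freqs(
    ancestral: Sequence[np.ndarray],
    theta: float,
    n_clusters: int,
    rng: np.random.Generator,
    calibrate_tol: float | None = None,
    max_tries: int = 500,
) -> list[list[np.ndarray]]:
    """Balding–Nichols cluster frequencies: Dirichlet(p * (1-theta)/theta).

    Returns ``freqs[cluster][locus]``; each vector sums to 1 and has mean
    equal to the ancestral vector across clusters; the expected divergence
    among clusters is ``theta``.

    With few loci the *realized* divergence of one draw scatters widely
    around theta (per-locus drift has r - 1 degrees of freedom).  When
    ``calibrate_tol`` is set, draws are rejected until the realized
    parametric divergence (:func:`parametric_fst`) is within that tolerance
    of the target, so the clusters are *at* the requested divergence rather
    than merely centered on it; the closest draw is kept if ``max_tries``
    is exhausted.
    """
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must lie in (0, 1)")
    scale = (1.0 - theta) / theta

    def one_draw() -> list[list[np.ndarray]]:
        out: list[list[np.ndarray]] = [[] for _ in range(n_clusters)]
        for p in ancestral:
            p = np.asarray(p, dtype=float)
            if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("ancestral frequencies must be a probability vector")
            if len(p) == 1:
                draws = np.ones((n_clusters, 1))
            else:
                draws = rng.dirichlet(np.maximum(p, 1e-12) * scale, size=n_clusters)
            for k in range(n_clusters):
                out[k].append(draws[k])
        return out

    if calibrate_tol is None or n_clusters < 2:
        return one_draw()
    best, best_err = None, np.inf
    for _ in range(max_tries):
        draw = one_draw()
        err = abs(parametric_fst(draw) - theta)
        if err < best_err:
            best, best_err = draw, err
        if err <= calibrate_tol:
            break
    return best


# ----------------------------------------------------------------------
# pedigree machinery


def _draw_founder(freqs: list[np.ndarray], tag_start: int, rng: np.random.Generator):
    """One founder: per-locus allele-index pairs under HWE plus unique IBD tags."""
    L = len(freqs)
    alleles = np.empty((L, 2), dtype=np.int64)
    for l, p in enumerate(freqs):
        alleles[l] = rng.choice(len(p), size=2, p=p)
    tags = np.arange(tag_start, tag_start + 2 * L).reshape(L, 2)
    return alleles, tags


def _mate(pa, pb, rng: np.random.Generator):
    """Mendelian offspring of two (alleles, tags) parents; loci independent."""
    L = pa[0].shape[0]
    pick_a = rng.integers(0, 2, size=L)
    pick_b = rng.integers(0, 2, size=L)
    idx = np.arange(L)
    alleles = np.stack([pa[0][idx, pick_a], pb[0][idx, pick_b]], axis=1)
    tags = np.stack([pa[1][idx, pick_a], pb[1][idx, pick_b]], axis=1)
    return alleles, tags


def sim_colony(
    family_type: str,
    local_freqs: list[np.ndarray],
    workers_per_colony: int,
    g: int,
    founders_m: int,
    rng: np.random.Generator,
    neotenic_pairs: int = 3,
):
    """Simulate one colony's worker genotypes under the given breeding system.

    Extended colonies run ``g`` rounds of within-colony neotenic
    succession as ``neotenic_pairs`` parallel full-sib lineages: round 1
    forms disjoint pairs among the founders' offspring, and each lineage
    then continues with a full-sib pair of its own offspring.  Every
    worker's ancestry is a pure full-sib-mating chain, so its pedigree
    inbreeding equals the recurrence value F_g exactly, while different
    lineages drift and fix independently — the multi-reproductive genotype
    signature (>4 genotype classes, three or more homozygous classes,
    distorted Mendelian ratios) that distinguishes extended from simple
    families, and which deepens with ``g``.  ``g = 0`` degenerates to a
    simple family.

    Returns ``(alleles, autozygosity, founder_alleles)`` where ``alleles``
    is ``(workers, L, 2)`` allele *indices* into each locus's frequency
    vector, and ``autozygosity`` is each worker's realized fraction of loci
    with identical-by-descent gene copies.
    """
    if family_type not in FAMILY_TYPES:
        raise ValueError(f"unknown family type {family_type!r}")
    L = len(local_freqs)
    n = workers_per_colony

    if family_type == "mixed":
        founders = [_draw_founder(local_freqs, 2 * L * i, rng) for i in range(founders_m)]
        workers = []
        for _ in range(n):
            i, j = rng.choice(founders_m, size=2, replace=False)
            workers.append(_mate(founders[i], founders[j], rng))
    else:
        founders = [_draw_founder(local_freqs, 0, rng), _draw_founder(local_freqs, 2 * L, rng)]
        pair = (founders[0], founders[1])
        if family_type == "extended" and g > 0:
            # parallel full-sib lineages seeded from the founder sibship
            lineages = [
                (_mate(pair[0], pair[1], rng), _mate(pair[0], pair[1], rng))
                for _ in range(neotenic_pairs)
            ]
            for _ in range(g - 1):
                lineages = [
                    (_mate(pa, pb, rng), _mate(pa, pb, rng)) for pa, pb in lineages
                ]
            workers = []
            for _ in range(n):
                pa, pb = lineages[rng.integers(len(lineages))]
                workers.append(_mate(pa, pb, rng))
        else:
            workers = [_mate(pair[0], pair[1], rng) for _ in range(n)]

    alleles = np.stack([w[0] for w in workers])
    tags = np.stack([w[1] for w in workers])
    autozyg = (tags[:, :, 0] == tags[:, :, 1]).mean(axis=1)
    founder_alleles = np.stack([f[0] for f in founders])
    return alleles, autozyg, founder_alleles


# ----------------------------------------------------------------------
# dataset assembly


def _allele_labels(k: int) -> tuple[int, ...]:
    # fragment-size-like codes, 3-digit writable
    return tuple(100 + 2 * i for i in range(k))


def _colony_positions(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) per colony and the cluster index of each colony."""
    clusters = np.repeat(np.arange(cfg.n_clusters), cfg.colonies_per_cluster)
    ew, ns = cfg.area
    if cfg.layout == "gradient":
        t = np.linspace(0.0, 1.0, cfg.n_colonies)
        x = ew / 2 + rng.normal(0, ew / 20, size=cfg.n_colonies)
        y = t * ns
        return np.stack([x, y], axis=1), clusters
    centers_y = (np.arange(cfg.n_clusters) + 0.5) / cfg.n_clusters * ns
    x = ew / 2 + rng.normal(0, cfg.cluster_spread, size=cfg.n_colonies)
    y = centers_y[clusters] + rng.normal(0, cfg.cluster_spread, size=cfg.n_colonies)
    return np.stack([x, y], axis=1), clusters


def sim_dataset(cfg: SimConfig) -> tuple[GenotypeDataset, list[PedigreeTruth]]:
    """Generate a full dataset plus per-colony pedigree ground truth.

    Fully reproducible from ``cfg.seed``: a root seed sequence spawns one
    child stream for the global draws and one per colony, so adding colonies
    never reshuffles earlier ones.
    """
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_colonies + 1)
    root = np.random.default_rng(children[0])

    loci = [LocusDef(f"L{l + 1}", _allele_labels(k)) for l, k in enumerate(cfg.allele_template)]
    ancestral = [root.dirichlet(np.ones(k)) if k > 1 else np.ones(1) for k in cfg.allele_template]
    cluster_freqs = sim_cluster_freqs(
        ancestral, cfg.theta, cfg.n_clusters, root, calibrate_tol=cfg.divergence_tol
    )
    positions, clusters = _colony_positions(cfg, root)
    hap_freqs = cfg.haplotype_freqs or default_haplotype_freqs(cfg.n_clusters)

    if cfg.layout == "gradient":
        # stepping-stone interpolation between the first and last cluster pools
        t = np.linspace(0.0, 1.0, cfg.n_colonies)
        colony_freqs = [
            [(1 - ti) * cluster_freqs[0][l] + ti * cluster_freqs[-1][l] for l in range(cfg.n_loci)]
            for ti in t
        ]
    else:
        colony_freqs = [cluster_freqs[clusters[c]] for c in range(cfg.n_colonies)]

    individual_ids: list[str] = []
    colony_ids: list[str] = []
    rows: list[np.ndarray] = []
    geo: dict[str, ColonyGeo] = {}
    truths: list[PedigreeTruth] = []
    label_arrays = [np.array(locus.allele_labels) for locus in loci]

    for c in range(cfg.n_colonies):
        rng = np.random.default_rng(children[c + 1])
        cid = f"C{c + 1:02d}"
        ftype = FAMILY_TYPES[rng.choice(3, p=cfg.family_mix)]
        g = cfg.neotenic_generations if ftype == "extended" else 0
        idx, autozyg, founder_idx = sim_colony(
            ftype, colony_freqs[c], cfg.workers_per_colony, g, cfg.founders_m, rng,
            neotenic_pairs=cfg.neotenic_pairs,
        )
        codes = np.stack([label_arrays[l][idx[:, l, :]] for l in range(cfg.n_loci)], axis=1)
        founder_codes = np.stack(
            [label_arrays[l][founder_idx[:, l, :]] for l in range(cfg.n_loci)], axis=1
        )
        rows.append(codes)
        individual_ids.extend(f"{cid}W{w + 1}" for w in range(cfg.workers_per_colony))
        colony_ids.extend([cid] * cfg.workers_per_colony)
        hf = hap_freqs[clusters[c]]
        hap = str(rng.choice(list(hf.keys()), p=np.array(list(hf.values())) / sum(hf.values())))
        geo[cid] = ColonyGeo(cid, float(positions[c, 0]), float(positions[c, 1]), hap)
        truths.append(
            PedigreeTruth(cid, ftype, int(clusters[c]), g, fullsib_inbreeding(g), autozyg, founder_codes)
        )

    genotypes = np.concatenate(rows, axis=0)
    dataset = GenotypeDataset(loci, individual_ids, colony_ids, genotypes, geo)
    return dataset, truths


def write_truth_csv(truths: Sequence[PedigreeTruth], path: str | Path) -> None:
    """Colony-level ground truth table: id, family type, g, mean pedigree F."""
    lines = ["colony_id,true_family_type,cluster,g,expected_F,mean_realized_F"]
    for t in truths:
        lines.append(
            f"{t.colony_id},{t.family_type},{t.cluster},{t.g},{t.expected_f},{t.realized_f.mean()}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
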