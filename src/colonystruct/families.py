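"""Colony breeding-system classification from worker genotype distributions.

A colony of social-insect workers is classified as one of three family
types by comparing its observed genotypes with Mendelian expectations:

* **mixed** — some locus shows more than four alleles, which no single
  parental pair can produce: offspring must descend from more than two
  unrelated reproductives (e.g. after colony fusion).
* **extended** — allele counts are compatible with a single pair, but the
  worker genotypes are not: either no parental pair has positive Mendelian
  probability for every observed genotype class (>4 genotype classes or
  three or more homozygous classes at a locus are sufficient signatures),
  or the genotype *frequencies* deviate significantly from the best-fitting
  pair's expectations by a combined-locus G-test.  This is the signature of
  breeding by related neotenic reproductives descended from the founders.
* **simple** — worker genotypes and frequencies are consistent with the
  direct offspring of a single outbred pair.

The Mendelian screen enumerates candidate parental pairs over the observed
alleles plus "wildcard" alleles (unobserved parental alleles never required
to explain an observed class); the G-test uses the maximum-likelihood
compatible pair per locus and sums G and df over loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2

from .model import MISSING, GenotypeDataset

#: sentinel codes for unobserved parental ("wildcard") alleles; negative so
#: they can never collide with real allele codes
_WILDCARDS = (-101, -102, -103)

Geno = tuple[int, int]  # canonical: a <= b for real alleles; wildcards sort first


@dataclass(frozen=True)
class ParentalPair:
    """Two unordered diploid parent genotypes at one locus.

    ``offspring`` maps each possible offspring genotype class to its
    Mendelian probability (multiples of 1/4; at most 4 classes, at most 2
    of them homozygous).
    """

    parent_a: Geno
    parent_b: Geno
    offspring: dict[Geno, float]
    n_wildcards: int

    @staticmethod
    def make(pa: Geno, pb: Geno) -> "ParentalPair":
        pa, pb = tuple(sorted(pa)), tuple(sorted(pb))
        if pb < pa:
            pa, pb = pb, pa
        off: dict[Geno, float] = {}
        for x in pa:
            for y in pb:
                g = (min(x, y), max(x, y))
                off[g] = off.get(g, 0.0) + 0.25
        wild = sum(1 for a in set(pa + pb) if a < 0)
        return ParentalPair(pa, pb, off, wild)


def enumerate_parent_pairs(genotype_counts: Mapping[Geno, int]) -> list[ParentalPair]:
    """All single parental pairs compatible with the observed genotypes.

    A pair is compatible iff every observed genotype class has positive
    Mendelian probability under it; unobserved classes are permitted
    (finite sampling).  Candidate parental alleles are the observed alleles
    plus at most ``4 - n_observed`` wildcards (a pair carries at most four
    allele slots, and every observed allele must occupy one).  With more
    than four observed alleles the result is empty by construction.

    Returns pairs sorted by (number of wildcards, genotype order) — the
    deterministic tie-break order used downstream.
    """
    observed = [g for g, c in genotype_counts.items() if c > 0]
    observed = [(min(a, b), max(a, b)) for a, b in observed]
    alleles = sorted({a for g in observed for a in g})
    if len(alleles) > 4:
        return []
    universe = list(_WILDCARDS[: 4 - len(alleles)]) + alleles
    genotypes = [tuple(sorted(g)) for g in combinations_with_replacement(universe, 2)]
    out = []
    seen = set()
    for pa, pb in combinations_with_replacement(genotypes, 2):
        pair = ParentalPair.make(pa, pb)
        key = (pair.parent_a, pair.parent_b)
        if key in seen:
            continue
        seen.add(key)
        if len(set(pair.parent_a + pair.parent_b)) > 4:
            continue
        if all(g in pair.offspring for g in observed):
            out.append(pair)
    out.sort(key=lambda p: (p.n_wildcards, p.parent_a, p.parent_b))
    return out


def _loglik(pair: ParentalPair, counts: Mapping[Geno, int]) -> float:
    return sum(c * np.log(pair.offspring[g]) for g, c in counts.items() if c > 0)


def best_parent_pair(genotype_counts: Mapping[Geno, int]) -> ParentalPair | None:
    """The maximum-likelihood compatible pair (ties: fewer wildcards, then
    genotype order); ``None`` when no pair is compatible."""
    pairs = enumerate_parent_pairs(genotype_counts)
    if not pairs:
        return None
    # pairs are already in tie-break order; stable max on log-likelihood
    lls = [_loglik(p, genotype_counts) for p in pairs]
    return pairs[int(np.argmax(lls))]


def g_statistic(pair: ParentalPair, counts: Mapping[Geno, int]) -> tuple[float, int]:
    """Multinomial G against the pair's Mendelian class probabilities.

    G = 2 * sum O_g ln(O_g / E_g) over classes with O_g > 0, with
    E_g = n * p_g; df = (number of positive-probability classes) - 1.
    A pair with a single offspring class contributes G = 0, df = 0.
    """
    n = sum(counts.values())
    g = 0.0
    for cls, c in counts.items():
        if c > 0:
            g += c * np.log(c / (n * pair.offspring[cls]))
    df = len(pair.offspring) - 1
    return 2.0 * g, df


@dataclass
class FamilyCall:
    """Breeding-system verdict for one colony."""

    colony_id: str
    verdict: str  # simple | extended | mixed | insufficient_data
    rules: list[str]
    G: float | None = None
    df: int | None = None
    p_value: float | None = None
    best_pairs: dict[str, ParentalPair] | None = None


def _locus_counts(dataset: GenotypeDataset, rows: np.ndarray, l: int) -> dict[Geno, int]:
    counts: dict[Geno, int] = {}
    for i in rows:
        a, b = dataset.genotypes[i, l]
        if a == MISSING:
            continue
        counts[(int(a), int(b))] = counts.get((int(a), int(b)), 0) + 1
    return counts


def gtest_simple_family(
    per_locus_counts: Sequence[Mapping[Geno, int]],
    per_locus_pairs: Sequence[ParentalPair],
) -> tuple[float, int, float]:
    """Combined-locus G-test against the best-pair expectations.

    Sums per-locus G and df; p is the upper chi-square tail.  Must only be
    called when the Mendelian screen passed at every polymorphic locus.
    """
    if len(per_locus_counts) != len(per_locus_pairs):
        raise ValueError("counts and pairs must align per locus")
    G, df = 0.0, 0
    for counts, pair in zip(per_locus_counts, per_locus_pairs):
        if pair is None:
            raise ValueError("G-test called on a locus that failed the Mendelian screen")
        g_l, df_l = g_statistic(pair, counts)
        G += g_l
        df += df_l
    p = float(chi2.sf(G, df)) if df > 0 else 1.0
    return G, df, p


def classify_colony(
    dataset: GenotypeDataset,
    colony_id: str,
    alpha: float = 0.05,
    min_workers: int = 5,
) -> FamilyCall:
    """Classify one colony by the ordered decision rules.

    1. any locus with more than four alleles -> ``mixed``;
    2. any locus with no compatible parental pair -> ``extended``;
    3. combined-locus G-test p < alpha -> ``extended``;
    4. otherwise ``simple``.

    Colonies with fewer than ``min_workers`` workers genotyped at at least
    one locus get the ``insufficient_data`` verdict.
    """
    rows = dataset.colony_members(colony_id)
    usable = sum(1 for i in rows if (dataset.genotypes[i, :, 0] != MISSING).any())
    if usable < min_workers:
        return FamilyCall(colony_id, "insufficient_data", ["min_workers"])

    all_counts = [_locus_counts(dataset, rows, l) for l in range(dataset.n_loci)]
    for l, counts in enumerate(all_counts):
        n_alleles = len({a for g in counts for a in g})
        if n_alleles > 4:
            return FamilyCall(colony_id, "mixed", [f">4 alleles at {dataset.loci[l].name}"])

    pairs: dict[str, ParentalPair] = {}
    counts_used, pairs_used = [], []
    for l, counts in enumerate(all_counts):
        if not counts:
            continue
        best = best_parent_pair(counts)
        if best is None:
            return FamilyCall(
                colony_id, "extended", [f"Mendelian-inconsistent at {dataset.loci[l].name}"]
            )
        pairs[dataset.loci[l].name] = best
        counts_used.append(counts)
        pairs_used.append(best)

    G, df, p = gtest_simple_family(counts_used, pairs_used)
    if df > 0 and p < alpha:
        return FamilyCall(colony_id, "extended", ["G-test deviation"], G, df, p, pairs)
    return FamilyCall(colony_id, "simple", [], G, df, p, pairs)


def classify_dataset(
    dataset: GenotypeDataset,
    alpha: float = 0.05,
    min_workers: int = 5,
    cluster_of: Mapping[str, object] | None = None,
) -> tuple[list[FamilyCall], dict]:
    """Classify every colony and summarize family-type proportions.

    ``cluster_of`` optionally maps colony ids to cluster labels for a
    per-cluster breakdown.  Proportions are over classified colonies
    (``insufficient_data`` excluded).
    """
    calls = [classify_colony(dataset, c, alpha, min_workers) for c in dataset.colonies]

    def proportions(subset: list[FamilyCall]) -> dict[str, float]:
        done = [c for c in subset if c.verdict != "insufficient_data"]
        if not done:
            return {}
        return {
            t: sum(1 for c in done if c.verdict == t) / len(done)
            for t in ("simple", "extended", "mixed")
        }

    summary: dict = {"overall": proportions(calls), "n_classified": sum(
        1 for c in calls if c.verdict != "insufficient_data"
    )}
    if cluster_of is not None:
        by: dict[object, list[FamilyCall]] = {}
        for call in calls:
            if call.colony_id in cluster_of:
                by.setdefault(cluster_of[call.colony_id], []).append(call)
        summary["per_cluster"] = {str(k): proportions(v) for k, v in sorted(by.items(), key=lambda kv: str(kv[0]))}
    return calls, summary
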