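"""Classical population-genetic estimators and permutation tests.

* observed / Nei-unbiased expected heterozygosity per locus,
* Weir & Cockerham (1984) F-statistics from per-allele variance components
  (a: among groups, b: among individuals within groups, c: within
  individuals), with multi-locus estimates formed as ratios of summed
  components — never as means of per-locus ratios,
* exact (table enumeration, Levene conditional probabilities) or Monte
  Carlo one-sided tests of heterozygote deficiency,
* genotypic linkage-disequilibrium G-tests with permutation nulls and a
  Bonferroni-corrected all-pairs scan,
* hierarchical AMOVA on gene-copy mismatch distances (among colonies /
  among individuals within colonies / within individuals) with
  permutation significance.

All permutation p-values use the (1 + hits) / (1 + reps) estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import lgamma, log
from typing import Mapping, Sequence

import numpy as np

from .model import MISSING, GenotypeDataset


# ----------------------------------------------------------------------
# heterozygosity


def observed_expected_het(
    dataset: GenotypeDataset, rows: Sequence[int] | None = None
) -> dict:
    """Per-locus H_O and Nei's unbiased H_E, plus their means.

    H_E = (2n / (2n - 1)) * (1 - sum p_i^2) with n the number of genotyped
    individuals at the locus.  Loci with no data are reported as NaN.
    """
    rows = np.arange(dataset.n_individuals) if rows is None else np.asarray(rows)
    ho, he, ns = [], [], []
    for l in range(dataset.n_loci):
        g = dataset.genotypes[rows, l, :]
        ok = g[:, 0] != MISSING
        n = int(ok.sum())
        ns.append(n)
        if n == 0:
            ho.append(np.nan)
            he.append(np.nan)
            continue
        ho.append(float((g[ok, 0] != g[ok, 1]).mean()))
        _, counts = np.unique(g[ok].ravel(), return_counts=True)
        p = counts / counts.sum()
        he.append(float(2 * n / (2 * n - 1) * (1.0 - np.sum(p**2))))
    return {
        "per_locus": {
            dataset.loci[l].name: {"H_O": ho[l], "H_E": he[l], "n": ns[l]}
            for l in range(dataset.n_loci)
        },
        "mean_H_O": float(np.nanmean(ho)),
        "mean_H_E": float(np.nanmean(he)),
    }


# ----------------------------------------------------------------------
# Weir & Cockerham variance components


@dataclass
class FStatResult:
    """Per-locus and overall F-statistics with their variance components."""

    grouping: str
    per_locus: dict[str, dict[str, float]]
    overall: dict[str, float]
    components: dict[str, np.ndarray] = field(repr=False)  # summed a, b, c per locus
    p_fis: float | None = None
    p_fst: float | None = None
    n_perm: int = 0


def _wc_locus_components(alleles: np.ndarray, groups: np.ndarray) -> tuple[float, float, float]:
    """Summed (a, b, c) over alleles for one locus.

    ``alleles``: (n, 2) codes with no missing rows; ``groups``: (n,) codes.
    With a single group the among-group component a is 0 and b uses the
    single-population form (s^2 = 0).
    """
    gids = np.unique(groups)
    r = len(gids)
    n_i = np.array([(groups == g).sum() for g in gids], dtype=float)
    nbar = n_i.mean()
    uniq = np.unique(alleles)
    a_sum = b_sum = c_sum = 0.0
    if r > 1:
        n_c = (r * nbar - np.sum(n_i**2) / (r * nbar)) / (r - 1)
    for A in uniq:
        carries = alleles == A
        p_i = np.array([carries[groups == g].mean() for g in gids])
        het = carries.sum(axis=1) == 1
        h_i = np.array([het[groups == g].mean() for g in gids])
        pbar = np.sum(n_i * p_i) / (r * nbar)
        hbar = np.sum(n_i * h_i) / (r * nbar)
        if r > 1:
            s2 = np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1) * nbar)
            a = (nbar / n_c) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
        else:
            a = 0.0
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def _resolve_groups(dataset: GenotypeDataset, grouping) -> tuple[np.ndarray, str]:
    """Group code per individual.  ``grouping`` is "colony", a mapping
    colony_id -> label, or an explicit per-individual array."""
    if isinstance(grouping, str) and grouping == "colony":
        return dataset.colony_codes.copy(), "colony"
    if isinstance(grouping, Mapping):
        labels = [grouping[c] for c in dataset.colony_ids]
        uniq = {v: i for i, v in enumerate(dict.fromkeys(labels))}
        return np.array([uniq[v] for v in labels]), "colony-map"
    arr = np.asarray(grouping)
    if len(arr) != dataset.n_individuals:
        raise ValueError("per-individual grouping has wrong length")
    uniq = {v: i for i, v in enumerate(dict.fromkeys(arr.tolist()))}
    return np.array([uniq[v] for v in arr.tolist()]), "custom"


def wc_fstats(
    dataset: GenotypeDataset,
    grouping="colony",
    n_perm: int = 0,
    seed: int | None = None,
) -> FStatResult:
    """Weir & Cockerham F_IS / F_ST / F_IT with permutation significance.

    F_IS significance: alleles permuted among individuals within groups
    (one-sided toward heterozygote deficiency, F_IS* >= observed).
    F_ST significance: individuals permuted among groups (one-sided toward
    differentiation).  Monomorphic loci contribute nothing; a fully
    monomorphic dataset yields NaN estimates.
    """
    groups, gname = _resolve_groups(dataset, grouping)
    rng = np.random.default_rng(seed)

    def components(genos: np.ndarray, grp: np.ndarray) -> np.ndarray:
        comp = np.zeros((dataset.n_loci, 3))
        for l in range(dataset.n_loci):
            al = genos[:, l, :]
            ok = al[:, 0] != MISSING
            if ok.sum() < 2 or len(np.unique(al[ok])) < 2:
                continue
            comp[l] = _wc_locus_components(al[ok], grp[ok])
        return comp

    comp = components(dataset.genotypes, groups)

    def ratios(c: np.ndarray) -> dict[str, float]:
        a, b, cc = c.sum(axis=0) if c.ndim == 2 else c
        tot = a + b + cc
        return {
            "F_IS": 1 - cc / (b + cc) if (b + cc) != 0 else np.nan,
            "F_ST": a / tot if tot != 0 else np.nan,
            "F_IT": 1 - cc / tot if tot != 0 else np.nan,
        }

    per_locus = {}
    for l in range(dataset.n_loci):
        per_locus[dataset.loci[l].name] = (
            ratios(comp[l]) if comp[l].any() else {"F_IS": np.nan, "F_ST": np.nan, "F_IT": np.nan}
        )
    overall = ratios(comp)

    p_fis = p_fst = None
    if n_perm > 0:
        obs = overall
        hits_fis = hits_fst = 0
        n = dataset.n_individuals
        for _ in range(n_perm):
            # F_IS null: shuffle gene copies among individuals within groups
            shuf = dataset.genotypes.copy()
            for g in np.unique(groups):
                rows = np.flatnonzero(groups == g)
                for l in range(dataset.n_loci):
                    copies = shuf[rows, l, :].ravel()
                    ok = copies != MISSING
                    vals = copies[ok]
                    rng.shuffle(vals)
                    copies[ok] = vals
                    shuf[rows, l, :] = copies.reshape(-1, 2)
            st = ratios(components(shuf, groups))
            if not np.isnan(obs["F_IS"]) and st["F_IS"] >= obs["F_IS"] - 1e-12:
                hits_fis += 1
            # F_ST null: shuffle individuals among groups
            st2 = ratios(components(dataset.genotypes, rng.permutation(groups)))
            if not np.isnan(obs["F_ST"]) and st2["F_ST"] >= obs["F_ST"] - 1e-12:
                hits_fst += 1
        p_fis = (1 + hits_fis) / (1 + n_perm)
        p_fst = (1 + hits_fst) / (1 + n_perm)

    return FStatResult(gname, per_locus, overall, {"abc_per_locus": comp}, p_fis, p_fst, n_perm)


def pairwise_fst(
    dataset: GenotypeDataset,
    cluster_of: Mapping[str, object],
    n_perm: int = 1000,
    seed: int | None = None,
) -> dict[tuple, dict[str, float]]:
    """Pairwise multi-locus W&C F_ST between clusters with permutation p-values."""
    labels = sorted({str(v) for v in cluster_of.values()})
    out = {}
    ss = np.random.SeedSequence(seed).spawn(len(labels) * (len(labels) - 1) // 2)
    for k, (la, lb) in enumerate(combinations(labels, 2)):
        rows = [
            i
            for i, c in enumerate(dataset.colony_ids)
            if str(cluster_of.get(c)) in (la, lb)
        ]
        sub = dataset.subset(rows)
        res = wc_fstats(
            sub,
            {c: str(cluster_of[c]) for c in sub.colonies},
            n_perm=n_perm,
            seed=ss[k].generate_state(1)[0] % (2**31),
        )
        out[(la, lb)] = {"F_ST": res.overall["F_ST"], "p": res.p_fst}
    return out


# ----------------------------------------------------------------------
# Hardy-Weinberg heterozygote-deficiency test


@dataclass
class HweTestResult:
    locus: str
    group: str
    p_value: float
    method: str  # "enumeration" | "monte_carlo" | "monomorphic"
    mc_reps: int = 0
    het_observed: int = 0


def _levene_log_prob(table: dict[tuple[int, int], int], allele_counts: np.ndarray, n: int) -> float:
    """Log conditional probability of a genotype-count table given allele counts."""
    M = int(allele_counts.sum())
    lp = lgamma(n + 1) - lgamma(M + 1) + sum(lgamma(int(a) + 1) for a in allele_counts)
    H = 0
    for (i, j), g in table.items():
        lp -= lgamma(g + 1)
        if i != j:
            H += g
    return lp + H * log(2.0)


def _enumerate_het_distribution(allele_counts: np.ndarray, max_tables: int) -> dict[int, float] | None:
    """Exact distribution of the heterozygote count under random pairing.

    Enumerates all genotype-count tables with the given allele margins;
    returns ``None`` when more than ``max_tables`` tables are visited.
    """
    k = len(allele_counts)
    n = int(allele_counts.sum()) // 2
    if k > 6 or n > 40:  # table space far beyond any sensible budget
        return None
    cells = [(i, j) for i in range(k) for j in range(i, k)]
    dist: dict[int, float] = {}
    budget = [max_tables]

    def rec(idx: int, remaining: np.ndarray, table: dict, het: int) -> bool:
        budget[0] -= 1  # count every visited node, not only complete tables
        if budget[0] <= 0:
            return False
        if idx == len(cells):
            if remaining.any():
                return True
            p = np.exp(_levene_log_prob(table, allele_counts, n))
            dist[het] = dist.get(het, 0.0) + p
            return True
        i, j = cells[idx]
        if i == j:
            gmax = int(remaining[i] // 2)
        else:
            gmax = int(min(remaining[i], remaining[j]))
        for g in range(gmax + 1):
            remaining[i] -= 2 * g if i == j else g
            if i != j:
                remaining[j] -= g
            table[(i, j)] = g
            ok = rec(idx + 1, remaining, table, het + (0 if i == j else g))
            remaining[i] += 2 * g if i == j else g
            if i != j:
                remaining[j] += g
            del table[(i, j)]
            if not ok:
                return False
        return True

    complete = rec(0, allele_counts.astype(int).copy(), {}, 0)
    if not complete:
        return None
    total = sum(dist.values())
    return {h: p / total for h, p in dist.items()}


def hwe_deficiency_test(
    dataset: GenotypeDataset,
    locus: int,
    rows: Sequence[int] | None = None,
    group: str = "all",
    mc_reps: int = 10_000,
    max_tables: int = 200_000,
    seed: int | None = None,
) -> HweTestResult:
    """One-sided exact test of heterozygote deficiency at one locus.

    Conditional on the observed allele counts, the p-value is the
    probability of a genotype configuration with a heterozygote count at or
    below the observed one.  Uses full table enumeration when feasible
    (Levene conditional probabilities), else Monte Carlo re-pairing of the
    gene copies.  Monomorphic loci return p = 1.
    """
    rows = np.arange(dataset.n_individuals) if rows is None else np.asarray(rows)
    g = dataset.genotypes[rows, locus, :]
    g = g[g[:, 0] != MISSING]
    name = dataset.loci[locus].name
    if len(g) == 0:
        return HweTestResult(name, group, 1.0, "monomorphic")
    copies = g.ravel()
    uniq, counts = np.unique(copies, return_counts=True)
    het_obs = int((g[:, 0] != g[:, 1]).sum())
    if len(uniq) < 2:
        return HweTestResult(name, group, 1.0, "monomorphic", het_observed=het_obs)

    dist = _enumerate_het_distribution(counts.astype(np.int64), max_tables)
    if dist is not None:
        p = sum(pr for h, pr in dist.items() if h <= het_obs)
        return HweTestResult(name, group, float(min(p, 1.0)), "enumeration", het_observed=het_obs)

    rng = np.random.default_rng(seed)
    codes = np.searchsorted(uniq, copies)
    order = np.argsort(rng.random((mc_reps, len(codes))), axis=1)
    shuffled = codes[order].reshape(mc_reps, -1, 2)
    het_null = (shuffled[:, :, 0] != shuffled[:, :, 1]).sum(axis=1)
    hits = int((het_null <= het_obs).sum())
    p = (1 + hits) / (1 + mc_reps)
    return HweTestResult(name, group, p, "monte_carlo", mc_reps, het_obs)


# ----------------------------------------------------------------------
# genotypic linkage disequilibrium


def _g_from_table(table: np.ndarray) -> float:
    n = table.sum()
    if n == 0:
        return 0.0
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    E = row * col / n
    mask = table > 0
    return float(2.0 * np.sum(table[mask] * np.log(table[mask] / E[mask])))


def _geno_codes(dataset: GenotypeDataset, rows: np.ndarray, l: int) -> np.ndarray:
    g = dataset.genotypes[rows, l, :]
    pairs = [tuple(x) for x in g]
    uniq = {p: i for i, p in enumerate(sorted(set(pairs)))}
    return np.array([uniq[p] for p in pairs])


def ld_test(
    dataset: GenotypeDataset,
    locus_a: int,
    locus_b: int,
    mc_reps: int = 10_000,
    grouping=None,
    seed: int | None = None,
) -> float:
    """Permutation G-test of genotypic association between two loci.

    The statistic is G on the two-locus genotype contingency table; the
    null is generated by permuting one locus's genotypes across individuals
    (within groups when ``grouping`` is given).  Degenerate tables (either
    locus with a single genotype class) return p = 1.
    """
    rows = np.arange(dataset.n_individuals)
    ok = (dataset.genotypes[rows, locus_a, 0] != MISSING) & (
        dataset.genotypes[rows, locus_b, 0] != MISSING
    )
    rows = rows[ok]
    ca = _geno_codes(dataset, rows, locus_a)
    cb = _geno_codes(dataset, rows, locus_b)
    na, nb = ca.max() + 1, cb.max() + 1
    if na < 2 or nb < 2:
        return 1.0
    obs = _g_from_table(np.bincount(ca * nb + cb, minlength=na * nb).reshape(na, nb))
    rng = np.random.default_rng(seed)
    if grouping is None:
        group_rows = [np.arange(len(rows))]
    else:
        groups, _ = _resolve_groups(dataset, grouping)
        groups = groups[rows]
        group_rows = [np.flatnonzero(groups == g) for g in np.unique(groups)]
    hits = 0
    cb_perm = cb.copy()
    for _ in range(mc_reps):
        for gr in group_rows:
            cb_perm[gr] = cb_perm[gr][rng.permutation(len(gr))]
        g_null = _g_from_table(
            np.bincount(ca * nb + cb_perm, minlength=na * nb).reshape(na, nb)
        )
        if g_null >= obs - 1e-12:
            hits += 1
    return (1 + hits) / (1 + mc_reps)


def ld_scan(
    dataset: GenotypeDataset,
    mc_reps: int = 10_000,
    alpha: float = 0.05,
    grouping=None,
    seed: int | None = None,
) -> dict:
    """All-pairs genotypic LD with Bonferroni-adjusted decisions."""
    pairs = list(combinations(range(dataset.n_loci), 2))
    ss = np.random.SeedSequence(seed).spawn(len(pairs))
    threshold = alpha / len(pairs) if pairs else alpha
    results = {}
    for k, (i, j) in enumerate(pairs):
        p = ld_test(dataset, i, j, mc_reps, grouping, ss[k].generate_state(1)[0] % (2**31))
        results[(dataset.loci[i].name, dataset.loci[j].name)] = {
            "p": p,
            "significant": p < threshold,
        }
    return {"pairs": results, "bonferroni_alpha": threshold, "n_pairs": len(pairs)}


# ----------------------------------------------------------------------
# AMOVA


@dataclass
class AmovaResult:
    """Three-level AMOVA: among colonies / among individuals within
    colonies / within individuals."""

    ss: dict[str, float]
    df: dict[str, int]
    sigma2: dict[str, float]  # variance components a (colonies), b (individuals), c (copies)
    percent: dict[str, float]
    phi: dict[str, float]
    p_among_colonies: float | None = None
    p_within_individuals: float | None = None
    n_perm: int = 0


def _copy_distance_sq(dataset: GenotypeDataset) -> np.ndarray:
    """Squared distances between all gene copies: allele mismatch count
    over loci where both copies are genotyped."""
    n, L = dataset.n_individuals, dataset.n_loci
    copies = dataset.genotypes.transpose(0, 2, 1).reshape(2 * n, L)
    D = np.zeros((2 * n, 2 * n))
    for l in range(L):
        a = copies[:, l]
        ok = a != MISSING
        D += (a[:, None] != a[None, :]) & ok[:, None] & ok[None, :]
    return D


def _amova_components(D: np.ndarray, ind_of_copy: np.ndarray, col_of_ind: np.ndarray) -> dict:
    M = D.shape[0]
    col_of_copy = col_of_ind[ind_of_copy]
    N = len(col_of_ind)
    cols, m_c = np.unique(col_of_copy, return_counts=True)
    C = len(cols)

    total_sum = D.sum() / 2.0
    ss_total = total_sum / M
    ss_wc = 0.0
    for c, m in zip(cols, m_c):
        idx = np.flatnonzero(col_of_copy == c)
        ss_wc += D[np.ix_(idx, idx)].sum() / 2.0 / m
    ss_wi = 0.0
    for i in range(N):
        idx = np.flatnonzero(ind_of_copy == i)
        ss_wi += D[idx[0], idx[1]] / 2.0
    ss_ac = ss_total - ss_wc
    ss_ai = ss_wc - ss_wi

    df_ac, df_ai, df_wi = C - 1, N - C, N
    ms_ac = ss_ac / df_ac if df_ac else np.nan
    ms_ai = ss_ai / df_ai if df_ai else np.nan
    ms_wi = ss_wi / df_wi

    # expected-mean-square coefficients for copies nested in individuals
    # nested in colonies, individuals all diploid
    sum_mi2_over_mc = sum(
        np.sum(np.full((m_c[k] // 2,), 4.0)) / m_c[k] for k in range(C)
    )
    k1 = (M - sum_mi2_over_mc) / df_ai if df_ai else np.nan
    k2 = (sum_mi2_over_mc - 4.0 * N / M) / df_ac if df_ac else np.nan
    k3 = (M - np.sum(m_c.astype(float) ** 2) / M) / df_ac if df_ac else np.nan

    sigma_c = ms_wi
    sigma_b = (ms_ai - sigma_c) / k1 if df_ai else 0.0
    sigma_a = (ms_ac - sigma_c - k2 * sigma_b) / k3 if df_ac else 0.0
    return {
        "ss": {"among_colonies": ss_ac, "among_individuals": ss_ai, "within_individuals": ss_wi},
        "df": {"among_colonies": df_ac, "among_individuals": df_ai, "within_individuals": df_wi},
        "sigma2": {"a": sigma_a, "b": sigma_b, "c": sigma_c},
    }


def amova(
    dataset: GenotypeDataset, n_perm: int = 0, seed: int | None = None
) -> AmovaResult:
    """Hierarchical AMOVA on gene-copy mismatch distances.

    Variance is partitioned among colonies (a), among individuals within
    colonies (b), and within individuals (c) using the standard nested
    ANOVA expectations with unequal sizes.  Significance: the among-colony
    component by permuting individuals among colonies; the within-individual
    level by permuting gene copies among individuals within colonies
    (statistic: b / (b + c)).
    """
    if dataset.n_colonies < 2:
        raise ValueError("AMOVA needs at least two colonies")
    D = _copy_distance_sq(dataset)
    n = dataset.n_individuals
    ind_of_copy = np.repeat(np.arange(n), 2)
    # copies are laid out (ind0 copy0, ind0 copy1, ind1 copy0, ...): rebuild
    # to match _copy_distance_sq ordering (transpose(0,2,1) -> copy-major per ind)
    ind_of_copy = np.arange(2 * n) // 2
    col_of_ind = dataset.colony_codes

    base = _amova_components(D, ind_of_copy, col_of_ind)
    sa, sb, sc = base["sigma2"]["a"], base["sigma2"]["b"], base["sigma2"]["c"]
    tot = sa + sb + sc
    percent = {
        k: (100.0 * v / tot if tot != 0 else np.nan)
        for k, v in zip(
            ("among_colonies", "among_individuals", "within_individuals"), (sa, sb, sc)
        )
    }
    phi = {
        "Phi_CT": sa / tot if tot else np.nan,  # among colonies vs total
        "Phi_IS": sb / (sb + sc) if (sb + sc) else np.nan,
        "Phi_IT": (sa + sb) / tot if tot else np.nan,
    }

    p_ac = p_wi = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits_ac = hits_wi = 0
        phi_is_obs = phi["Phi_IS"]
        for _ in range(n_perm):
            perm_cols = rng.permutation(col_of_ind)
            r1 = _amova_components(D, ind_of_copy, perm_cols)
            s = r1["sigma2"]
            if s["a"] / (s["a"] + s["b"] + s["c"]) >= phi["Phi_CT"] - 1e-12:
                hits_ac += 1
            # permute copies among individuals within colonies
            perm = np.arange(2 * n)
            for ccode in np.unique(col_of_ind):
                idx = np.flatnonzero(col_of_ind[ind_of_copy] == ccode)
                perm[idx] = idx[rng.permutation(len(idx))]
            r2 = _amova_components(D[np.ix_(perm, perm)], ind_of_copy, col_of_ind)
            s2 = r2["sigma2"]
            denom = s2["b"] + s2["c"]
            if denom and s2["b"] / denom >= phi_is_obs - 1e-12:
                hits_wi += 1
        p_ac = (1 + hits_ac) / (1 + n_perm)
        p_wi = (1 + hits_wi) / (1 + n_perm)

    return AmovaResult(base["ss"], base["df"], base["sigma2"], percent, phi, p_ac, p_wi, n_perm)
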