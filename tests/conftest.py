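"""Shared fixtures and independent brute-force oracles.

The oracles reimplement each statistic directly from its defining formula
(plain Python loops, no shared code with the package) so the vectorized
implementations can be checked against them on small random instances.
"""

from __future__ import annotations

import numpy as np
import pytest

from colonystruct import GenotypeDataset, LocusDef


# ----------------------------------------------------------------------
# dataset builders


def dataset_from_arrays(genotypes, colony_ids, allele_labels=None):
    """Build a GenotypeDataset from a raw (n, L, 2) allele-code array."""
    genotypes = np.asarray(genotypes)
    n, L, _ = genotypes.shape
    loci = []
    for l in range(L):
        observed = sorted(set(genotypes[:, l, :].ravel().tolist()) - {-1})
        labels = tuple(observed) if observed else (0,)
        if allele_labels is not None:
            labels = tuple(allele_labels[l])
        loci.append(LocusDef(f"L{l + 1}", labels))
    ids = [f"i{i}" for i in range(n)]
    return GenotypeDataset(loci, ids, list(colony_ids), genotypes)


@pytest.fixture
def random_small_dataset():
    """Factory for small random datasets (<=5 colonies x <=6 ind x <=3 loci)."""

    def make(rng: np.random.Generator):
        n_col = rng.integers(2, 6)
        n_per = rng.integers(2, 7)
        n_loci = rng.integers(1, 4)
        n_alleles = [int(rng.integers(2, 5)) for _ in range(n_loci)]
        genos = np.stack(
            [rng.integers(0, k, size=(n_col * n_per, 2)) for k in n_alleles], axis=1
        )
        colony_ids = [f"c{j}" for j in range(n_col) for _ in range(n_per)]
        return dataset_from_arrays(genos, colony_ids)

    return make


# ----------------------------------------------------------------------
# Weir & Cockerham brute-force oracle


def wc_oracle(dataset: GenotypeDataset, groups) -> dict:
    """Direct summation of the per-allele variance-component formulas."""
    groups = np.asarray(groups)
    A = B = C = 0.0
    for l in range(dataset.n_loci):
        al = dataset.genotypes[:, l, :]
        ok = al[:, 0] != -1
        alle, grp = al[ok], groups[ok]
        if len(alle) < 2 or len(set(alle.ravel().tolist())) < 2:
            continue
        gids = sorted(set(grp.tolist()))
        r = len(gids)
        n_i = [float(sum(g == gid for g in grp)) for gid in gids]
        nbar = sum(n_i) / r
        if r > 1:
            n_c = (r * nbar - sum(x * x for x in n_i) / (r * nbar)) / (r - 1)
        for allele in sorted(set(alle.ravel().tolist())):
            p_i, h_i = [], []
            for gid in gids:
                rows = [k for k in range(len(grp)) if grp[k] == gid]
                p_i.append(sum((alle[k] == allele).sum() for k in rows) / (2.0 * len(rows)))
                h_i.append(
                    sum((alle[k] == allele).sum() == 1 for k in rows) / float(len(rows))
                )
            pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
            hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
            if r > 1:
                s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
                a = (nbar / n_c) * (
                    s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
                )
                b = (nbar / (nbar - 1)) * (
                    pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
                )
            else:
                a = 0.0
                b = (nbar / (nbar - 1)) * (
                    pbar * (1 - pbar) - (2 * nbar - 1) / (4 * nbar) * hbar
                )
            c = hbar / 2
            A, B, C = A + a, B + b, C + c
    tot = A + B + C
    return {
        "F_IS": 1 - C / (B + C) if (B + C) else np.nan,
        "F_ST": A / tot if tot else np.nan,
        "F_IT": 1 - C / tot if tot else np.nan,
    }


# ----------------------------------------------------------------------
# AMOVA brute-force oracle (pairwise distances, no scatter shortcut)


def amova_oracle(dataset: GenotypeDataset) -> dict:
    """Sums of squares from explicit gene-copy pair loops."""
    n, L = dataset.n_individuals, dataset.n_loci
    copies = []  # (colony, individual, allele-vector)
    for i in range(n):
        for c in range(2):
            copies.append((dataset.colony_ids[i], i, dataset.genotypes[i, :, c]))
    M = len(copies)

    def d2(x, y):
        return sum(
            1
            for l in range(L)
            if x[2][l] != -1 and y[2][l] != -1 and x[2][l] != y[2][l]
        )

    ss_total = sum(d2(copies[i], copies[j]) for i in range(M) for j in range(i + 1, M)) / M
    colonies = sorted(set(c for c, _, _ in copies))
    ss_wc = 0.0
    for col in colonies:
        sub = [cp for cp in copies if cp[0] == col]
        m = len(sub)
        ss_wc += sum(d2(sub[i], sub[j]) for i in range(m) for j in range(i + 1, m)) / m
    ss_wi = 0.0
    for ind in range(n):
        sub = [cp for cp in copies if cp[1] == ind]
        ss_wi += d2(sub[0], sub[1]) / 2.0
    C = len(colonies)
    df_ac, df_ai, df_wi = C - 1, n - C, n
    ms_ac, ms_ai, ms_wi = (ss_total - ss_wc) / df_ac, (ss_wc - ss_wi) / df_ai, ss_wi / df_wi
    m_c = [2 * sum(1 for cid in dataset.colony_ids if cid == col) for col in colonies]
    sum_mi2 = sum(4.0 * (m / 2) / m for m in m_c)  # = 2C for diploids
    k1 = (M - sum_mi2) / df_ai
    k2 = (sum_mi2 - 4.0 * n / M) / df_ac
    k3 = (M - sum(m * m for m in m_c) / M) / df_ac
    sc = ms_wi
    sb = (ms_ai - sc) / k1
    sa = (ms_ac - sc - k2 * sb) / k3
    return {
        "ss": {
            "among_colonies": ss_total - ss_wc,
            "among_individuals": ss_wc - ss_wi,
            "within_individuals": ss_wi,
        },
        "sigma2": {"a": sa, "b": sb, "c": sc},
    }


# ----------------------------------------------------------------------
# Moran / Mantel / G naive oracles


def morans_i_oracle(values, W) -> float:
    values = np.asarray(values, float)
    W = np.asarray(W, float)
    n = len(values)
    z = values - values.mean()
    num = sum(W[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return n / W.sum() * num / sum(z[i] ** 2 for i in range(n))


def mantel_r_oracle(d1, d2) -> float:
    n = d1.shape[0]
    x = [d1[i, j] for i in range(n) for j in range(i)]
    y = [d2[i, j] for i in range(n) for j in range(i)]
    x, y = np.array(x), np.array(y)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def g_stat_oracle(observed: dict, expected_probs: dict) -> float:
    n = sum(observed.values())
    g = 0.0
    for cls, o in observed.items():
        if o > 0:
            g += o * np.log(o / (n * expected_probs[cls]))
    return 2.0 * g
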