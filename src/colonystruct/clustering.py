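"""Admixture-model Bayesian clustering by Gibbs sampling, with Evanno
delta-K model selection.

The model is the standard admixture model for unlinked codominant markers:
K clusters are panmictic gene pools with their own allele frequencies
(Dirichlet(1) priors per locus); each diploid individual i has admixture
proportions q_i ~ Dirichlet(alpha) (alpha fixed, default 1), and each of
its gene copies originates from cluster k with probability q_ik and then
carries allele a with probability p_kla.  A Gibbs sweep updates, in turn,
the cluster-of-origin of every gene copy, the cluster allele frequencies,
and the individual admixture vectors, all from their full conditionals.

Per retained sweep the data log-likelihood ln P(X | P, Q) is recorded;
model support for a given K is summarized by the usual estimator
L(K) = mean(lnL) - var(lnL) / 2.  The number of clusters is then chosen
across replicate runs by the delta-K statistic: the absolute second
difference of mean L(K), normalized by the among-replicate standard
deviation at K.

Intended for one-individual-per-colony datasets so within-colony sibship
does not masquerade as population structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import MISSING, GenotypeDataset


@dataclass
class ClusterRunResult:
    """One MCMC run at a fixed K."""

    K: int
    q: np.ndarray = field(repr=False)  # posterior-mean admixture, individuals x K
    p: list[np.ndarray] = field(repr=False)  # posterior-mean freqs per locus, K x alleles
    lnl_trace: np.ndarray = field(repr=False)
    l_hat: float = np.nan
    seed: int | None = None
    burn_in: int = 0
    sweeps: int = 0
    thin: int = 1
    individual_ids: list[str] = field(default_factory=list)


def _flatten(dataset: GenotypeDataset):
    """Flat allele indexing across loci: copies (n, 2L) with global allele
    column offsets, a missing mask, and per-locus index blocks."""
    n, L = dataset.n_individuals, dataset.n_loci
    sizes = [locus.n_alleles for locus in dataset.loci]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    flat = np.zeros((n, 2 * L), dtype=np.int64)
    miss = np.zeros((n, 2 * L), dtype=bool)
    for l, locus in enumerate(dataset.loci):
        idx = locus.allele_index()
        g = dataset.genotypes[:, l, :]
        for c in range(2):
            col = 2 * l + c
            for i in range(n):
                a = int(g[i, c])
                if a == MISSING:
                    miss[i, col] = True
                else:
                    flat[i, col] = offsets[l] + idx[a]
    blocks = [np.arange(offsets[l], offsets[l + 1]) for l in range(L)]
    return flat, miss, offsets, blocks


def gibbs_admixture(
    dataset: GenotypeDataset,
    K: int,
    burn_in: int = 5_000,
    sweeps: int = 10_000,
    alpha_prior: float = 1.0,
    thin: int = 10,
    seed: int | None = None,
) -> ClusterRunResult:
    """Gibbs sampler for the admixture model at a fixed number of clusters.

    Scaled-down defaults (5,000 burn-in + 10,000 sweeps) suit desk-scale
    data; study-scale settings (50,000 + 100,000) are a parameter change.
    K = 1 is legal and serves as the no-structure reference: q is
    identically 1 and L(K) reduces to the Dirichlet-multinomial fit of the
    pooled allele frequencies.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    flat, miss, offsets, blocks = _flatten(dataset)
    n, ncop = flat.shape
    A = int(offsets[-1])
    ok = ~miss
    n_ok = int(ok.sum())

    # initial values
    q = np.full((n, K), 1.0 / K)
    p = np.empty((K, A))
    for b in blocks:
        p[:, b] = rng.dirichlet(np.ones(len(b)), size=K) if len(b) > 1 else 1.0

    q_sum = np.zeros((n, K))
    p_sum = np.zeros((K, A))
    lnl = []
    kept = 0

    total = burn_in + sweeps
    flat_rows = flat.ravel()
    ok_flat = ok.ravel()
    i_flat = np.repeat(np.arange(n), ncop)
    sizes = np.diff(offsets)
    block_of_col = np.repeat(np.arange(len(sizes)), sizes)
    for sweep in range(total):
        # 1. copy origins z | q, p (and the mixture likelihood for lnL)
        w = p[:, flat] * q.T[:, :, None]  # (K, n, 2L)
        tot = w.sum(axis=0)
        u = rng.random((n, ncop)) * tot
        z = (np.cumsum(w, axis=0) < u).sum(axis=0)

        # 2. p | z  (Dirichlet with allele counts per cluster)
        counts_p = np.bincount(
            (z.ravel() * A + flat_rows)[ok_flat], minlength=K * A
        ).reshape(K, A)
        gamma = rng.standard_gamma(1.0 + counts_p)
        block_sums = np.add.reduceat(gamma, offsets[:-1], axis=1)
        p = gamma / block_sums[:, block_of_col]

        # 3. q | z  (Dirichlet with copy counts per individual)
        counts_q = np.bincount(
            (i_flat * K + z.ravel())[ok_flat], minlength=n * K
        ).reshape(n, K)
        gq = rng.standard_gamma(alpha_prior + counts_q)
        q = gq / gq.sum(axis=1, keepdims=True)

        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            lnl.append(float(np.log(tot[ok]).sum()))
            # online relabeling: within-chain label switching would otherwise
            # average the admixture vectors toward uniformity
            if kept == 0 or K == 1:
                perm = np.arange(K)
            else:
                ref = p_sum / kept
                cost = ((ref[:, None, :] - p[None, :, :]) ** 2).sum(axis=2)
                perm = linear_sum_assignment(cost)[1]
            q_sum += q[:, perm]
            p_sum += p[perm, :]
            kept += 1

    lnl = np.array(lnl)
    l_hat = float(lnl.mean() - lnl.var(ddof=1) / 2.0) if len(lnl) > 1 else float(lnl.mean())
    p_mean = p_sum / kept
    return ClusterRunResult(
        K,
        q_sum / kept,
        [p_mean[:, b] for b in blocks],
        lnl,
        l_hat,
        seed,
        burn_in,
        sweeps,
        thin,
        list(dataset.individual_ids),
    )


# ----------------------------------------------------------------------
# Evanno delta-K


@dataclass
class DeltaKTable:
    """Replicate L(K) table with the delta-K statistic per interior K."""

    k_values: list[int]
    l_hat: dict[int, list[float]]
    mean_l: dict[int, float]
    sd_l: dict[int, float]
    delta_k: dict[int, float]
    selected_k: int | None


def evanno_deltak(l_hat_by_k: Mapping[int, Sequence[float]]) -> DeltaKTable:
    """delta-K model selection over replicate log-likelihood summaries.

    delta-K(K) = |mean L(K-1) - 2 mean L(K) + mean L(K+1)| / sd(K), defined
    for interior K with sd > 0; the selected K maximizes delta-K.  With all
    second differences zero (L linear in K) no K is selected.
    """
    ks = sorted(l_hat_by_k)
    if len(ks) < 3 or any(ks[i + 1] - ks[i] != 1 for i in range(len(ks) - 1)):
        raise ValueError("need at least 3 consecutive K values")
    if any(len(l_hat_by_k[k]) < 2 for k in ks):
        raise ValueError("need at least 2 replicates per K")
    mean_l = {k: float(np.mean(l_hat_by_k[k])) for k in ks}
    sd_l = {k: float(np.std(l_hat_by_k[k], ddof=1)) for k in ks}
    delta: dict[int, float] = {}
    for k in ks[1:-1]:
        second = abs(mean_l[k - 1] - 2 * mean_l[k] + mean_l[k + 1])
        if sd_l[k] > 0:
            delta[k] = second / sd_l[k]
    candidates = {k: v for k, v in delta.items() if v > 0}
    selected = max(candidates, key=candidates.get) if candidates else None
    return DeltaKTable(ks, {k: list(map(float, l_hat_by_k[k])) for k in ks}, mean_l, sd_l, delta, selected)


# ----------------------------------------------------------------------
# label alignment across runs


def _similarity(pa: list[np.ndarray], pb: list[np.ndarray], ka: int, kb: int) -> float:
    """Similarity of two clusters' frequency profiles across loci
    (negative squared distance)."""
    return -sum(float(np.sum((fa[ka] - fb[kb]) ** 2)) for fa, fb in zip(pa, pb))


def align_runs_greedy(reference: ClusterRunResult, run: ClusterRunResult) -> np.ndarray:
    """Greedy label matching of ``run`` onto ``reference``.

    Repeatedly pairs the most similar unmatched cluster frequency profiles.
    Returns ``perm`` with ``perm[k_ref] = k_run``.
    """
    K = reference.K
    sims = np.array(
        [[_similarity(reference.p, run.p, i, j) for j in range(K)] for i in range(K)]
    )
    perm = np.full(K, -1)
    used_i, used_j = set(), set()
    for _ in range(K):
        best = None
        for i in range(K):
            if i in used_i:
                continue
            for j in range(K):
                if j in used_j:
                    continue
                if best is None or sims[i, j] > best[0]:
                    best = (sims[i, j], i, j)
        _, i, j = best
        perm[i] = j
        used_i.add(i)
        used_j.add(j)
    return perm


def align_runs_exhaustive(reference: ClusterRunResult, run: ClusterRunResult) -> np.ndarray:
    """Optimal label matching by brute force over all K! permutations."""
    K = reference.K
    best, best_perm = -np.inf, None
    for pm in permutations(range(K)):
        s = sum(_similarity(reference.p, run.p, i, pm[i]) for i in range(K))
        if s > best:
            best, best_perm = s, np.array(pm)
    return best_perm


def align_and_summarize(runs: Sequence[ClusterRunResult], method: str = "greedy") -> dict:
    """Resolve label switching across replicate runs and build a consensus.

    The first run is the reference; every other run's labels are matched to
    it (greedy by default, exhaustive optional).  Returns the per-individual
    mean admixture matrix and the modal cluster of each individual.
    """
    if not runs:
        raise ValueError("need at least one run")
    align = align_runs_greedy if method == "greedy" else align_runs_exhaustive
    ref = runs[0]
    q_acc = ref.q.copy()
    for run in runs[1:]:
        if run.K != ref.K:
            raise ValueError("all runs must share K")
        perm = align(ref, run)
        q_acc += run.q[:, perm]
    q_mean = q_acc / len(runs)
    return {
        "q_mean": q_mean,
        "modal_cluster": q_mean.argmax(axis=1),
        "individual_ids": ref.individual_ids,
        "n_runs": len(runs),
        "K": ref.K,
    }


def assignment_accuracy(modal: np.ndarray, truth: np.ndarray) -> float:
    """Best-permutation agreement between inferred and true labels."""
    ks = np.unique(np.concatenate([modal, truth]))
    best = 0.0
    for pm in permutations(ks):
        mapping = dict(zip(ks, pm))
        acc = float(np.mean([mapping[m] == t for m, t in zip(modal, truth)]))
        best = max(best, acc)
    return best
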