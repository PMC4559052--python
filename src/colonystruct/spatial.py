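"""Spatial genetic structure: isolation by distance and spatial PCA.

Isolation by distance (IBD) is assessed by correlating Edwards' angular
genetic distances between colony allele-frequency profiles with Euclidean
geographic distances (Mantel permutation test), and by a two-dimensional
kernel density of the pairwise scatter, which distinguishes a continuous
cline (one cloud) from distinct differentiated patches (several modes).

Spatial PCA (sPCA) finds linear combinations of allele frequencies that
maximize the product of variance and Moran's spatial autocorrelation:
with column-centered frequencies X (colonies x alleles) and a
row-normalized K-nearest-neighbor weight matrix W, the analysis
eigendecomposes H = (1/n) X' ((W + W') / 2) X.  Because row normalization
makes the total weight equal n, each eigenvalue factorizes exactly as
lambda_i = var(score_i) * I(score_i): large positive eigenvalues are
*global* structures (neighboring colonies alike), large negative ones are
*local* structures (neighbors dissimilar).  Global/local significance is
assessed by permuting colony profiles over locations and recording the
extreme positive (resp. negative) eigenvalue — a permutation statistic
sharing the null of the classical sPCA tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import GenotypeDataset, GroupFrequencies, frequency_matrix


# ----------------------------------------------------------------------
# genetic & geographic distances


def edwards_distance(fa: GroupFrequencies, fb: GroupFrequencies) -> float:
    """Edwards' angular distance between two frequency profiles.

    D = sqrt(1 - (1/L) * sum_l sum_a sqrt(p_la * q_la)); loci with zero
    gene copies in either group are dropped (L reduced).
    """
    overlap, L = 0.0, 0
    for l, (p, q) in enumerate(zip(fa.freqs, fb.freqs)):
        if l in fa.empty_loci or l in fb.empty_loci:
            continue
        overlap += float(np.sum(np.sqrt(p * q)))
        L += 1
    if L == 0:
        raise ValueError("no locus with data in both groups")
    return float(np.sqrt(max(0.0, 1.0 - overlap / L)))


def edwards_distance_matrix(freqs: Sequence[GroupFrequencies]) -> np.ndarray:
    n = len(freqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = edwards_distance(freqs[i], freqs[j])
    return D


def geographic_distance_matrix(coords: np.ndarray) -> np.ndarray:
    d = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((d**2).sum(axis=2))


def mantel_test(
    d_gen: np.ndarray, d_geo: np.ndarray, n_perm: int = 999, seed: int | None = None
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation over lower-triangle entries; the null is
    generated by simultaneous row/column permutation of one matrix;
    one-sided p for positive association, (1 + hits) / (1 + n_perm).
    """
    d_gen = np.asarray(d_gen, float)
    d_geo = np.asarray(d_geo, float)
    if d_gen.shape != d_geo.shape or d_gen.shape[0] != d_gen.shape[1]:
        raise ValueError("distance matrices must be square and of equal size")
    il = np.tril_indices_from(d_gen, k=-1)
    x = d_gen[il]

    def corr_with(mat: np.ndarray) -> float:
        y = mat[il]
        xm, ym = x - x.mean(), y - y.mean()
        denom = np.sqrt((xm**2).sum() * (ym**2).sum())
        return float((xm * ym).sum() / denom) if denom else np.nan

    r = corr_with(d_geo)
    rng = np.random.default_rng(seed)
    hits = 0
    n = d_gen.shape[0]
    for _ in range(n_perm):
        p = rng.permutation(n)
        if corr_with(d_geo[np.ix_(p, p)]) >= r - 1e-12:
            hits += 1
    return r, (1 + hits) / (1 + n_perm)


def ibd_density(
    d_gen: np.ndarray,
    d_geo: np.ndarray,
    bandwidth: tuple[float, float] | None = None,
    gridsize: int = 100,
) -> dict:
    """Gaussian product-kernel density of the (geographic, genetic) scatter.

    Bandwidths default to the per-axis normal-reference rule
    (sigma * m^(-1/6) for m pairs, the 2-D Scott rule).  Returns grid axes
    and a density integrating to ~1 over the grid.
    """
    il = np.tril_indices_from(np.asarray(d_gen), k=-1)
    x = np.asarray(d_geo, float)[il]
    y = np.asarray(d_gen, float)[il]
    m = len(x)
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance axis: kernel density undefined")
    if bandwidth is None:
        bandwidth = (sx * m ** (-1 / 6), sy * m ** (-1 / 6))
    hx, hy = bandwidth
    gx = np.linspace(x.min() - 3 * hx, x.max() + 3 * hx, gridsize)
    gy = np.linspace(y.min() - 3 * hy, y.max() + 3 * hy, gridsize)
    kx = np.exp(-0.5 * ((gx[:, None] - x[None, :]) / hx) ** 2) / (hx * np.sqrt(2 * np.pi))
    ky = np.exp(-0.5 * ((gy[:, None] - y[None, :]) / hy) ** 2) / (hy * np.sqrt(2 * np.pi))
    dens = kx @ ky.T / m  # (gridsize_x, gridsize_y)
    return {"x": gx, "y": gy, "density": dens.T, "bandwidth": (hx, hy)}


# ----------------------------------------------------------------------
# connection network and Moran's I


@dataclass
class ConnectionNetwork:
    """K-nearest-neighbor connection network with row-normalized weights."""

    node_ids: list[str]
    adjacency: np.ndarray = field(repr=False)  # binary, not necessarily symmetric
    W: np.ndarray = field(repr=False)  # row-normalized
    K: int = 0


def knn_graph(coords: np.ndarray, node_ids: Sequence[str], K: int) -> ConnectionNetwork:
    """Directed K-nearest-neighbor graph on planar coordinates.

    Distance ties are broken by node order (lower index first); duplicated
    coordinates are allowed (zero-distance neighbors come first).
    """
    coords = np.asarray(coords, float)
    n = len(coords)
    if K < 1 or K > n - 1:
        raise ValueError("K must be between 1 and n - 1")
    D = geographic_distance_matrix(coords)
    A = np.zeros((n, n))
    idx = np.arange(n)
    for i in range(n):
        order = np.lexsort((idx, D[i]))
        neighbors = [j for j in order if j != i][:K]
        A[i, neighbors] = 1.0
    W = A / A.sum(axis=1, keepdims=True)
    return ConnectionNetwork(list(node_ids), A, W, K)


def morans_i(values: np.ndarray, W: np.ndarray) -> float:
    """Moran's spatial autocorrelation: I = (n / sum W) * (z' W z) / (z' z)."""
    z = np.asarray(values, float)
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("Moran's I undefined for a constant vector")
    n = len(z)
    return float(n / W.sum() * (z @ W @ z) / denom)


# ----------------------------------------------------------------------
# spatial PCA


@dataclass
class SpcaResult:
    """Eigenstructure of the variance x autocorrelation criterion."""

    eigenvalues: np.ndarray  # signed, sorted descending
    scores: np.ndarray = field(repr=False)  # colonies x axes
    loadings: np.ndarray = field(repr=False)  # squared eigenvector components, alleles x axes
    axis_variance: np.ndarray = field(default=None, repr=False)
    axis_moran: np.ndarray = field(default=None, repr=False)
    allele_labels: list[str] = field(default_factory=list)
    colony_ids: list[str] = field(default_factory=list)
    global_p: float | None = None
    local_p: float | None = None


def _spca_matrix(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    Xc = X - X.mean(axis=0, keepdims=True)
    Wsym = (W + W.T) / 2.0
    return Xc.T @ Wsym @ Xc / n, Xc


def spca(
    X: np.ndarray,
    network: ConnectionNetwork,
    allele_labels: Sequence[str] | None = None,
    n_axes: int | None = None,
) -> SpcaResult:
    """Spatial PCA of a colony allele-frequency matrix.

    ``X`` is (colonies x alleles); it is column-centered internally.  One
    individual genotype per colony works as a degenerate frequency profile
    (values in {0, 0.5, 1}).  Eigenvalues are signed and sorted descending;
    scores are the centered data projected on each eigenvector; loadings
    are the squared eigenvector components (summing to 1 per axis).
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("sPCA needs at least 3 colonies")
    if network.W.shape[0] != n:
        raise ValueError("network and data disagree on the number of colonies")
    H, Xc = _spca_matrix(X, network.W)
    vals, vecs = np.linalg.eigh((H + H.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if n_axes is not None:  # leading (global) axes only; None keeps all
        vals, vecs = vals[:n_axes], vecs[:, :n_axes]
    scores = Xc @ vecs
    var = scores.var(axis=0)
    moran = np.array(
        [morans_i(scores[:, i], network.W) if var[i] > 0 else np.nan for i in range(scores.shape[1])]
    )
    return SpcaResult(
        vals,
        scores,
        vecs**2,
        var,
        moran,
        list(allele_labels) if allele_labels else [f"a{i}" for i in range(X.shape[1])],
        list(network.node_ids),
    )


def spca_tests(
    X: np.ndarray,
    network: ConnectionNetwork,
    n_perm: int = 9999,
    seed: int | None = None,
) -> dict:
    """Permutation tests for global and local spatial structure.

    Statistics: the largest positive eigenvalue of H (global) and the
    largest-magnitude negative eigenvalue (local); the null permutes colony
    frequency profiles over locations.  p = (1 + hits) / (1 + n_perm).
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    H, _ = _spca_matrix(X, network.W)
    vals = np.linalg.eigvalsh((H + H.T) / 2.0)
    stat_g = float(vals.max())
    stat_l = float(max(0.0, -vals.min()))
    rng = np.random.default_rng(seed)
    hits_g = hits_l = 0
    for _ in range(n_perm):
        Hp, _ = _spca_matrix(X[rng.permutation(n)], network.W)
        v = np.linalg.eigvalsh((Hp + Hp.T) / 2.0)
        if v.max() >= stat_g - 1e-15:
            hits_g += 1
        if max(0.0, -v.min()) >= stat_l - 1e-15:
            hits_l += 1
    return {
        "global_stat": stat_g,
        "global_p": (1 + hits_g) / (1 + n_perm),
        "local_stat": stat_l,
        "local_p": (1 + hits_l) / (1 + n_perm),
        "n_perm": n_perm,
    }


def loading_report(result: SpcaResult, axis: int = 0, top_k: int | None = None) -> list[tuple[str, float]]:
    """Alleles ranked by squared loading on one axis (largest first)."""
    lo = result.loadings[:, axis]
    order = np.argsort(lo)[::-1]
    if top_k is not None:
        order = order[:top_k]
    return [(result.allele_labels[i], float(lo[i])) for i in order]


def colony_frequency_matrix(dataset: GenotypeDataset, freqs: Sequence[GroupFrequencies]):
    """Convenience wrapper: stack per-colony frequencies with allele labels."""
    return frequency_matrix(freqs, dataset.loci)
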