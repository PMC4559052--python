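"""Core data structures for colony-structured diploid genotype data.

The central container is :class:`GenotypeDataset`: a set of diploid
individuals, each belonging to a colony, genotyped at a shared panel of
codominant loci (microsatellites).  Genotypes are stored as a dense
``(n_individuals, n_loci, 2)`` integer array of allele codes with ``-1``
marking missing data; the pair of alleles at a locus is unordered and kept
in canonical order (low allele first) so equality of genotypes is
representation independent.

Colonies carry optional geographic metadata (:class:`ColonyGeo`): planar
x/y coordinates in meters and an optional maternally inherited haplotype
label (e.g. a mitochondrial COII haplotype).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

MISSING = -1


@dataclass(frozen=True)
class LocusDef:
    """A codominant locus: a name and the ordered set of known allele codes.

    Allele codes are opaque integers (nominally fragment sizes in bp); no
    repeat-unit structure is assumed.
    """

    name: str
    allele_labels: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.allele_labels) < 1:
            raise ValueError(f"locus {self.name!r} must declare at least one allele")
        if len(set(self.allele_labels)) != len(self.allele_labels):
            raise ValueError(f"locus {self.name!r} has duplicate allele labels")

    @property
    def n_alleles(self) -> int:
        return len(self.allele_labels)

    def allele_index(self) -> dict[int, int]:
        return {a: i for i, a in enumerate(self.allele_labels)}


@dataclass(frozen=True)
class Genotype:
    """One unordered diploid genotype; canonical order ``allele_a <= allele_b``."""

    allele_a: int
    allele_b: int

    @classmethod
    def of(cls, a: int, b: int) -> "Genotype":
        if a == MISSING or b == MISSING:
            return cls(MISSING, MISSING)
        return cls(min(a, b), max(a, b))

    @property
    def missing(self) -> bool:
        return self.allele_a == MISSING

    @property
    def homozygous(self) -> bool:
        return not self.missing and self.allele_a == self.allele_b


@dataclass(frozen=True)
class IndividualRecord:
    """One individual: id, colony membership and its genotype vector."""

    individual_id: str
    colony_id: str
    genotypes: tuple[Genotype, ...]


@dataclass(frozen=True)
class ColonyGeo:
    """Colony location (planar meters) and optional mtDNA haplotype label."""

    colony_id: str
    x: float
    y: float
    haplotype: str | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"colony {self.colony_id!r} has non-finite coordinates")


@dataclass
class GroupFrequencies:
    """Per-locus allele frequencies and gene-copy counts for one group.

    ``freqs[l]`` is aligned to ``loci[l].allele_labels``; ``n_copies[l]`` is
    the number of non-missing gene copies the estimate is based on.  A locus
    with zero copies has a zero vector and is flagged in ``empty_loci``.
    """

    group_id: str
    freqs: list[np.ndarray]
    n_copies: np.ndarray
    empty_loci: list[int] = field(default_factory=list)


class GenotypeDataset:
    """Diploid individuals grouped into colonies, genotyped at shared loci.

    Parameters
    ----------
    loci:
        Locus definitions; every allele observed in ``genotypes`` must appear
        in its locus's ``allele_labels``.
    individual_ids, colony_ids:
        Per-individual identifiers; parallel sequences.
    genotypes:
        ``(n, L, 2)`` integer allele codes, ``-1`` for missing.  Stored in
        canonical (sorted) order along the last axis.
    geo:
        Optional mapping ``colony_id -> ColonyGeo``; when given, every colony
        present in ``colony_ids`` must have an entry.
    """

    def __init__(
        self,
        loci: Sequence[LocusDef],
        individual_ids: Sequence[str],
        colony_ids: Sequence[str],
        genotypes: np.ndarray,
        geo: Mapping[str, ColonyGeo] | None = None,
    ) -> None:
        genotypes = np.asarray(genotypes, dtype=np.int64)
        if genotypes.ndim != 3 or genotypes.shape[2] != 2:
            raise ValueError("genotypes must have shape (n, n_loci, 2)")
        if genotypes.shape[0] != len(individual_ids) or len(individual_ids) != len(colony_ids):
            raise ValueError("individual_ids, colony_ids and genotypes disagree on n")
        if genotypes.shape[1] != len(loci):
            raise ValueError("genotype vector length must equal the locus list length")
        # canonicalize: sort allele pairs; any missing allele voids the genotype
        g = np.sort(genotypes, axis=2)
        any_missing = (genotypes == MISSING).any(axis=2)
        g[any_missing] = MISSING
        self.loci = list(loci)
        self.individual_ids = list(individual_ids)
        self.colony_ids = list(colony_ids)
        self.genotypes = g
        self.colonies: list[str] = list(dict.fromkeys(self.colony_ids))
        self._colony_index = {c: i for i, c in enumerate(self.colonies)}
        self.colony_codes = np.array([self._colony_index[c] for c in self.colony_ids])
        self.geo: dict[str, ColonyGeo] = dict(geo) if geo else {}
        if self.geo:
            missing_geo = [c for c in self.colonies if c not in self.geo]
            if missing_geo:
                raise ValueError(f"colonies without ColonyGeo: {missing_geo}")
        for l, locus in enumerate(self.loci):
            observed = set(np.unique(g[:, l, :]).tolist()) - {MISSING}
            unknown = observed - set(locus.allele_labels)
            if unknown:
                raise ValueError(
                    f"alleles {sorted(unknown)} at locus {locus.name!r} missing from allele_labels"
                )

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_colonies(self) -> int:
        return len(self.colonies)

    def records(self) -> Iterable[IndividualRecord]:
        for i, (iid, cid) in enumerate(zip(self.individual_ids, self.colony_ids)):
            yield IndividualRecord(
                iid, cid, tuple(Genotype.of(*self.genotypes[i, l]) for l in range(self.n_loci))
            )

    def colony_members(self, colony_id: str) -> np.ndarray:
        """Row indices of the individuals belonging to ``colony_id``."""
        return np.flatnonzero(self.colony_codes == self._colony_index[colony_id])

    def subset(self, rows: Sequence[int]) -> "GenotypeDataset":
        rows = np.asarray(rows)
        return GenotypeDataset(
            self.loci,
            [self.individual_ids[i] for i in rows],
            [self.colony_ids[i] for i in rows],
            self.genotypes[rows],
            {c: self.geo[c] for c in dict.fromkeys(self.colony_ids[i] for i in rows)}
            if self.geo
            else None,
        )

    def coords(self) -> np.ndarray:
        """Colony coordinates, ``(n_colonies, 2)``, in ``self.colonies`` order."""
        if not self.geo:
            raise ValueError("dataset has no colony geography")
        return np.array([[self.geo[c].x, self.geo[c].y] for c in self.colonies])

    def equivalent(self, other: "GenotypeDataset") -> bool:
        """Equality of genotype content, colony partition and locus order."""
        return (
            [l.name for l in self.loci] == [l.name for l in other.loci]
            and self.colony_ids == other.colony_ids
            and np.array_equal(self.genotypes, other.genotypes)
        )


# ----------------------------------------------------------------------
# frequencies


def group_allele_frequencies(
    dataset: GenotypeDataset, groups: Mapping[str, Sequence[int]]
) -> list[GroupFrequencies]:
    """Allele frequencies per group over non-missing gene copies.

    ``groups`` maps a group id to the row indices of its members.
    """
    out = []
    for gid, rows in groups.items():
        rows = np.asarray(rows)
        freqs, copies, empty = [], [], []
        for l, locus in enumerate(dataset.loci):
            alleles = dataset.genotypes[rows, l, :].ravel()
            alleles = alleles[alleles != MISSING]
            idx = locus.allele_index()
            counts = np.zeros(locus.n_alleles)
            for a in alleles:
                counts[idx[int(a)]] += 1
            n = counts.sum()
            if n == 0:
                empty.append(l)
                freqs.append(counts)
            else:
                freqs.append(counts / n)
            copies.append(int(n))
        out.append(GroupFrequencies(gid, freqs, np.array(copies), empty))
    return out


def colony_allele_frequencies(dataset: GenotypeDataset) -> list[GroupFrequencies]:
    """Per-colony allele frequencies (one :class:`GroupFrequencies` per colony)."""
    groups = {c: dataset.colony_members(c) for c in dataset.colonies}
    return group_allele_frequencies(dataset, groups)


def frequency_matrix(freq_list: Sequence[GroupFrequencies], loci: Sequence[LocusDef]):
    """Stack group frequencies into a (groups x total alleles) matrix.

    Returns ``(X, labels)`` where labels are ``"loc{l+1}.{allele}"`` strings
    naming each column by locus index and allele code.
    """
    X = np.vstack([np.concatenate(gf.freqs) for gf in freq_list])
    labels = [
        f"loc{l + 1}.{a}" for l, locus in enumerate(loci) for a in locus.allele_labels
    ]
    return X, labels


# ----------------------------------------------------------------------
# haplotypes and coordinates


def haplotype_summary(
    geo: Iterable[ColonyGeo], regions: Mapping[str, str] | None = None
) -> dict:
    """Counts and proportions of colony haplotype labels.

    Returns ``{"overall": {label: (count, proportion)}, "regions": {...}}``;
    proportions are over labeled colonies only.  ``regions`` optionally maps
    colony ids to region names for a per-region breakdown.
    """

    def summarize(labels: list[str]) -> dict[str, tuple[int, float]]:
        total = len(labels)
        out = {}
        for lab in sorted(set(labels)):
            c = labels.count(lab)
            out[lab] = (c, c / total)
        return out

    labeled = [g for g in geo if g.haplotype is not None]
    result = {"overall": summarize([g.haplotype for g in labeled])}
    if regions is not None:
        by_region: dict[str, list[str]] = {}
        for g in labeled:
            if g.colony_id in regions:
                by_region.setdefault(regions[g.colony_id], []).append(g.haplotype)
        result["regions"] = {r: summarize(v) for r, v in sorted(by_region.items())}
    return result


def lonlat_to_planar(lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular projection to planar meters at the mean latitude.

    A convenience for datasets whose coordinates arrive as lon/lat degrees;
    Euclidean distances on the result approximate great-circle distances for
    regional-scale extents.
    """
    R = 6_371_000.0
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lat0 = np.deg2rad(lat.mean())
    x = np.deg2rad(lon) * R * np.cos(lat0)
    y = np.deg2rad(lat) * R
    return x, y
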