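"""GENEPOP text format reader/writer and the colony metadata CSV.

The GENEPOP dialect handled here: a title line, locus names (one per line,
or one line comma-separated), colony blocks separated by a line reading
``pop`` (case-insensitive), and individual rows ``id , g1 g2 ...`` where
each genotype field concatenates two allele codes of fixed width (2 or 3
digits per allele); ``00``/``000`` encodes a missing allele.  One ``pop``
block is interpreted as one colony.  The writer always emits the 3-digit
dialect.

The colony metadata table is a CSV ``colony_id,x,y[,haplotype]`` with
planar coordinates in meters and an optional haplotype label per colony.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import MISSING, ColonyGeo, GenotypeDataset, LocusDef


class GenepopParseError(ValueError):
    """Malformed GENEPOP content; the message names the offending line."""


def _parse_genotype_field(field: str, lineno: int) -> tuple[int, int]:
    if len(field) == 4:
        w = 2
    elif len(field) == 6:
        w = 3
    else:
        raise GenepopParseError(
            f"line {lineno}: genotype field {field!r} is not 4 or 6 digits wide"
        )
    if not field.isdigit():
        raise GenepopParseError(f"line {lineno}: genotype field {field!r} is not numeric")
    a, b = int(field[:w]), int(field[w:])
    return (a if a != 0 else MISSING), (b if b != 0 else MISSING)


def read_genepop(path: str | Path) -> GenotypeDataset:
    """Read a GENEPOP file into a :class:`GenotypeDataset` (no coordinates).

    Colony ids are taken from each pop block's first individual id prefix if
    rows share one (common convention), else ``pop1``, ``pop2``, ...;
    individual ids are ``<colony>_<k>``.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise GenepopParseError("file too short to be GENEPOP")
    # locus names: lines 2.. until first "pop"
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = [s.strip() for s in lines[i].split(",") if s.strip()]
        locus_names.extend(chunk)
        i += 1
    if i == len(lines):
        raise GenepopParseError("no 'pop' separator found")
    n_loci = len(locus_names)

    pops: list[list[tuple[str, list[tuple[int, int]]]]] = []
    current: list[tuple[str, list[tuple[int, int]]]] | None = None
    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            current = []
            pops.append(current)
            continue
        if current is None:
            raise GenepopParseError(f"line {lineno + 1}: data before first 'pop'")
        if "," in line:
            ident, _, rest = line.partition(",")
        else:  # tolerate missing comma: first token is the id
            ident, _, rest = line.partition(" ")
        fields = rest.split()
        if len(fields) != n_loci:
            raise GenepopParseError(
                f"line {lineno + 1}: {len(fields)} genotype fields, expected {n_loci}"
            )
        genos = [_parse_genotype_field(f, lineno + 1) for f in fields]
        current.append((ident.strip(), genos))

    colony_ids: list[str] = []
    individual_ids: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    for p, pop in enumerate(pops):
        ids = [ident for ident, _ in pop]
        prefix = ids[0] if ids and all(x == ids[0] for x in ids) else None
        cid = prefix if prefix else f"pop{p + 1}"
        for k, (ident, genos) in enumerate(pop):
            colony_ids.append(cid)
            individual_ids.append(f"{cid}_{k + 1}" if prefix else ident)
            rows.append(genos)

    arr = np.array(rows, dtype=np.int64) if rows else np.empty((0, n_loci, 2), dtype=np.int64)
    loci = []
    for l, name in enumerate(locus_names):
        observed = sorted(set(arr[:, l, :].ravel().tolist()) - {MISSING}) if len(rows) else []
        loci.append(LocusDef(name, tuple(observed) if observed else (0,)))
    return GenotypeDataset(loci, individual_ids, colony_ids, arr)


def write_genepop(dataset: GenotypeDataset, path: str | Path, title: str = "colonystruct export") -> None:
    """Write the 3-digit GENEPOP dialect, one ``pop`` block per colony."""
    wide = any(a > 999 for locus in dataset.loci for a in locus.allele_labels)
    if wide:
        raise ValueError("allele codes above 999 cannot be written in the 3-digit dialect")

    def fmt(a: int) -> str:
        return "000" if a == MISSING else f"{a:03d}"

    out = [title]
    out.extend(locus.name for locus in dataset.loci)
    for c in dataset.colonies:
        out.append("pop")
        for i in dataset.colony_members(c):
            g = dataset.genotypes[i]
            fields = " ".join(fmt(int(g[l, 0])) + fmt(int(g[l, 1])) for l in range(dataset.n_loci))
            out.append(f"{dataset.colony_ids[i]} , {fields}")
    Path(path).write_text("\n".join(out) + "\n")


# ----------------------------------------------------------------------


def read_colony_table(path: str | Path) -> list[ColonyGeo]:
    """Read the colony metadata CSV (``colony_id,x,y[,haplotype]``)."""
    out: list[ColonyGeo] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"colony_id", "x", "y"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"colony table must have columns {sorted(required)}")
        for row in reader:
            cid = row["colony_id"].strip()
            if cid in seen:
                raise ValueError(f"duplicate colony id {cid!r}")
            seen.add(cid)
            try:
                x, y = float(row["x"]), float(row["y"])
            except ValueError as e:
                raise ValueError(f"non-numeric coordinate for colony {cid!r}") from e
            hap = (row.get("haplotype") or "").strip() or None
            out.append(ColonyGeo(cid, x, y, hap))
    return out


def write_colony_table(geo: Sequence[ColonyGeo], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["colony_id", "x", "y", "haplotype"])
        for g in geo:
            w.writerow([g.colony_id, repr(g.x), repr(g.y), g.haplotype or ""])
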