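"""Readers and writers for the pipeline's plain-text table formats.

Formats
-------
marker map
    Tab-separated with header columns ``marker_id, rs_id, position_bp, kind,
    amplicon_id, subregion_id``.  Empty ``rs_id`` / ``subregion_id`` mean
    absent.  Rows are sorted by position on load; duplicate positions and
    non-contiguous amplicon runs are rejected.

haplotype matrix
    Tab-separated, one haplotype per row.  First column ``haplotype_id``,
    reserved columns ``source`` and ``group_id``, then one column per
    marker_id (any order; realigned to the map on load).  The missing token
    defaults to ``NA``.  A header comment ``#default=reference`` switches on
    sparse mode, in which empty cells take a caller-supplied reference
    allele per column — mirroring deposited tables that print only the
    alleles differing from the human reference sequence.

pedigree + genotypes
    PED-like, whitespace separated: ``family_id subject_id father_id
    mother_id`` then two allele tokens per marker.  ``0`` as a parent id
    means founder; ``0`` as an allele token means MISSING.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Union

from .model import (
    MISSING,
    CEHGroupSpec,
    GenotypeTable,
    Haplotype,
    HaplotypeSource,
    Marker,
    MarkerKind,
    MarkerMap,
    Pedigree,
    PedigreeSubject,
)

PathLike = Union[str, Path]

_MAP_COLUMNS = ["marker_id", "rs_id", "position_bp", "kind", "amplicon_id", "subregion_id"]
_RESERVED_HAP_COLUMNS = ["haplotype_id", "source", "group_id"]


def read_marker_map(path: PathLike) -> MarkerMap:
    """Load a marker map TSV, validating order and amplicon contiguity."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        if reader.fieldnames is None or [
            c for c in _MAP_COLUMNS if c not in reader.fieldnames
        ]:
            raise ValueError(
                f"{path}: marker map must have columns {_MAP_COLUMNS}, "
                f"got {reader.fieldnames}"
            )
        markers = []
        for row in reader:
            kind_token = row["kind"].strip()
            try:
                kind = MarkerKind(kind_token)
            except ValueError:
                raise ValueError(
                    f"{path}: unknown marker kind {kind_token!r} for "
                    f"{row['marker_id']!r} (expected SNP or DIP)"
                ) from None
            sub = row["subregion_id"].strip()
            markers.append(
                Marker(
                    marker_id=row["marker_id"].strip(),
                    rs_id=row["rs_id"].strip() or None,
                    position_bp=int(row["position_bp"]),
                    kind=kind,
                    amplicon_id=row["amplicon_id"].strip(),
                    subregion_id=int(sub) if sub else None,
                )
            )
    return MarkerMap(markers)


def write_marker_map(marker_map: MarkerMap, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_MAP_COLUMNS)
        for m in marker_map:
            w.writerow(
                [
                    m.marker_id,
                    m.rs_id or "",
                    m.position_bp,
                    m.kind.value,
                    m.amplicon_id,
                    "" if m.subregion_id is None else m.subregion_id,
                ]
            )


def read_haplotype_matrix(
    path: PathLike,
    marker_map: MarkerMap,
    *,
    missing_token: str = "NA",
    reference: Optional[Haplotype] = None,
) -> list[Haplotype]:
    """Load a haplotype matrix and align columns to map order.

    ``reference`` supplies the per-column default allele used for empty
    cells when the file carries the ``#default=reference`` header comment;
    it is required in that case and ignored otherwise.
    """
    default_mode = False
    with open(path, newline="") as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            if line.strip() == "#default=reference":
                default_mode = True
            continue
        body.append(line)
    if default_mode and reference is None:
        raise ValueError(
            f"{path}: header requests reference defaulting but no reference "
            "haplotype was supplied"
        )
    reader = csv.reader(body, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise ValueError(f"{path}: empty haplotype matrix") from None
    if header[: len(_RESERVED_HAP_COLUMNS)] != _RESERVED_HAP_COLUMNS:
        raise ValueError(
            f"{path}: first columns must be {_RESERVED_HAP_COLUMNS}"
        )
    marker_cols = header[len(_RESERVED_HAP_COLUMNS):]
    col_to_map = []
    for col in marker_cols:
        try:
            col_to_map.append(marker_map.index_of(col))
        except KeyError:
            raise ValueError(
                f"{path}: column {col!r} is not a marker in the map"
            ) from None

    haps = []
    for row in reader:
        if not row:
            continue
        hap_id, source, group_id = row[0], row[1], row[2]
        cells = row[3:]
        if len(cells) != len(marker_cols):
            raise ValueError(f"{path}: row {hap_id!r} has wrong cell count")
        alleles: list = [MISSING] * len(marker_map)
        seen = [False] * len(marker_map)
        for cell, mi in zip(cells, col_to_map):
            token = cell.strip()
            if token == missing_token:
                value = MISSING
            elif token == "":
                if default_mode:
                    value = reference.alleles[mi]
                else:
                    value = MISSING
            else:
                marker = marker_map[mi]
                if not marker.valid_allele(token):
                    raise ValueError(
                        f"{path}: allele {token!r} invalid for "
                        f"{marker.kind.value} marker {marker.marker_id!r}"
                    )
                value = token
            alleles[mi] = value
            seen[mi] = True
        if default_mode and reference is not None:
            for mi, was_seen in enumerate(seen):
                if not was_seen:
                    alleles[mi] = reference.alleles[mi]
        haps.append(
            Haplotype(
                haplotype_id=hap_id,
                alleles=alleles,
                source=HaplotypeSource(source),
                group_id=group_id or None,
            )
        )
    return haps


def write_haplotype_matrix(
    haps: list[Haplotype],
    marker_map: MarkerMap,
    path: PathLike,
    *,
    missing_token: str = "NA",
) -> None:
    """Write a dense haplotype matrix in map order (round-trip safe)."""
    for h in haps:
        if not h.aligned_to(marker_map):
            raise ValueError(
                f"haplotype {h.haplotype_id!r} has {len(h.alleles)} alleles, "
                f"map has {len(marker_map)} markers"
            )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_RESERVED_HAP_COLUMNS + [m.marker_id for m in marker_map])
        for h in haps:
            w.writerow(
                [h.haplotype_id, h.source.value, h.group_id or ""]
                + [missing_token if a is MISSING else a for a in h.alleles]
            )


def read_pedigree_genotypes(
    path: PathLike, marker_map: MarkerMap
) -> tuple[list[Pedigree], GenotypeTable]:
    """Parse a PED-like file into pedigrees and an unordered genotype table."""
    n = len(marker_map)
    families: dict[str, list[PedigreeSubject]] = {}
    table = GenotypeTable(n)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 4 + 2 * n:
                raise ValueError(
                    f"{path}:{lineno}: expected {4 + 2 * n} fields "
                    f"(4 + 2 alleles x {n} markers), got {len(fields)}"
                )
            fam, sid, father, mother = fields[:4]
            families.setdefault(fam, []).append(
                PedigreeSubject(
                    subject_id=sid,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                )
            )
            pairs = []
            for i in range(n):
                a, b = fields[4 + 2 * i], fields[5 + 2 * i]
                pairs.append(
                    (MISSING if a == "0" else a, MISSING if b == "0" else b)
                )
            table.set_subject(sid, pairs)
    pedigrees = [Pedigree(fam, subs) for fam, subs in families.items()]
    return pedigrees, table


def write_pedigree_genotypes(
    pedigrees: list[Pedigree],
    table: GenotypeTable,
    path: PathLike,
) -> None:
    with open(path, "w") as fh:
        for ped in pedigrees:
            for s in ped.subjects:
                pairs = table.subject_pairs(s.subject_id)
                tokens = []
                for a, b in pairs:
                    tokens.append("0" if a is MISSING else a)
                    tokens.append("0" if b is MISSING else b)
                fh.write(
                    " ".join(
                        [
                            ped.family_id,
                            s.subject_id,
                            s.father_id or "0",
                            s.mother_id or "0",
                        ]
                        + tokens
                    )
                    + "\n"
                )


def read_group_specs(path: PathLike, marker_map: MarkerMap) -> list[CEHGroupSpec]:
    """Load CEH group definitions from YAML: {group_id: {marker_id: allele}}."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    specs = []
    for group_id, reqs in raw.items():
        specs.append(
            CEHGroupSpec(
                group_id=group_id,
                core_requirements={
                    marker_map.index_of(mid): allele
                    for mid, allele in reqs.items()
                },
            )
        )
    return specs
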