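"""Domain types for conserved-extended-haplotype (CEH) analysis.

Coordinate conventions
----------------------
All genomic positions are 1-based inclusive GRCh37 chromosome-6 base-pair
coordinates, and the telomere-to-centromere direction of the MHC class II
region coincides with increasing position.  Every inter-point distance in
the package is a plain subtraction ``pos_b - pos_a`` (no +1 adjustment).

Alleles are opaque categorical tokens: single nucleotides for SNPs, and
arbitrary strings (e.g. ``"del"``, ``"ins:TT"``) for deletion-insertion
polymorphisms (DIPs), compared by exact string equality.  A missing call is
the Python value ``None`` (the :data:`MISSING` alias), which is distinct
from every allele token and is never coerced into one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

#: Sentinel for an absent allele call.  ``None`` by design: it cannot collide
#: with any allele token and it is falsy, which keeps comparisons short.
MISSING = None

#: Token for the dominant allele at a marker where the retained members split
#: into co-dominant tracks, or where every retained member is missing.
UNDEFINED = "__UNDEFINED__"

SNP_ALLELES = frozenset({"A", "C", "G", "T"})


class MarkerKind(str, Enum):
    SNP = "SNP"
    DIP = "DIP"


class HaplotypeSource(str, Enum):
    PEDIGREE_FOUNDER = "pedigree_founder"
    HOMOZYGOUS_SAMPLE = "homozygous_sample"
    REFERENCE = "reference"
    SYNTHETIC_TRUTH = "synthetic_truth"


@dataclass(frozen=True)
class Marker:
    """A polymorphic site on the marker map.

    ``marker_id`` is the amplicon-local name (e.g. ``"DOB7.5-2"``);
    ``position_bp`` is the 1-based GRCh37 coordinate; ``subregion_id`` is the
    1..K id of the NCF sub-region the marker belongs to, or ``None`` for
    markers outside the analyzed sub-regions (e.g. the core anchor markers).
    """

    marker_id: str
    position_bp: int
    kind: MarkerKind = MarkerKind.SNP
    amplicon_id: str = "AMP1"
    rs_id: Optional[str] = None
    subregion_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.position_bp <= 0:
            raise ValueError(
                f"marker {self.marker_id}: position_bp must be positive, "
                f"got {self.position_bp}"
            )
        if not isinstance(self.kind, MarkerKind):
            object.__setattr__(self, "kind", MarkerKind(self.kind))

    def valid_allele(self, token: str) -> bool:
        """Whether ``token`` is a legal (non-missing) allele for this marker."""
        if token is MISSING:
            return False
        if self.kind is MarkerKind.SNP:
            return token in SNP_ALLELES
        return isinstance(token, str) and len(token) > 0


class MarkerMap:
    """Ordered polymorphic sites: the coordinate backbone of the analysis.

    Markers are kept sorted telomere-to-centromere (strictly increasing
    ``position_bp``); markers sharing an ``amplicon_id`` must form a
    contiguous run.  Sub-regions are derived: for each ``subregion_id`` used
    by any marker the map records the centromeric-most (maximum) position of
    its markers, which is the boundary point the NCF statistic subtracts.
    """

    def __init__(self, markers: list[Marker]):
        markers = sorted(markers, key=lambda m: m.position_bp)
        for a, b in zip(markers, markers[1:]):
            if a.position_bp == b.position_bp:
                raise ValueError(
                    f"duplicate position {a.position_bp}: markers "
                    f"{a.marker_id!r} and {b.marker_id!r}"
                )
        seen_amplicons: dict[str, int] = {}
        for i, m in enumerate(markers):
            if m.amplicon_id in seen_amplicons:
                if seen_amplicons[m.amplicon_id] != i - 1:
                    raise ValueError(
                        f"amplicon {m.amplicon_id!r} is not a contiguous run "
                        f"in position order (marker {m.marker_id!r})"
                    )
            seen_amplicons[m.amplicon_id] = i
        self.markers: list[Marker] = markers
        self._index_by_id = {m.marker_id: i for i, m in enumerate(markers)}
        if len(self._index_by_id) != len(markers):
            raise ValueError("duplicate marker_id in map")

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def __getitem__(self, i: int) -> Marker:
        return self.markers[i]

    def index_of(self, marker_id: str) -> int:
        return self._index_by_id[marker_id]

    @property
    def positions(self) -> list[int]:
        return [m.position_bp for m in self.markers]

    @property
    def subregions(self) -> list[tuple[int, int]]:
        """Ordered ``(subregion_id, centromeric_most_position_bp)`` pairs."""
        out: dict[int, int] = {}
        for m in self.markers:
            if m.subregion_id is not None:
                out[m.subregion_id] = max(
                    out.get(m.subregion_id, 0), m.position_bp
                )
        return sorted(out.items(), key=lambda kv: kv[1])

    def subregion_of_position(self, pos: int, anchor_bp: int) -> Optional[int]:
        """Sub-region whose interval ``(prev boundary, boundary]`` contains pos."""
        prev = anchor_bp
        for sid, cm in self.subregions:
            if prev < pos <= cm:
                return sid
            prev = cm
        return None


@dataclass
class Haplotype:
    """A phased allele vector aligned to a :class:`MarkerMap`."""

    haplotype_id: str
    alleles: list[Optional[str]]
    source: HaplotypeSource = HaplotypeSource.SYNTHETIC_TRUTH
    group_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not isinstance(self.source, HaplotypeSource):
            self.source = HaplotypeSource(self.source)

    def aligned_to(self, marker_map: MarkerMap) -> bool:
        return len(self.alleles) == len(marker_map)

    def missing_fraction(self) -> float:
        if not self.alleles:
            return 0.0
        return sum(a is MISSING for a in self.alleles) / len(self.alleles)


class GenotypeTable:
    """Unordered diploid allele pairs per (subject, marker).

    A subject present at any marker is present (possibly MISSING) at every
    marker: the table stores one full-length vector of pairs per subject.
    Pairs are unordered; they are canonicalized on storage (MISSING last,
    tokens sorted) so equality is order-free.
    """

    def __init__(self, n_markers: int):
        self.n_markers = n_markers
        self._data: dict[str, list[tuple]] = {}

    @staticmethod
    def _canon(pair: tuple) -> tuple:
        a, b = pair
        if a is MISSING and b is MISSING:
            return (MISSING, MISSING)
        if a is MISSING:
            return (b, MISSING)
        if b is MISSING:
            return (a, MISSING)
        return (a, b) if a <= b else (b, a)

    def set_subject(self, subject_id: str, pairs: list[tuple]) -> None:
        if len(pairs) != self.n_markers:
            raise ValueError(
                f"subject {subject_id!r}: expected {self.n_markers} genotype "
                f"pairs, got {len(pairs)}"
            )
        self._data[subject_id] = [self._canon(p) for p in pairs]

    def pair(self, subject_id: str, marker_index: int) -> tuple:
        return self._data[subject_id][marker_index]

    def subject_pairs(self, subject_id: str) -> list[tuple]:
        return list(self._data[subject_id])

    @property
    def subjects(self) -> list[str]:
        return list(self._data)

    def __contains__(self, subject_id: str) -> bool:
        return subject_id in self._data

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeTable)
            and self.n_markers == other.n_markers
            and self._data == other._data
        )

    @staticmethod
    def from_haplotype_pair(
        subject_id: str, h1: Haplotype, h2: Haplotype, table: "GenotypeTable"
    ) -> None:
        table.set_subject(subject_id, list(zip(h1.alleles, h2.alleles)))


@dataclass
class PedigreeSubject:
    subject_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """A family: subjects with optional in-family parent references."""

    def __init__(self, family_id: str, subjects: list[PedigreeSubject]):
        self.family_id = family_id
        self.subjects = subjects
        ids = {s.subject_id for s in subjects}
        if len(ids) != len(subjects):
            raise ValueError(f"family {family_id}: duplicate subject_id")
        for s in subjects:
            for p in (s.father_id, s.mother_id):
                if p is not None and p not in ids:
                    raise ValueError(
                        f"family {family_id}: subject {s.subject_id!r} "
                        f"references absent parent {p!r}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        colors: dict[str, int] = {}
        by_id = {s.subject_id: s for s in self.subjects}

        def visit(sid: str) -> None:
            if colors.get(sid) == 1:
                raise ValueError(
                    f"family {self.family_id}: cyclic parentage at {sid!r}"
                )
            if colors.get(sid) == 2:
                return
            colors[sid] = 1
            s = by_id[sid]
            for p in (s.father_id, s.mother_id):
                if p is not None:
                    visit(p)
            colors[sid] = 2

        for s in self.subjects:
            visit(s.subject_id)

    @property
    def founders(self) -> list[PedigreeSubject]:
        return [s for s in self.subjects if s.is_founder]

    @property
    def children(self) -> list[PedigreeSubject]:
        return [s for s in self.subjects if not s.is_founder]

    def subject(self, subject_id: str) -> PedigreeSubject:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


@dataclass
class CEHGroupSpec:
    """A CEH group keyed by required alleles at designated core markers.

    Stands in for the HLA / complotype allele combinations that define each
    conserved extended haplotype in serological typing.
    """

    group_id: str
    core_requirements: dict[int, str]

    def __post_init__(self) -> None:
        if not self.core_requirements:
            raise ValueError(
                f"group {self.group_id}: at least one core requirement needed"
            )

    def matches(self, hap: Haplotype) -> Optional[bool]:
        """True/False, or None when a required call is MISSING (untypable)."""
        untypable = False
        for idx, allele in self.core_requirements.items():
            call = hap.alleles[idx]
            if call is MISSING:
                untypable = True
            elif call != allele:
                return False
        return None if untypable else True
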