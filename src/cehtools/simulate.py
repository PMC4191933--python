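"""Synthetic cohorts with planted CEH architecture and a ground-truth ledger.

The generator emulates the statistical structure the downstream analysis
assumes: a small number of ancestral conserved-extended-haplotype (CEH)
sequences at high frequency, eroded centromerically by single crossovers
onto common background haplotypes at sub-region-specific intensity, rare
isolated private mutations, amplicon-level missingness, and transmission
through nuclear pedigrees with occasional intra-family crossovers.

Guarantees the analysis relies on
---------------------------------
* A group member equals its ancestor at every marker telomeric to its drawn
  crossover position and equals its donor at every marker at or centromeric
  to it.
* The donor differs from the ancestor at the first two markers centromeric
  to the crossover position, so the loss of the dominant sequence is
  observable exactly at the landing marker and is never mistaken for an
  isolated private variant.
* Private mutations are isolated single-marker substitutions, never placed
  at core markers or adjacent to a planted crossover, and carry an allele
  unique in the cohort at that marker.
* All randomness flows from the single configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

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

_NUCS = ("A", "C", "G", "T")


@dataclass
class GroupPlan:
    group_id: str
    n_members: int

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError(f"group {self.group_id}: n_members must be >= 1")


@dataclass
class PedigreePlan:
    n_families: int = 0
    children_per_family: int = 2
    intra_family_crossover_prob: float = 0.0


@dataclass
class SimConfig:
    """Cohort generation parameters.

    Defaults follow the shape of the study cohort this pipeline targets:
    a handful of CEH groups with 16-30 members each plus a pool of common
    background haplotypes (~160 chromosomes in total), eleven NCF
    sub-regions over a few hundred kb of map, per-sub-region crossover
    probabilities of a few percent, and rare private mutation and
    amplicon-dropout rates.
    """

    groups: list[GroupPlan] = field(
        default_factory=lambda: [
            GroupPlan("CEH1", 30),
            GroupPlan("CEH2", 23),
            GroupPlan("CEH3", 18),
            GroupPlan("CEH4", 16),
        ]
    )
    background_pool: int = 40
    background_maf: float = 0.5
    subregion_sizes: list[int] = field(default_factory=lambda: [10] * 11)
    n_core_markers: int = 4
    positions: Optional[list[int]] = None
    span: tuple[int, int] = (32_700_000, 33_150_000)
    dip_fraction: float = 0.1
    n_amplicons: int = 12
    p_r: Optional[list[float]] = None  # default 0.03 per sub-region
    crossovers_exact: Optional[dict[str, list[int]]] = None
    mu: float = 0.0
    missing_rate: float = 0.0
    pedigree: Optional[PedigreePlan] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_r is None:
            self.p_r = [0.03] * len(self.subregion_sizes)
        if len(self.p_r) != len(self.subregion_sizes):
            raise ValueError("p_r must have one entry per sub-region")
        for p in self.p_r:
            if not 0.0 <= p <= 1.0:
                raise ValueError("crossover probabilities must be in [0, 1]")
        if not 0.0 <= self.mu <= 1.0 or not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("rates must be in [0, 1]")
        if min(self.subregion_sizes) < 1:
            raise ValueError("every sub-region needs at least one marker")
        n_groups = len(self.groups)
        if n_groups and 2 ** self.n_core_markers <= 2 * n_groups:
            raise ValueError(
                "n_core_markers too small to give every group a distinct "
                "core allele pattern plus background patterns"
            )

    @property
    def n_markers(self) -> int:
        return self.n_core_markers + sum(self.subregion_sizes)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        raw = dict(raw)
        if "groups" in raw:
            raw["groups"] = [GroupPlan(**g) for g in raw["groups"]]
        if raw.get("pedigree") is not None:
            raw["pedigree"] = PedigreePlan(**raw["pedigree"])
        if "span" in raw:
            raw["span"] = tuple(raw["span"])
        return cls(**raw)


@dataclass
class ChildTransmission:
    family_id: str
    child_id: str
    paternal_hap: str
    maternal_hap: str
    # (parent_subject_id, donor2_hap_id, switch interval as marker indices)
    crossover: Optional[tuple[str, str, tuple[int, int]]] = None


@dataclass
class SimTruth:
    """Complete ground-truth ledger for one simulated cohort."""

    anchor_bp: int
    group_of: dict[str, Optional[str]] = field(default_factory=dict)
    crossover_pos: dict[str, Optional[int]] = field(default_factory=dict)
    landing_index: dict[str, Optional[int]] = field(default_factory=dict)
    donor_of: dict[str, Optional[str]] = field(default_factory=dict)
    private_mutations: list[tuple[str, int]] = field(default_factory=list)
    transmissions: list[ChildTransmission] = field(default_factory=list)
    ancestors: dict[str, Haplotype] = field(default_factory=dict)
    group_specs: list[CEHGroupSpec] = field(default_factory=list)
    true_haplotypes: dict[str, Haplotype] = field(default_factory=dict)

    def survivors_at(self, group_id: str, position_bp: int) -> set[str]:
        """Members whose crossover (if any) lies centromeric to position_bp."""
        return {
            h
            for h, g in self.group_of.items()
            if g == group_id
            and (
                self.crossover_pos[h] is None
                or self.crossover_pos[h] > position_bp
            )
        }

    def crossover_counts(
        self, group_id: str, marker_map: MarkerMap
    ) -> list[int]:
        """True crossover count per sub-region, in sub-region order."""
        counts = []
        prev = self.anchor_bp
        for _sid, cm in marker_map.subregions:
            n = sum(
                1
                for h, g in self.group_of.items()
                if g == group_id
                and self.crossover_pos[h] is not None
                and prev < self.crossover_pos[h] <= cm
            )
            counts.append(n)
            prev = cm
        return counts


def _build_marker_map(cfg: SimConfig, rng: np.random.Generator) -> MarkerMap:
    n = cfg.n_markers
    if cfg.positions is not None:
        if len(cfg.positions) != n:
            raise ValueError(
                f"positions has {len(cfg.positions)} entries, config "
                f"implies {n} markers"
            )
        positions = sorted(cfg.positions)
    else:
        lo, hi = cfg.span
        positions = sorted(
            int(p) + 1 for p in rng.choice(hi - lo, size=n, replace=False) + lo
        )
    kinds = [
        MarkerKind.DIP if rng.random() < cfg.dip_fraction else MarkerKind.SNP
        for _ in range(n)
    ]
    # core markers first, then sub-regions in order
    subregion_ids: list[Optional[int]] = [None] * cfg.n_core_markers
    for r, size in enumerate(cfg.subregion_sizes, start=1):
        subregion_ids.extend([r] * size)
    # amplicons: core is its own amplicon (serologically typed in practice,
    # exempt from sequencing dropout); the rest in contiguous chunks
    amplicons = ["AMP_CORE"] * cfg.n_core_markers
    rest = n - cfg.n_core_markers
    n_amp = max(1, min(cfg.n_amplicons, rest))
    bounds = np.linspace(0, rest, n_amp + 1).astype(int)
    for a in range(n_amp):
        amplicons.extend([f"AMP{a + 1:02d}"] * (bounds[a + 1] - bounds[a]))
    markers = [
        Marker(
            marker_id=f"M{i + 1:04d}",
            position_bp=positions[i],
            kind=kinds[i],
            amplicon_id=amplicons[i],
            subregion_id=subregion_ids[i],
        )
        for i in range(n)
    ]
    return MarkerMap(markers)


def _marker_alleles(kind: MarkerKind, rng: np.random.Generator) -> tuple[str, str]:
    if kind is MarkerKind.SNP:
        ref, alt = rng.choice(4, size=2, replace=False)
        return _NUCS[ref], _NUCS[alt]
    return "del", "ins:" + _NUCS[int(rng.integers(4))]


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[MarkerMap, list[Haplotype], list[Pedigree], GenotypeTable, SimTruth]:
    """Generate a cohort; returns observed haplotypes plus the truth ledger.

    The returned haplotype list carries amplicon-level missingness (if
    configured); pristine allele vectors are kept in ``SimTruth``.
    """
    rng = np.random.default_rng(cfg.seed)
    marker_map = _build_marker_map(cfg, rng)
    n = len(marker_map)
    n_core = cfg.n_core_markers
    ref_alt = [_marker_alleles(m.kind, rng) for m in marker_map]
    anchor_bp = (
        marker_map[n_core - 1].position_bp
        if n_core
        else marker_map[0].position_bp - 1
    )

    # distinct core patterns for groups; backgrounds draw from the rest
    all_patterns = [
        tuple((code >> b) & 1 for b in range(n_core))
        for code in range(2 ** n_core)
    ]
    rng.shuffle(all_patterns)
    group_patterns = {
        g.group_id: all_patterns[i] for i, g in enumerate(cfg.groups)
    }
    background_patterns = all_patterns[len(cfg.groups):]

    def pattern_alleles(pattern: tuple[int, ...]) -> list[str]:
        return [ref_alt[i][pattern[i]] for i in range(n_core)]

    truth = SimTruth(anchor_bp=anchor_bp)
    truth.group_specs = [
        CEHGroupSpec(
            group_id=g.group_id,
            core_requirements={
                i: a
                for i, a in enumerate(pattern_alleles(group_patterns[g.group_id]))
            },
        )
        for g in cfg.groups
    ]

    # ancestors and background pool
    def random_tail(maf: float) -> list[str]:
        draws = rng.random(n - n_core) < maf
        return [
            ref_alt[n_core + k][1] if draws[k] else ref_alt[n_core + k][0]
            for k in range(n - n_core)
        ]

    for g in cfg.groups:
        anc = Haplotype(
            haplotype_id=f"ANC_{g.group_id}",
            alleles=pattern_alleles(group_patterns[g.group_id])
            + random_tail(0.5),
            source=HaplotypeSource.SYNTHETIC_TRUTH,
            group_id=g.group_id,
        )
        truth.ancestors[g.group_id] = anc

    backgrounds: list[Haplotype] = []
    for b in range(cfg.background_pool):
        pat = background_patterns[int(rng.integers(len(background_patterns)))]
        backgrounds.append(
            Haplotype(
                haplotype_id=f"BG{b + 1:03d}",
                alleles=pattern_alleles(pat) + random_tail(cfg.background_maf),
                source=HaplotypeSource.SYNTHETIC_TRUTH,
            )
        )

    donor_pool = backgrounds + [
        truth.ancestors[g.group_id] for g in cfg.groups
    ]
    subregion_points = marker_map.subregions  # [(sid, cm_pos)]

    def draw_crossover(
        region_idx: int, ancestor: Haplotype, exclude_donor: str
    ) -> tuple[int, int, Haplotype]:
        """Return (xpos, landing marker index, donor) for a crossover in
        sub-region ``region_idx`` (0-based), with the donor guaranteed to
        differ from the ancestor at the landing marker and the next one."""
        lo = anchor_bp if region_idx == 0 else subregion_points[region_idx - 1][1]
        hi = subregion_points[region_idx][1]
        # keep two markers centromeric to the landing site on the map
        hi = min(hi, marker_map[n - 2].position_bp)
        if hi <= lo + 1:
            raise ValueError(
                f"sub-region {subregion_points[region_idx][0]} too narrow to "
                "place an observable crossover"
            )
        positions = marker_map.positions
        for _ in range(200):
            xpos = int(rng.integers(lo + 1, hi + 1))  # strictly inside (lo, hi]
            j = int(np.searchsorted(positions, xpos, side="left"))
            if j > n - 2:
                continue
            candidates = [
                d
                for d in donor_pool
                if d.haplotype_id != exclude_donor
                and d.alleles[j] != ancestor.alleles[j]
                and d.alleles[j + 1] != ancestor.alleles[j + 1]
            ]
            if candidates:
                donor = candidates[int(rng.integers(len(candidates)))]
                return xpos, j, donor
        raise ValueError(
            "could not place an observable crossover; donor pool too similar "
            "to the ancestor"
        )

    members: list[Haplotype] = []
    for g in cfg.groups:
        anc = truth.ancestors[g.group_id]
        ids = [f"{g.group_id}_H{i + 1:03d}" for i in range(g.n_members)]
        crossed: dict[str, tuple[int, int, Haplotype]] = {}
        if cfg.crossovers_exact is not None:
            plan = cfg.crossovers_exact.get(g.group_id, [0] * len(cfg.p_r))
            if len(plan) != len(cfg.p_r):
                raise ValueError(
                    f"crossovers_exact[{g.group_id}] must list one count per "
                    "sub-region"
                )
            if sum(plan) > g.n_members:
                raise ValueError(
                    f"group {g.group_id}: more planted crossovers than members"
                )
            remaining = list(ids)
            for r, k in enumerate(plan):
                chosen = rng.choice(len(remaining), size=k, replace=False)
                picked = [remaining[int(c)] for c in chosen]
                for hid in picked:
                    crossed[hid] = draw_crossover(r, anc, anc.haplotype_id)
                    remaining.remove(hid)
        else:
            for hid in ids:
                for r, p in enumerate(cfg.p_r):
                    if rng.random() < p:
                        crossed[hid] = draw_crossover(r, anc, anc.haplotype_id)
                        break
        for hid in ids:
            if hid in crossed:
                xpos, j, donor = crossed[hid]
                alleles = anc.alleles[:j] + donor.alleles[j:]
                truth.crossover_pos[hid] = xpos
                truth.landing_index[hid] = j
                truth.donor_of[hid] = donor.haplotype_id
            else:
                alleles = list(anc.alleles)
                truth.crossover_pos[hid] = None
                truth.landing_index[hid] = None
                truth.donor_of[hid] = None
            truth.group_of[hid] = g.group_id
            members.append(
                Haplotype(
                    haplotype_id=hid,
                    alleles=alleles,
                    source=HaplotypeSource.SYNTHETIC_TRUTH,
                    group_id=g.group_id,
                )
            )

    for bg in backgrounds:
        truth.group_of[bg.haplotype_id] = None
        truth.crossover_pos[bg.haplotype_id] = None
        truth.landing_index[bg.haplotype_id] = None
        truth.donor_of[bg.haplotype_id] = None

    haps = members + backgrounds

    # private mutations: isolated, on the ancestral (telomeric) segment only,
    # unique allele at the site cohort-wide
    if cfg.mu > 0:
        for h in members:
            j = truth.landing_index[h.haplotype_id]
            limit = (j - 1) if j is not None else n
            last_hit = -10
            for i in range(n_core, limit):
                if i - last_hit <= 1:
                    continue
                if rng.random() >= cfg.mu:
                    continue
                marker = marker_map[i]
                present = {
                    o.alleles[i]
                    for o in haps
                    if o is not h and o.alleles[i] is not MISSING
                }
                if marker.kind is MarkerKind.SNP:
                    options = [t for t in _NUCS if t != h.alleles[i]]
                else:
                    options = [
                        t
                        for t in ("del", "ins:A", "ins:C", "ins:G", "ins:T")
                        if t != h.alleles[i]
                    ]
                options = [t for t in options if t not in present]
                if not options:
                    continue
                h.alleles[i] = options[int(rng.integers(len(options)))]
                truth.private_mutations.append((h.haplotype_id, i))
                last_hit = i

    truth.true_haplotypes = {
        h.haplotype_id: Haplotype(
            h.haplotype_id, list(h.alleles), h.source, h.group_id
        )
        for h in haps
    }

    # amplicon-level missingness (core amplicon exempt)
    if cfg.missing_rate > 0:
        amp_indices: dict[str, list[int]] = {}
        for i, m in enumerate(marker_map):
            if m.amplicon_id != "AMP_CORE":
                amp_indices.setdefault(m.amplicon_id, []).append(i)
        for h in haps:
            for amp, idxs in amp_indices.items():
                if rng.random() < cfg.missing_rate:
                    for i in idxs:
                        h.alleles[i] = MISSING

    if cfg.pedigree is not None and cfg.pedigree.n_families > 0:
        pedigrees, table = emit_pedigrees(
            haps, cfg.pedigree, rng=rng, truth=truth
        )
    else:
        pedigrees, table = [], GenotypeTable(n)

    return marker_map, haps, pedigrees, table, truth


def emit_pedigrees(
    haps: list[Haplotype],
    plan: PedigreePlan,
    *,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    truth: Optional[SimTruth] = None,
) -> tuple[list[Pedigree], GenotypeTable]:
    """Assign haplotypes to nuclear-family founders and transmit to children.

    Each family consumes four distinct founder haplotypes (two per parent).
    With probability ``intra_family_crossover_prob`` a child receives one
    recombinant gamete formed from the two haplotypes of a randomly chosen
    parent; the recombination is recorded in the truth ledger when given.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    need = plan.n_families * 4
    if need > len(haps):
        raise ValueError(
            f"pedigree plan needs {need} founder haplotypes but only "
            f"{len(haps)} were emitted"
        )
    if plan.children_per_family < 0:
        raise ValueError("children_per_family must be >= 0")
    n = len(haps[0].alleles)
    order = list(rng.permutation(len(haps)))
    table = GenotypeTable(n)
    pedigrees = []
    for f in range(plan.n_families):
        fam = f"FAM{f + 1:03d}"
        fh1, fh2, mh1, mh2 = (haps[order[4 * f + k]] for k in range(4))
        father, mother = f"{fam}_F", f"{fam}_M"
        subjects = [
            PedigreeSubject(father),
            PedigreeSubject(mother),
        ]
        table.set_subject(father, list(zip(fh1.alleles, fh2.alleles)))
        table.set_subject(mother, list(zip(mh1.alleles, mh2.alleles)))
        for c in range(plan.children_per_family):
            child = f"{fam}_C{c + 1}"
            subjects.append(PedigreeSubject(child, father_id=father, mother_id=mother))
            pat_pair, mat_pair = (fh1, fh2), (mh1, mh2)
            pat_choice = int(rng.integers(2))
            mat_choice = int(rng.integers(2))
            paternal = list(pat_pair[pat_choice].alleles)
            maternal = list(mat_pair[mat_choice].alleles)
            pat_id = pat_pair[pat_choice].haplotype_id
            mat_id = mat_pair[mat_choice].haplotype_id
            xrec = None
            if rng.random() < plan.intra_family_crossover_prob:
                k = int(rng.integers(1, n))  # switch between k-1 and k
                which = int(rng.integers(2))  # 0 paternal, 1 maternal
                if which == 0:
                    other = pat_pair[1 - pat_choice]
                    paternal = paternal[:k] + list(other.alleles[k:])
                    xrec = (father, other.haplotype_id, (k - 1, k))
                else:
                    other = mat_pair[1 - mat_choice]
                    maternal = maternal[:k] + list(other.alleles[k:])
                    xrec = (mother, other.haplotype_id, (k - 1, k))
            table.set_subject(child, list(zip(paternal, maternal)))
            if truth is not None:
                truth.transmissions.append(
                    ChildTransmission(fam, child, pat_id, mat_id, xrec)
                )
        pedigrees.append(Pedigree(fam, subjects))
    return pedigrees, table
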