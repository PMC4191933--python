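"""Founder-haplotype reconstruction by segregation analysis in pedigrees.

The phasing proceeds in two layers, mirroring how pedigree data determine
phase logically rather than statistically:

1. Per-marker transmission: for every child and marker, enumerate the
   orderings of the child's unordered genotype consistent with both parents'
   genotypes (MISSING acts as a wildcard).  An empty set is a Mendelian
   violation: the marker is excised for the family (set MISSING in the
   affected haplotypes), flagged, and additionally flagged as a suspected
   silent (null) allele when a homozygous parent shares no allele with the
   child.  When every consistent ordering agrees on the allele a parent
   transmitted, that transmission is determined.

2. Phase linkage: for each parent, heterozygous markers are linked into two
   haplotypes by tracking which parental haplotype each child's gamete
   follows, greedily minimizing the number of within-gamete switches.  A
   surviving switch is an intra-family crossover and is reported with its
   bounding marker interval; the parental (founder) haplotypes themselves
   are unaffected by child recombination.  Heterozygous markers at which no
   child transmission is determined (e.g. every family member heterozygous
   for the same alleles) are surfaced in the ambiguity set, never guessed.

Residual ambiguity is resolved separately by :func:`assign_ambiguous_phase`,
which applies the group-consensus rule: the allele of the group's dominant
sequence goes to the haplotype that matches the dominant sequence at the
nearest unambiguous flanking markers; without any dominant context the
assignment falls back to a deterministic lexical rule.  Either way the
alleles are flagged as inferred.

Unrelated subjects homozygous at every typed marker contribute a single
haplotype (consanguineous-style samples); statistical phasing of unrelated
heterozygous subjects is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import (
    MISSING,
    GenotypeTable,
    Haplotype,
    HaplotypeSource,
    MarkerMap,
    Pedigree,
)


@dataclass
class FamilyCrossover:
    family_id: str
    child_id: str
    parent_id: str
    interval_indices: tuple[int, int]  # (last marker on old source, first on new)
    interval_bp: tuple[int, int]


@dataclass
class Ambiguity:
    family_id: str
    parent_id: str  # subject whose haplotype pair is unresolved
    marker_index: int
    alleles: tuple[str, str]
    linkage_only: bool = False  # het marker informative in principle but unlinked


@dataclass
class PhaseResult:
    family_id: str
    founder_haplotypes: list[Haplotype] = field(default_factory=list)
    hap_pairs: dict[str, tuple[Haplotype, ...]] = field(default_factory=dict)
    mendelian_flags: list[tuple[int, Optional[str]]] = field(default_factory=list)
    null_suspicions: list[int] = field(default_factory=list)
    crossovers: list[FamilyCrossover] = field(default_factory=list)
    ambiguities: list[Ambiguity] = field(default_factory=list)
    # phased blocks whose orientation relative to the main track no subject
    # links; (parent_id, marker indices of the block)
    linkage_blocks: list[tuple[str, list[int]]] = field(default_factory=list)
    inferred: list[tuple[str, int]] = field(default_factory=list)
    excised_markers: set[int] = field(default_factory=set)
    review_flag: bool = False  # >1 switch in a single gamete


def _consistent_orderings(child_pair, father_pair, mother_pair):
    """Orderings (from_father, from_mother) of a child's genotype consistent
    with the parents' unordered genotypes; MISSING is a wildcard."""

    def can_transmit(pair, allele):
        if allele is MISSING:
            return True
        a, b = pair
        if a is MISSING or b is MISSING:
            return True  # unknown parental allele could be anything
        return allele == a or allele == b

    x, y = child_pair
    out = set()
    for fx, mx in ((x, y), (y, x)):
        if can_transmit(father_pair, fx) and can_transmit(mother_pair, mx):
            out.add((fx, mx))
    return out


def _null_allele_pattern(child_pair, father_pair, mother_pair) -> bool:
    """Homozygous parent sharing no allele with a fully typed child: the
    classic signature of a silent (null) allele segregating."""
    for pair in (father_pair, mother_pair):
        a, b = pair
        if a is not MISSING and a == b:
            cx, cy = child_pair
            if cx is not MISSING and cy is not MISSING and a not in (cx, cy):
                return True
    return False


def phase_family(
    pedigree: Pedigree, genotypes: GenotypeTable, marker_map: MarkerMap
) -> PhaseResult:
    """Reconstruct founder haplotypes for one family by segregation."""
    n = len(marker_map)
    result = PhaseResult(family_id=pedigree.family_id)

    genotyped = [s for s in pedigree.subjects if s.subject_id in genotypes]
    if not genotyped:
        raise ValueError(
            f"family {pedigree.family_id}: no genotyped subject"
        )

    couples: dict[tuple[str, str], list[str]] = {}
    for s in pedigree.children:
        if s.subject_id not in genotypes:
            continue
        couples.setdefault((s.father_id, s.mother_id), []).append(s.subject_id)

    parents_in_couples = {p for pair in couples for p in pair}

    # Mendelian screening (family-wide): excise violating markers
    for (father, mother), kids in couples.items():
        fp = genotypes.subject_pairs(father) if father in genotypes else None
        mp = genotypes.subject_pairs(mother) if mother in genotypes else None
        for i in range(n):
            fpair = fp[i] if fp else (MISSING, MISSING)
            mpair = mp[i] if mp else (MISSING, MISSING)
            for kid in kids:
                cpair = genotypes.pair(kid, i)
                if not _consistent_orderings(cpair, fpair, mpair):
                    result.mendelian_flags.append((i, kid))
                    result.excised_markers.add(i)
                    if _null_allele_pattern(cpair, fpair, mpair):
                        result.null_suspicions.append(i)

    def phase_parent(parent: str, partner: str, kids: list[str]) -> None:
        pp = (
            genotypes.subject_pairs(parent)
            if parent in genotypes
            else [(MISSING, MISSING)] * n
        )
        qp = (
            genotypes.subject_pairs(partner)
            if partner in genotypes
            else [(MISSING, MISSING)] * n
        )
        hap1: list = [MISSING] * n
        hap2: list = [MISSING] * n
        # determined transmissions per child per marker
        trans: dict[str, list] = {k: [MISSING] * n for k in kids}
        for i in range(n):
            if i in result.excised_markers:
                continue
            for kid in kids:
                opts = _consistent_orderings(
                    genotypes.pair(kid, i), pp[i], qp[i]
                )
                sent = {o[0] for o in opts}
                if len(sent) == 1:
                    allele = next(iter(sent))
                    if allele is not MISSING:
                        trans[kid][i] = allele

        # Phase linkage with orientation components.  Stretches of
        # heterozygous markers are mutually oriented only through children
        # whose transmissions are determined at markers of both stretches;
        # such a link may arrive retrospectively, in which case the earlier
        # component is joined (and physically swapped when joined inverted).
        # Components never linked to the main track are surfaced as
        # linkage-ambiguous blocks rather than silently guessed.
        state: dict[str, Optional[int]] = {k: None for k in kids}
        state_comp: dict[str, int] = {}
        last_informative: dict[str, Optional[int]] = {k: None for k in kids}
        switch_counts: dict[str, int] = {k: 0 for k in kids}
        comp_parent: dict[int, int] = {}
        comp_markers: dict[int, list[int]] = {}
        next_comp = 0

        def find(c: int) -> int:
            while comp_parent[c] != c:
                comp_parent[c] = comp_parent[comp_parent[c]]
                c = comp_parent[c]
            return c

        def swap_component(root: int) -> None:
            for j in comp_markers[root]:
                hap1[j], hap2[j] = hap2[j], hap1[j]
            for k in kids:
                if state[k] is not None and find(state_comp[k]) == root:
                    state[k] = 3 - state[k]

        def union(child_root: int, into_root: int) -> None:
            comp_parent[child_root] = into_root
            comp_markers[into_root].extend(comp_markers.pop(child_root))

        for i in range(n):
            if i in result.excised_markers:
                continue
            a, b = pp[i]
            if a is MISSING or b is MISSING:
                continue
            if a == b:
                hap1[i] = hap2[i] = a
                continue
            voters = sorted(
                k
                for k in kids
                if trans[k][i] is not MISSING and trans[k][i] in (a, b)
            )
            if not voters:
                result.ambiguities.append(
                    Ambiguity(pedigree.family_id, parent, i, (a, b))
                )
                continue
            by_root: dict[int, list[str]] = {}
            fresh: list[str] = []
            for k in voters:
                if state[k] is None:
                    fresh.append(k)
                else:
                    by_root.setdefault(find(state_comp[k]), []).append(k)
            if not by_root:
                comp = next_comp
                next_comp += 1
                comp_parent[comp] = comp
                comp_markers[comp] = []
                h1_allele = min(a, b)
            else:
                comp = max(
                    by_root, key=lambda r: (len(by_root[r]), -r)
                )  # largest voting component carries the frame

                def flips(h1_allele: str) -> list[str]:
                    out = []
                    for k in by_root[comp]:
                        implied = 1 if trans[k][i] == h1_allele else 2
                        if implied != state[k]:
                            out.append(k)
                    return sorted(out)

                fa, fb = flips(a), flips(b)
                if len(fa) < len(fb):
                    h1_allele = a
                elif len(fb) < len(fa):
                    h1_allele = b
                elif not fa and not fb:
                    h1_allele = min(a, b)
                else:
                    # genuine tie: deterministically flip the
                    # lexicographically greatest child set
                    h1_allele = a if fa > fb else b
            h2_allele = b if h1_allele == a else a
            hap1[i], hap2[i] = h1_allele, h2_allele
            comp_markers[comp].append(i)

            # join other components: their voters' parities link the frames
            for other_root, members in list(by_root.items()):
                if other_root == comp:
                    continue
                votes = []
                for k in members:
                    implied = 1 if trans[k][i] == h1_allele else 2
                    votes.append(implied == state[k])
                keep = (
                    sum(votes) >= len(votes) - sum(votes)
                )  # majority; tie keeps orientation
                if not keep:
                    swap_component(other_root)
                union(other_root, comp)

            for k in voters:
                implied = 1 if trans[k][i] == h1_allele else 2
                if state[k] is not None and implied != state[k]:
                    j = last_informative[k]
                    result.crossovers.append(
                        FamilyCrossover(
                            pedigree.family_id,
                            k,
                            parent,
                            (j, i),
                            (
                                marker_map[j].position_bp,
                                marker_map[i].position_bp,
                            ),
                        )
                    )
                    switch_counts[k] += 1
                    if switch_counts[k] > 1:
                        result.review_flag = True
                state[k] = implied
                state_comp[k] = comp
                last_informative[k] = i

        roots = {find(c) for c in comp_parent}
        if roots:
            main = max(roots, key=lambda r: (len(comp_markers[r]), -r))
            for r in roots - {main}:
                block = sorted(comp_markers[r])
                result.linkage_blocks.append((parent, block))
                result.ambiguities.append(
                    Ambiguity(
                        pedigree.family_id,
                        parent,
                        block[0],
                        (hap1[block[0]], hap2[block[0]]),
                        linkage_only=True,
                    )
                )

        h1 = Haplotype(
            f"{parent}_h1", hap1, HaplotypeSource.PEDIGREE_FOUNDER
        )
        h2 = Haplotype(
            f"{parent}_h2", hap2, HaplotypeSource.PEDIGREE_FOUNDER
        )
        result.hap_pairs[parent] = (h1, h2)
        result.founder_haplotypes.extend([h1, h2])

    for (father, mother), kids in couples.items():
        if father in genotypes:
            phase_parent(father, mother, kids)
        if mother in genotypes:
            phase_parent(mother, father, kids)

    # unrelated genotyped founders without children in this family
    for s in pedigree.founders:
        if s.subject_id in parents_in_couples or s.subject_id not in genotypes:
            continue
        pairs = genotypes.subject_pairs(s.subject_id)
        het_markers = [
            i
            for i, (a, b) in enumerate(pairs)
            if a is not MISSING and b is not MISSING and a != b
        ]
        if not het_markers:
            hap = Haplotype(
                f"{s.subject_id}_h",
                [
                    a if (a is not MISSING and a == b) else MISSING
                    for a, b in pairs
                ],
                HaplotypeSource.HOMOZYGOUS_SAMPLE,
            )
            result.hap_pairs[s.subject_id] = (hap,)
            result.founder_haplotypes.append(hap)
        else:
            hap1 = [
                a if (a is not MISSING and a == b) else MISSING
                for a, b in pairs
            ]
            hap2 = list(hap1)
            h1 = Haplotype(
                f"{s.subject_id}_h1", hap1, HaplotypeSource.PEDIGREE_FOUNDER
            )
            h2 = Haplotype(
                f"{s.subject_id}_h2", hap2, HaplotypeSource.PEDIGREE_FOUNDER
            )
            result.hap_pairs[s.subject_id] = (h1, h2)
            result.founder_haplotypes.extend([h1, h2])
            for i in het_markers:
                a, b = pairs[i]
                result.ambiguities.append(
                    Ambiguity(pedigree.family_id, s.subject_id, i, (a, b))
                )

    return result


def detect_family_crossovers(
    result: PhaseResult,
    pedigree: Optional[Pedigree] = None,
    marker_map: Optional[MarkerMap] = None,
) -> list[FamilyCrossover]:
    """Intra-family crossover records produced by the segregation pass."""
    return list(result.crossovers)


def assign_ambiguous_phase(
    result: PhaseResult,
    marker_map: MarkerMap,
    dominants: Optional[Sequence] = None,
) -> list[Haplotype]:
    """Resolve the ambiguity set and return the completed haplotypes.

    For each ambiguous heterozygous marker, the haplotype that matches a
    group dominant sequence at the nearest unambiguous non-missing flanking
    markers receives the dominant allele there; with no usable dominant
    context the lexically smaller allele goes to the haplotype with the
    lower haplotype_id.  Every assignment is flagged as inferred.
    """
    dominants = list(dominants or [])

    undecided_markers: dict[str, set[int]] = {}
    for amb in result.ambiguities:
        if not amb.linkage_only:
            undecided_markers.setdefault(amb.parent_id, set()).add(
                amb.marker_index
            )
    block_markers: dict[str, set[int]] = {}
    for parent, block in result.linkage_blocks:
        block_markers.setdefault(parent, set()).update(block)

    def context(parent, h1, h2):
        skip = undecided_markers.get(parent, set()) | block_markers.get(
            parent, set()
        )
        return (
            _best_dominant(h1, dominants, skip),
            _best_dominant(h2, dominants, skip),
        )

    # orient whole linkage-ambiguous blocks first
    for parent, block in result.linkage_blocks:
        haps = result.hap_pairs.get(parent)
        if not haps or len(haps) != 2:
            continue
        h1, h2 = haps
        d1, d2 = context(parent, h1, h2)
        keep = _block_agreement(h1, d1, block) + _block_agreement(h2, d2, block)
        swap_s = _block_agreement(h2, d1, block) + _block_agreement(h1, d2, block)
        if keep == swap_s:
            v1 = tuple(h1.alleles[j] or "" for j in block)
            v2 = tuple(h2.alleles[j] or "" for j in block)
            first, _ = sorted((h1, h2), key=lambda h: h.haplotype_id)
            swap = (v2 < v1) if first is h1 else (v1 < v2)
        else:
            swap = swap_s > keep
        if swap:
            for j in block:
                h1.alleles[j], h2.alleles[j] = h2.alleles[j], h1.alleles[j]
        for j in block:
            result.inferred.append((h1.haplotype_id, j))
            result.inferred.append((h2.haplotype_id, j))

    by_parent: dict[str, list[Ambiguity]] = {}
    for amb in result.ambiguities:
        if amb.linkage_only:
            continue
        by_parent.setdefault(amb.parent_id, []).append(amb)

    for parent, ambs in by_parent.items():
        haps = result.hap_pairs.get(parent)
        if not haps or len(haps) != 2:
            continue
        h1, h2 = haps
        d1, d2 = context(parent, h1, h2)
        amb_markers = {a.marker_index for a in ambs}
        skip = undecided_markers.get(parent, set()) | block_markers.get(
            parent, set()
        )
        for amb in sorted(ambs, key=lambda a: a.marker_index):
            i = amb.marker_index
            a, b = amb.alleles
            # a haplotype that left its group (crossed over) no longer
            # matches any dominant globally; fall back to the sequence it
            # follows locally around the ambiguous site
            e1 = d1 or _site_context(h1, dominants, i, skip)
            e2 = d2 or _site_context(h2, dominants, i, skip)
            cand1 = _dominant_claim(h1, e1, i, (a, b), amb_markers)
            cand2 = _dominant_claim(h2, e2, i, (a, b), amb_markers)
            if cand1 is not None and cand2 is not None and cand1 != cand2:
                h1.alleles[i], h2.alleles[i] = cand1, cand2
            elif cand1 is not None:
                h1.alleles[i] = cand1
                h2.alleles[i] = b if cand1 == a else a
            elif cand2 is not None:
                h2.alleles[i] = cand2
                h1.alleles[i] = b if cand2 == a else a
            else:
                lo, hi_ = sorted((a, b))
                first, second = sorted((h1, h2), key=lambda h: h.haplotype_id)
                first.alleles[i], second.alleles[i] = lo, hi_
            result.inferred.append((h1.haplotype_id, i))
            result.inferred.append((h2.haplotype_id, i))
    return result.founder_haplotypes


def _best_dominant(hap, dominants, skip, min_agreement: float = 0.9):
    """The dominant sequence of the group the haplotype belongs to,
    identified by overall agreement across informative markers outside
    ``skip``; None when nothing agrees convincingly."""
    from .model import UNDEFINED

    best, best_frac = None, min_agreement
    for dom in dominants:
        agree = total = 0
        for j, allele in enumerate(hap.alleles):
            if j in skip or allele is MISSING:
                continue
            d = dom.alleles[j]
            if d is MISSING or d == UNDEFINED:
                continue
            total += 1
            agree += allele == d
        if total >= 2 and agree / total >= best_frac:
            best, best_frac = dom, agree / total
    return best


def _site_context(hap, dominants, i, skip, window: int = 3):
    """Dominant sequence the haplotype follows locally around marker ``i``:
    it must match at the nearest ``window`` informative markers on each side
    (vacuous at map edges); ties broken by overall agreement."""
    from .model import UNDEFINED

    candidates = []
    for dom in dominants:
        ok = True
        for step in (-1, 1):
            found = 0
            j = i + step
            while 0 <= j < len(hap.alleles) and found < window:
                d = dom.alleles[j]
                if (
                    j not in skip
                    and hap.alleles[j] is not MISSING
                    and d is not MISSING
                    and d != UNDEFINED
                ):
                    if hap.alleles[j] != d:
                        ok = False
                        break
                    found += 1
                j += step
            if not ok:
                break
        if ok:
            candidates.append(dom)
    if not candidates:
        return None
    if len(candidates) == 1:
        return candidates[0]
    return max(
        candidates,
        key=lambda dom: sum(
            1
            for j, allele in enumerate(hap.alleles)
            if j not in skip
            and allele is not MISSING
            and dom.alleles[j] not in (MISSING, UNDEFINED)
            and allele == dom.alleles[j]
        ),
    )


def _block_agreement(hap, dom, block) -> int:
    from .model import UNDEFINED

    if dom is None:
        return 0
    score = 0
    for j in block:
        d = dom.alleles[j]
        if d is MISSING or d == UNDEFINED or hap.alleles[j] is MISSING:
            continue
        score += hap.alleles[j] == d
    return score


def _dominant_claim(hap, dom, i, alleles, amb_markers):
    """The allele ``dom`` supplies at marker ``i`` for this haplotype, when
    the haplotype follows ``dom`` at the nearest unambiguous flanking
    markers and the dominant allele is one of the unresolved pair."""
    from .model import UNDEFINED

    if dom is None:
        return None
    dom_allele = dom.alleles[i] if i < len(dom.alleles) else MISSING
    if dom_allele is MISSING or dom_allele == UNDEFINED or dom_allele not in alleles:
        return None
    for step in (-1, 1):
        j = i + step
        while 0 <= j < len(hap.alleles):
            if (
                j not in amb_markers
                and hap.alleles[j] is not MISSING
                and dom.alleles[j] is not MISSING
                and dom.alleles[j] != UNDEFINED
            ):
                if hap.alleles[j] != dom.alleles[j]:
                    return None
                break
            j += step
    return dom_allele


def derive_genotype(h1: Haplotype, h2: Haplotype) -> list[tuple]:
    """Unordered genotype pairs implied by a haplotype pair."""
    return [
        GenotypeTable._canon((a, b)) for a, b in zip(h1.alleles, h2.alleles)
    ]


def genotype_compatible(derived: list[tuple], observed: list[tuple]) -> bool:
    """Exact agreement wherever the derived pair is fully called; a derived
    MISSING never contradicts an observation."""
    for d, o in zip(derived, observed):
        if MISSING in d:
            continue
        if d != o:
            return False
    return True
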