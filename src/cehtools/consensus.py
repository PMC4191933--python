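"""Group assignment, dominant sequences and fixity curves.

A CEH group's *dominant sequence* is the allele vector followed by the
largest anchored subset of its haplotypes, swept telomere-to-centromere.
At each marker the dominant allele is the modal allele among the still
retained members with non-missing calls.  A retained member *deviates*
where its non-missing allele differs from the dominant allele.  A deviation
is *isolated* when the member matches the dominant allele at its nearest
non-missing markers on both sides (one marker each side by default); such
microvariation — rare private SNP/DIP alleles within an otherwise conserved
haplotype — does not count as loss of fixity and the member stays retained.
A non-isolated deviation (two or more consecutive deviating markers: a
crossover onto another sequence) removes the member from the retained set
at that marker, permanently.  MISSING spans never remove a member: identity
is assumed across unsequenced intervals.

When the retained members split into equally large modal classes, the
track forks into co-dominant continuations (as seen for CEHs with two
equally representative centromeric class II sequences); the merged track's
dominant allele becomes UNDEFINED wherever the continuations disagree.

*Fixity* at a marker is the retained count divided by the full original
group size, so the curve starts at 1 at the anchor and never increases
centromerically.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .model import (
    MISSING,
    UNDEFINED,
    CEHGroupSpec,
    Haplotype,
    MarkerMap,
)


@dataclass
class GroupAssignment:
    assignments: dict[str, Optional[str]]
    untypable: set[str] = field(default_factory=set)

    def members(self, group_id: str) -> list[str]:
        return [h for h, g in self.assignments.items() if g == group_id]


def assign_groups(
    haps: list[Haplotype], specs: list[CEHGroupSpec]
) -> GroupAssignment:
    """Assign each haplotype to the unique group whose core alleles it carries.

    Specs must partition: two specs that could both accept one haplotype
    (no core marker at which they demand different alleles) are a
    configuration error.  A haplotype with a MISSING call at a required
    marker of an otherwise matching spec is left unassigned and flagged
    untypable.  Assigned group ids are also written onto the haplotypes.
    """
    for i, s1 in enumerate(specs):
        for s2 in specs[i + 1:]:
            shared_conflict = any(
                idx in s2.core_requirements
                and s2.core_requirements[idx] != allele
                for idx, allele in s1.core_requirements.items()
            )
            if not shared_conflict:
                raise ValueError(
                    f"group specs {s1.group_id!r} and {s2.group_id!r} overlap: "
                    "no core marker distinguishes them"
                )
    out = GroupAssignment(assignments={})
    for h in haps:
        matched = [s.group_id for s in specs if s.matches(h) is True]
        if len(matched) > 1:  # unreachable given the partition check
            raise ValueError(
                f"haplotype {h.haplotype_id!r} matches multiple groups: "
                f"{matched}"
            )
        if matched:
            out.assignments[h.haplotype_id] = matched[0]
            h.group_id = matched[0]
        else:
            out.assignments[h.haplotype_id] = None
            h.group_id = None
            if any(s.matches(h) is None for s in specs):
                out.untypable.add(h.haplotype_id)
    return out


@dataclass
class CoDominantSplit:
    marker_index: int
    branch_alleles: list[str]
    branches: list["DominantSequence"]


@dataclass
class DominantSequence:
    """Anchored consensus of one group (or one co-dominant branch)."""

    group_id: str
    anchor: int
    group_size: int  # full original group size (fixity denominator)
    member_ids: list[str]
    alleles: list  # per map marker: token, UNDEFINED, or MISSING pre-anchor
    retained_count: list[int]
    support: list[int]
    removal_index: dict[str, int] = field(default_factory=dict)
    isolated_deviations: list[tuple[str, int, str]] = field(default_factory=list)
    splits: list[CoDominantSplit] = field(default_factory=list)

    def retained_at(self, marker_index: int) -> set[str]:
        """Members still carrying the dominant sequence at a marker."""
        return {
            m
            for m in self.member_ids
            if self.removal_index.get(m, len(self.alleles)) > marker_index
        }

    @property
    def final_retained(self) -> set[str]:
        return self.retained_at(len(self.alleles) - 1)


@dataclass
class FixityCurve:
    group_id: str
    positions: list[int]
    retained_count: list[int]
    fraction: list[float]


def compute_dominant_sequence(
    group_haps: list[Haplotype],
    marker_map: MarkerMap,
    anchor: int = 0,
    *,
    isolation_window: int = 1,
    group_id: Optional[str] = None,
) -> DominantSequence:
    """Sweep the group telomere→centromere and build its dominant sequence."""
    if not group_haps:
        raise ValueError("cannot compute a dominant sequence for an empty group")
    if group_id is None:
        group_id = group_haps[0].group_id or "group"
    alleles_by_id = {h.haplotype_id: h.alleles for h in group_haps}
    n = len(marker_map)
    member_ids = [h.haplotype_id for h in group_haps]
    return _sweep(
        group_id,
        member_ids,
        alleles_by_id,
        marker_map,
        start=anchor,
        anchor=anchor,
        group_size=len(member_ids),
        prefix=[MISSING] * anchor,
        isolation_window=isolation_window,
    )


def _provisional_dominant(alleles_by_id, retained, j) -> Optional[str]:
    counts = Counter(
        alleles_by_id[m][j]
        for m in retained
        if alleles_by_id[m][j] is not MISSING
    )
    if not counts:
        return None
    top = counts.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return None  # tie: undecidable
    return top[0][0]


def _is_isolated(
    member, i, dom_alleles, alleles_by_id, retained, n, window
) -> bool:
    """Member matches the dominant allele at its nearest ``window``
    non-missing informative markers on each side (vacuous at map edges).
    Telomeric markers use the already-fixed track; centromeric markers use
    a provisional mode over the currently retained members."""
    calls = alleles_by_id[member]
    # telomeric
    found = 0
    j = i - 1
    while j >= 0 and found < window:
        if (
            calls[j] is not MISSING
            and dom_alleles[j] is not MISSING
            and dom_alleles[j] != UNDEFINED
        ):
            if calls[j] != dom_alleles[j]:
                return False
            found += 1
        j -= 1
    # centromeric
    found = 0
    j = i + 1
    while j < n and found < window:
        if calls[j] is not MISSING:
            prov = _provisional_dominant(alleles_by_id, retained, j)
            if prov is not None:
                if calls[j] != prov:
                    return False
                found += 1
        j += 1
    return True


def _sweep(
    group_id,
    member_ids,
    alleles_by_id,
    marker_map,
    *,
    start,
    anchor,
    group_size,
    prefix,
    isolation_window,
) -> DominantSequence:
    n = len(marker_map)
    track = DominantSequence(
        group_id=group_id,
        anchor=anchor,
        group_size=group_size,
        member_ids=list(member_ids),
        alleles=list(prefix),
        retained_count=[len(member_ids)] * start,
        support=[0] * start,
    )
    retained: list[str] = list(member_ids)
    i = start
    while i < n:
        calls = {
            m: alleles_by_id[m][i]
            for m in retained
            if alleles_by_id[m][i] is not MISSING
        }
        if not calls:
            track.alleles.append(UNDEFINED)
            track.retained_count.append(len(retained))
            track.support.append(0)
            i += 1
            continue
        counts = Counter(calls.values()).most_common()
        modal = [t for t, c in counts if c == counts[0][1]]
        if len(modal) > 1:
            _fork(
                track,
                i,
                sorted(modal),
                retained,
                alleles_by_id,
                marker_map,
                isolation_window,
            )
            return track
        dom = modal[0]
        for m in list(retained):
            call = calls.get(m)
            if call is None or call == dom:
                continue
            if _is_isolated(
                m, i, track.alleles + [dom], alleles_by_id, retained, n,
                isolation_window,
            ):
                track.isolated_deviations.append((m, i, call))
            else:
                track.removal_index[m] = i
                retained.remove(m)
        track.alleles.append(dom)
        track.retained_count.append(len(retained))
        track.support.append(
            sum(1 for m in retained if alleles_by_id[m][i] is not MISSING)
        )
        i += 1
    return track


def _fork(track, i, modal, retained, alleles_by_id, marker_map, window):
    """Split the retained set into co-dominant branches at marker ``i``."""
    n = len(marker_map)
    branch_members: dict[str, list[str]] = {t: [] for t in modal}
    undecided: list[str] = []
    for m in retained:
        call = alleles_by_id[m][i]
        if call in branch_members:
            branch_members[call].append(m)
        else:
            undecided.append(m)
    # members MISSING or deviating at the split marker join the branch they
    # agree with at their next non-missing marker, else the largest branch
    for m in undecided:
        best = None
        j = i + 1
        while j < n and best is None:
            call = alleles_by_id[m][j]
            if call is not MISSING:
                for t in modal:
                    others = branch_members[t]
                    prov = _provisional_dominant(alleles_by_id, others, j)
                    if prov is not None and prov == call:
                        best = t
                        break
                break
            j += 1
        if best is None:
            best = max(modal, key=lambda t: (len(branch_members[t]), t))
        branch_members[best].append(m)

    branches = []
    for t in modal:
        sub = _sweep(
            track.group_id + f"|{t}@{i}",
            branch_members[t],
            alleles_by_id,
            marker_map,
            start=i,
            anchor=track.anchor,
            group_size=track.group_size,
            prefix=list(track.alleles),
            isolation_window=window,
        )
        branches.append(sub)
    track.splits.append(CoDominantSplit(i, modal, branches))
    for sub in branches:
        track.removal_index.update(sub.removal_index)
        track.isolated_deviations.extend(sub.isolated_deviations)
        track.splits.extend(sub.splits)
    # merged arrays: UNDEFINED where the continuations disagree
    for j in range(i, n):
        toks = {b.alleles[j] for b in branches}
        track.alleles.append(
            toks.pop() if len(toks) == 1 else UNDEFINED
        )
        track.retained_count.append(
            sum(b.retained_count[j] for b in branches)
        )
        track.support.append(sum(b.support[j] for b in branches))


def compute_fixity_curve(
    dom: DominantSequence, marker_map: MarkerMap, group_size: Optional[int] = None
) -> FixityCurve:
    """Retained fraction per analyzed marker, denominated by full group size."""
    size = group_size if group_size is not None else dom.group_size
    positions, counts, fractions = [], [], []
    for i in range(dom.anchor, len(marker_map)):
        positions.append(marker_map[i].position_bp)
        counts.append(dom.retained_count[i])
        fractions.append(dom.retained_count[i] / size)
    return FixityCurve(dom.group_id, positions, counts, fractions)
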