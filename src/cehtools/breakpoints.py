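"""Break-point localization, reference representation, tags and privates.

A haplotype that leaves its group's dominant sequence does so somewhere
between the last sequenced marker at which it still matched and the first
non-isolated mismatch; the crossover cannot be placed more precisely than
that interval, and unsequenced (MISSING) markers in between widen it.

The same sweep, run against an external reference haplotype (an MHC
Haplotype Project cell-line-style allele vector), yields the extent to
which the reference *represents* the group: representation ends where the
dominant sequence begins to contain alleles the reference does not carry,
tolerating isolated private mismatches in the reference itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .consensus import DominantSequence
from .model import MISSING, UNDEFINED, Haplotype, MarkerMap


class BreakpointStatus(str, Enum):
    RETAINED_THROUGH_END = "retained_through_end"
    CROSSED_OVER = "crossed_over"
    UNRESOLVABLE = "unresolvable"


@dataclass
class BreakpointCall:
    haplotype_id: str
    group_id: str
    status: BreakpointStatus
    last_match_pos: Optional[int] = None
    first_mismatch_pos: Optional[int] = None

    @property
    def interval_width_bp(self) -> int:
        if self.last_match_pos is None or self.first_mismatch_pos is None:
            return 0
        return self.first_mismatch_pos - self.last_match_pos


@dataclass
class RepresentationExtent:
    reference_id: str
    group_id: str
    whole_map: bool
    end_interval: Optional[tuple[int, int]] = None
    private_mismatches_tolerated: list[int] = field(default_factory=list)
    unresolvable: bool = False


def _member_track(dom: DominantSequence, member: str) -> DominantSequence:
    """Deepest co-dominant branch containing the member (or the main track)."""
    best, best_fork = dom, -1
    for split in dom.splits:
        for b in split.branches:
            if member in b.member_ids and split.marker_index > best_fork:
                best, best_fork = b, split.marker_index
    return best


def call_breakpoints(
    group_haps: list[Haplotype],
    dom: DominantSequence,
    marker_map: MarkerMap,
    *,
    anchor_bp: Optional[int] = None,
) -> list[BreakpointCall]:
    """One interval call per group member against its dominant track.

    ``anchor_bp`` is the boundary used as last_match_pos for a member
    deviating at the anchor marker itself; by default the anchor marker's
    own position (all members are assumed to carry the dominant sequence at
    the centromeric end of the core region).
    """
    if anchor_bp is None:
        anchor_bp = marker_map[dom.anchor].position_bp
    alleles_by_id = {h.haplotype_id: h.alleles for h in group_haps}
    calls = []
    for m in dom.member_ids:
        if m not in dom.removal_index:
            calls.append(
                BreakpointCall(m, dom.group_id, BreakpointStatus.RETAINED_THROUGH_END)
            )
            continue
        i = dom.removal_index[m]
        track = _member_track(dom, m)
        hap = alleles_by_id[m]
        last_match = None
        for j in range(i - 1, dom.anchor - 1, -1):
            t = track.alleles[j]
            if (
                hap[j] is not MISSING
                and t is not MISSING
                and t != UNDEFINED
                and hap[j] == t
            ):
                last_match = marker_map[j].position_bp
                break
        calls.append(
            BreakpointCall(
                m,
                dom.group_id,
                BreakpointStatus.CROSSED_OVER,
                last_match_pos=last_match if last_match is not None else anchor_bp,
                first_mismatch_pos=marker_map[i].position_bp,
            )
        )
    return calls


def representation_extent(
    reference: Haplotype,
    dom: DominantSequence,
    marker_map: MarkerMap,
    *,
    isolation_window: int = 1,
    max_missing_fraction: float = 0.5,
) -> RepresentationExtent:
    """How far the reference carries the group's dominant sequence.

    The scan runs telomere→centromere from the anchor.  Isolated reference
    mismatches (flanked by matches, like a cell line's private mutation) are
    tolerated and recorded.  At a co-dominant split the scan follows the
    continuation the reference matches; representation ends at the first
    non-isolated mismatch or at a split matching neither continuation.
    """
    n = len(marker_map)
    analyzed = range(dom.anchor, n)
    missing = sum(1 for i in analyzed if reference.alleles[i] is MISSING)
    if len(marker_map) - dom.anchor > 0 and missing / (n - dom.anchor) > max_missing_fraction:
        return RepresentationExtent(
            reference.haplotype_id, dom.group_id, whole_map=False,
            unresolvable=True,
        )

    track = dom
    tolerated: list[int] = []
    last_match: Optional[int] = None
    ref = reference.alleles

    def track_allele(i: int):
        return track.alleles[i]

    def isolated_here(i: int) -> bool:
        # telomeric flank against the fixed track, centromeric likewise
        for step in (-1, 1):
            found = 0
            j = i + step
            while 0 <= j < n and found < isolation_window:
                t = track.alleles[j]
                if ref[j] is not MISSING and t is not MISSING and t != UNDEFINED:
                    if ref[j] != t:
                        return False
                    found += 1
                j += step
        return True

    i = dom.anchor
    while i < n:
        split = next(
            (s for s in track.splits if s.marker_index == i), None
        )
        if split is not None and track.alleles[i] == UNDEFINED:
            chosen = None
            if ref[i] is not MISSING:
                for b in split.branches:
                    if b.alleles[i] == ref[i]:
                        chosen = b
                        break
            else:
                j = i + 1
                while j < n and chosen is None:
                    if ref[j] is not MISSING:
                        for b in split.branches:
                            if b.alleles[j] not in (MISSING, UNDEFINED) and b.alleles[j] == ref[j]:
                                chosen = b
                        break
                    j += 1
            if chosen is None:
                return RepresentationExtent(
                    reference.haplotype_id,
                    dom.group_id,
                    whole_map=False,
                    end_interval=(
                        marker_map[last_match].position_bp
                        if last_match is not None
                        else marker_map[dom.anchor].position_bp,
                        marker_map[i].position_bp,
                    ),
                    private_mismatches_tolerated=tolerated,
                )
            track = chosen
        t = track_allele(i)
        r = ref[i]
        if t is MISSING or t == UNDEFINED or r is MISSING:
            i += 1
            continue
        if r == t:
            last_match = i
        else:
            if isolated_here(i):
                tolerated.append(i)
            else:
                return RepresentationExtent(
                    reference.haplotype_id,
                    dom.group_id,
                    whole_map=False,
                    end_interval=(
                        marker_map[last_match].position_bp
                        if last_match is not None
                        else marker_map[dom.anchor].position_bp,
                        marker_map[i].position_bp,
                    ),
                    private_mismatches_tolerated=tolerated,
                )
        i += 1
    return RepresentationExtent(
        reference.haplotype_id,
        dom.group_id,
        whole_map=True,
        private_mismatches_tolerated=tolerated,
    )


def find_tag_markers(
    dom: DominantSequence,
    cohort_haps: list[Haplotype],
    marker_map: MarkerMap,
) -> list[tuple[int, str]]:
    """Marker/allele pairs carried by every retained group member and by no
    haplotype outside the retained set (non-missing calls only)."""
    by_id = {h.haplotype_id: h for h in cohort_haps}
    tags = []
    for i in range(dom.anchor, len(marker_map)):
        retained = dom.retained_at(i)
        inside = [
            by_id[m].alleles[i]
            for m in retained
            if m in by_id and by_id[m].alleles[i] is not MISSING
        ]
        if not inside:
            continue
        candidate = inside[0]
        if any(a != candidate for a in inside):
            continue
        outside_carries = any(
            h.alleles[i] == candidate
            for h in cohort_haps
            if h.haplotype_id not in retained
            and h.alleles[i] is not MISSING
        )
        if not outside_carries:
            tags.append((i, candidate))
    return tags


def find_private_variants(
    cohort_haps: list[Haplotype],
    dom: DominantSequence,
    marker_map: MarkerMap,
) -> list[tuple[str, int, str]]:
    """Isolated deviations whose allele occurs on exactly one cohort haplotype."""
    out = []
    seen = set()
    for member, i, allele in dom.isolated_deviations:
        if (member, i) in seen:
            continue
        seen.add((member, i))
        carriers = sum(
            1
            for h in cohort_haps
            if h.alleles[i] is not MISSING and h.alleles[i] == allele
        )
        if carriers == 1:
            out.append((member, i, allele))
    return out
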