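"""End-to-end driver: haplotypes + group specs → fixity, breakpoints, NCF."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .breakpoints import BreakpointCall, call_breakpoints
from .consensus import (
    DominantSequence,
    FixityCurve,
    GroupAssignment,
    assign_groups,
    compute_dominant_sequence,
    compute_fixity_curve,
)
from .model import CEHGroupSpec, Haplotype, MarkerMap
from .ncf import NCFTable, compute_ncf


@dataclass
class GroupResult:
    group_id: str
    members: list[Haplotype]
    dominant: DominantSequence
    fixity: FixityCurve
    breakpoints: list[BreakpointCall]
    ncf: NCFTable


@dataclass
class CohortResult:
    assignment: GroupAssignment
    groups: dict[str, GroupResult]


def analyze_cohort(
    haps: Sequence[Haplotype],
    marker_map: MarkerMap,
    specs: Sequence[CEHGroupSpec],
    *,
    anchor: int = 0,
    anchor_bp: Optional[int] = None,
    isolation_window: int = 1,
) -> CohortResult:
    """Assign groups, then compute each group's dominant sequence, fixity
    curve, breakpoint calls and NCF table against the map's sub-regions.

    ``anchor`` is the map index where every group member is assumed to carry
    its dominant sequence (the centromeric end of the core region);
    ``anchor_bp`` is the genomic boundary used for the first sub-region's
    distance (defaults to the position of the last marker before the first
    sub-region marker).
    """
    haps = list(haps)
    assignment = assign_groups(haps, list(specs))
    groups: dict[str, GroupResult] = {}
    for spec in specs:
        member_ids = set(assignment.members(spec.group_id))
        members = [h for h in haps if h.haplotype_id in member_ids]
        if not members:
            continue
        dom = compute_dominant_sequence(
            members,
            marker_map,
            anchor,
            isolation_window=isolation_window,
            group_id=spec.group_id,
        )
        fixity = compute_fixity_curve(dom, marker_map)
        bps = call_breakpoints(members, dom, marker_map, anchor_bp=anchor_bp)
        ncf = compute_ncf(
            bps,
            marker_map,
            group_size=len(members),
            anchor_bp=anchor_bp,
            group_id=spec.group_id,
        )
        groups[spec.group_id] = GroupResult(
            spec.group_id, members, dom, fixity, bps, ncf
        )
    return CohortResult(assignment, groups)
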