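"""Normalized crossover frequency (NCF) per genomic sub-region.

NCF measures the erosion of a CEH dominant sequence by recombination,
normalized so sub-regions of different physical size are comparable:

    NCF = (crossovers / total remaining haplotypes) x (1 Mb / distance covered)

where, for each analyzed sub-region in telomere→centromere order,

* *crossovers* is the number of haplotypes losing the dominant sequence in
  the sub-region — including crossovers deduced to have occurred in the gap
  between this sub-region and the previous one, which are assigned here;
* *total remaining haplotypes* is the number still carrying the dominant
  sequence throughout the region immediately telomeric (all group members
  are assumed to carry the dominant sequence at the anchor, so the first
  sub-region's denominator is the full group size);
* *distance covered* is the most centromeric analyzed point of the
  sub-region minus the most centromeric analyzed point of the previous one
  (or the configured anchor position for the first sub-region).

Because the bar plots draw the genomic axis to scale with bar height = NCF
and bar width = distance, bar *areas* — not heights — are proportional to
the fraction of remaining haplotypes lost, and are the quantity to compare
between sub-regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .breakpoints import BreakpointCall, BreakpointStatus
from .consensus import FixityCurve
from .model import MarkerMap

MB = 1_000_000


def ncf_value(crossovers: int, remaining: int, distance_bp: int) -> float:
    """The NCF formula for a single sub-region."""
    if remaining <= 0:
        if crossovers > 0:
            raise ValueError(
                f"impossible state: {crossovers} crossovers with no remaining "
                "haplotypes"
            )
        return 0.0
    if distance_bp <= 0:
        raise ValueError(f"non-positive distance {distance_bp}")
    return (crossovers / remaining) * (MB / distance_bp)


@dataclass
class NCFRow:
    subregion_id: int
    start_bp: int  # centromeric-most point of the prior region (exclusive)
    end_bp: int  # centromeric-most point of this region (inclusive)
    crossovers: int
    remaining: int
    distance_bp: int
    ncf: float

    @property
    def ncf_display(self) -> float:
        """Value at the one-decimal precision used in reports."""
        return round(self.ncf, 1)

    @property
    def bar_area(self) -> float:
        """ncf x width / 1 Mb == crossovers / remaining."""
        return self.ncf * self.distance_bp / MB


@dataclass
class NCFTable:
    group_id: str
    group_size: int
    anchor_bp: int
    rows: list[NCFRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group_id": self.group_id,
                "subregion_id": [r.subregion_id for r in self.rows],
                "start_bp": [r.start_bp for r in self.rows],
                "end_bp": [r.end_bp for r in self.rows],
                "crossovers": [r.crossovers for r in self.rows],
                "remaining": [r.remaining for r in self.rows],
                "distance_bp": [r.distance_bp for r in self.rows],
                "ncf": [r.ncf for r in self.rows],
                "ncf_display": [r.ncf_display for r in self.rows],
            }
        )


def compute_ncf(
    breakpoints: Sequence[BreakpointCall],
    marker_map: MarkerMap,
    group_size: int,
    *,
    anchor_bp: Optional[int] = None,
    group_id: Optional[str] = None,
) -> NCFTable:
    """Tabulate crossovers, remaining counts and NCF per sub-region.

    A crossed-over call is assigned to the sub-region whose interval
    ``(previous boundary, boundary]`` contains its first mismatching
    position, so crossovers deduced between two analyzed regions count in
    the centromeric (current) one.
    """
    subregions = marker_map.subregions
    if not subregions:
        raise ValueError("marker map defines no sub-regions")
    if anchor_bp is None:
        first_idx = min(
            i
            for i, m in enumerate(marker_map)
            if m.subregion_id is not None
        )
        anchor_bp = (
            marker_map[first_idx - 1].position_bp
            if first_idx > 0
            else marker_map[0].position_bp - 1
        )
    if group_id is None:
        group_id = breakpoints[0].group_id if breakpoints else "group"

    counts = {sid: 0 for sid, _ in subregions}
    for call in breakpoints:
        if call.status is not BreakpointStatus.CROSSED_OVER:
            continue
        pos = call.first_mismatch_pos
        sid = marker_map.subregion_of_position(pos, anchor_bp)
        if sid is None:
            raise ValueError(
                f"breakpoint at {pos} for {call.haplotype_id!r} lies outside "
                "the analyzed sub-regions"
            )
        counts[sid] += 1

    rows = []
    remaining = group_size
    prev = anchor_bp
    for sid, cm in subregions:
        k = counts[sid]
        distance = cm - prev
        rows.append(
            NCFRow(
                subregion_id=sid,
                start_bp=prev,
                end_bp=cm,
                crossovers=k,
                remaining=remaining,
                distance_bp=distance,
                ncf=ncf_value(k, remaining, distance),
            )
        )
        remaining -= k
        prev = cm
    return NCFTable(group_id, group_size, anchor_bp, rows)


def remaining_trajectory(table: NCFTable) -> list[int]:
    """Remaining haplotype counts entering each sub-region, plus the count
    retained through the last one (length K+1)."""
    out = [r.remaining for r in table.rows]
    out.append(table.rows[-1].remaining - table.rows[-1].crossovers)
    return out


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    # fixed float formatting so identical inputs give identical bytes
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f", lineterminator="\n")


def render_reports(
    fixity_curves: Sequence[FixityCurve],
    ncf_tables: Sequence[NCFTable],
    marker_map: MarkerMap,
    out_dir: Path,
    *,
    plot: bool = True,
) -> dict[str, Path]:
    """Write fixity and NCF TSVs and a to-scale bar/fixity figure.

    TSV output is bit-stable for identical inputs.  In the figure each
    sub-region is a bar spanning its genomic interval with height NCF, so
    bar area is proportional to the fraction of remaining haplotypes lost;
    the fixity curves are overlaid on a secondary axis.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fix_frames = [
        pd.DataFrame(
            {
                "group_id": c.group_id,
                "position_bp": c.positions,
                "retained_count": c.retained_count,
                "fraction": c.fraction,
            }
        )
        for c in fixity_curves
    ]
    fix = (
        pd.concat(fix_frames, ignore_index=True)
        if fix_frames
        else pd.DataFrame(
            columns=["group_id", "position_bp", "retained_count", "fraction"]
        )
    )
    paths["fixity"] = out_dir / "fixity.tsv"
    _write_tsv(fix, paths["fixity"])

    ncf_frames = [t.to_frame() for t in ncf_tables]
    ncf = (
        pd.concat(ncf_frames, ignore_index=True)
        if ncf_frames
        else pd.DataFrame(
            columns=[
                "group_id", "subregion_id", "start_bp", "end_bp",
                "crossovers", "remaining", "distance_bp", "ncf", "ncf_display",
            ]
        )
    )
    paths["ncf"] = out_dir / "ncf.tsv"
    _write_tsv(ncf, paths["ncf"])

    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        groups = sorted(
            {t.group_id for t in ncf_tables}
            | {c.group_id for c in fixity_curves}
        )
        n_g = max(1, len(groups))
        fig, axes = plt.subplots(
            n_g, 1, figsize=(10, 2.6 * n_g), squeeze=False, sharex=True
        )
        curve_by_group = {c.group_id: c for c in fixity_curves}
        table_by_group = {t.group_id: t for t in ncf_tables}
        for ax, g in zip(axes[:, 0], groups or ["(empty)"]):
            t = table_by_group.get(g)
            if t:
                for r in t.rows:
                    ax.bar(
                        r.start_bp,
                        r.ncf,
                        width=r.distance_bp,
                        align="edge",
                        color="#4878a8",
                        edgecolor="black",
                        linewidth=0.5,
                    )
            ax.set_ylabel("NCF (/Mb)")
            ax.set_title(g, fontsize=9)
            c = curve_by_group.get(g)
            if c:
                ax2 = ax.twinx()
                ax2.plot(c.positions, c.fraction, color="#b04030", lw=1.2)
                ax2.set_ylim(0, 1.05)
                ax2.set_ylabel("fixity")
        axes[-1, 0].set_xlabel("GRCh37 chr6 position (bp)")
        fig.tight_layout()
        paths["plot"] = out_dir / "ncf_fixity.png"
        fig.savefig(paths["plot"], dpi=120)
        plt.close(fig)
    return paths
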