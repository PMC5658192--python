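"""Per-origin ssDNA peak-area quantification.

The activity statistic for an origin is the running sum of gridded S/G1
values walked outward from the origin's grid point, one point at a time on
each side independently, until three below-threshold values have been
accumulated on that side. Every traversed value — including below-threshold
ones — contributes to the area, so the statistic captures both peak height
and width. Overlap detection between adjacent peak territories automates
the manual exclusion of origins firing in close proximity.

The walk is parameterized: the stop counter can be cumulative (default) or
consecutive, and below-threshold values can be included in (default) or
excluded from the sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeAnnotation
from .profiles import ChromosomeProfile, SmoothedProfileSet

__all__ = ["PeakRecord", "PeakTable", "peak_area", "call_all_origins", "flag_overlaps"]

#: Below-threshold values a side accumulates before it stops.
N_BELOW_STOP = 3
#: Grid points traversed by the walk on a track that is below threshold
#: everywhere: the origin plus N_BELOW_STOP per side.
MIN_TRAVERSAL_POINTS = 2 * N_BELOW_STOP + 1


@dataclass(frozen=True)
class PeakRecord:
    """Peak-area walk result for one origin.

    ``left_index``/``right_index`` index the chromosome profile arrays;
    ``left_bp``/``right_bp`` are the corresponding grid coordinates. A
    ``masked`` record carries no area (NaN). ``truncated`` marks a walk
    stopped by a chromosome end or a masked gap before its third
    below-threshold value.
    """

    origin_id: str
    chrom: str
    origin_pos: int
    origin_index: int
    area: float
    left_index: int
    right_index: int
    left_bp: int
    right_bp: int
    overlapping: bool = False
    masked: bool = False
    truncated: bool = False

    @property
    def flagged(self) -> bool:
        return self.overlapping or self.masked or self.truncated

    @property
    def flags(self) -> str:
        names = [
            n
            for n, v in (
                ("overlapping", self.overlapping),
                ("masked", self.masked),
                ("truncated", self.truncated),
            )
            if v
        ]
        return ",".join(names) if names else "."


@dataclass
class PeakTable:
    """One peak record per annotated origin for a single sample track."""

    genotype: str
    records: list[PeakRecord]
    threshold: float
    profiles: SmoothedProfileSet | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self) -> dict[str, PeakRecord]:
        return {r.origin_id: r for r in self.records}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "origin_id": [r.origin_id for r in self.records],
                "chrom": [r.chrom for r in self.records],
                "origin_pos": [r.origin_pos for r in self.records],
                "area": [r.area for r in self.records],
                "left_bp": [r.left_bp for r in self.records],
                "right_bp": [r.right_bp for r in self.records],
                "flags": [r.flags for r in self.records],
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _nearest_grid_index(positions: np.ndarray, pos: int) -> int:
    """Index of the grid point nearest pos; ties go to the lower coordinate."""
    j = int(np.searchsorted(positions, pos))
    if j == 0:
        return 0
    if j == len(positions):
        return len(positions) - 1
    # tie (equidistant) falls to j - 1, the lower coordinate
    return j if (positions[j] - pos) < (pos - positions[j - 1]) else j - 1


def _walk_side(
    values: np.ndarray,
    positions: np.ndarray,
    start: int,
    step_dir: int,
    theta: float,
    grid_step: int,
    stop_rule: str,
    include_below: bool,
    n_below: int,
) -> tuple[float, int, bool]:
    """Walk one side; returns (side sum, boundary index, truncated)."""
    total = 0.0
    below_count = 0
    i = start
    while below_count < n_below:
        j = i + step_dir
        if j < 0 or j >= len(values):
            return total, i, True  # chromosome end
        if abs(int(positions[j]) - int(positions[i])) != grid_step:
            return total, i, True  # masked gap: treated like an end
        below = values[j] < theta
        if include_below or not below:
            total += float(values[j])
        if below:
            below_count += 1
        elif stop_rule == "consecutive":
            below_count = 0
        i = j
    return total, i, False


def peak_area(
    profile: ChromosomeProfile,
    origin_pos: int,
    theta: float,
    origin_id: str = "origin",
    masks: list[tuple[int, int]] | None = None,
    stop_rule: str = "cumulative",
    include_below: bool = True,
    n_below: int = N_BELOW_STOP,
    grid_step: int | None = None,
) -> PeakRecord:
    """Run the peak-area walk for one origin on one chromosome profile.

    Starting at the grid point nearest ``origin_pos`` (ties broken toward
    the lower coordinate), the walk proceeds outward one grid point at a
    time independently on each side; a side stops immediately after its
    count of strictly-below-``theta`` values reaches ``n_below`` (counted
    cumulatively by default, consecutively if ``stop_rule='consecutive'``),
    or at a chromosome end / masked gap, which sets the ``truncated`` flag.
    The origin point itself is summed exactly once and does not count
    toward either side's stop counter.
    """
    if stop_rule not in ("cumulative", "consecutive"):
        raise ValueError(f"unknown stop_rule {stop_rule!r}")
    if len(profile) == 0:
        raise ValueError(f"empty profile for chromosome {profile.chrom}")
    if masks and any(s <= origin_pos < e for s, e in masks):
        return PeakRecord(
            origin_id, profile.chrom, origin_pos, -1, float("nan"),
            -1, -1, -1, -1, masked=True,
        )
    if grid_step is None:
        diffs = np.diff(profile.positions)
        grid_step = int(diffs.min()) if len(diffs) else 1
    pos = profile.positions
    vals = profile.values
    i0 = _nearest_grid_index(pos, origin_pos)
    area = float(vals[i0])
    args = (theta, grid_step, stop_rule, include_below, n_below)
    left_sum, left_idx, left_trunc = _walk_side(vals, pos, i0, -1, *args)
    right_sum, right_idx, right_trunc = _walk_side(vals, pos, i0, +1, *args)
    return PeakRecord(
        origin_id,
        profile.chrom,
        origin_pos,
        i0,
        area + left_sum + right_sum,
        left_idx,
        right_idx,
        int(pos[left_idx]),
        int(pos[right_idx]),
        truncated=left_trunc or right_trunc,
    )


def call_all_origins(
    profiles: SmoothedProfileSet,
    annotation: GenomeAnnotation,
    genotype: str = "sample",
    **walk_kwargs,
) -> PeakTable:
    """Quantify every annotated origin against one smoothed track.

    The threshold is the track's genome-wide mean. Origins inside masked
    intervals are flagged ``masked`` and carry no area. An origin on a
    chromosome absent from the profile set is an error.
    """
    theta = profiles.threshold
    records = []
    for o in annotation.origins:
        if o.chrom not in profiles:
            raise ValueError(f"origin {o.id}: chromosome {o.chrom} not in profile set")
        chrom_masks = [(s, e) for c, s, e in profiles.masks if c == o.chrom]
        records.append(
            peak_area(
                profiles[o.chrom],
                o.pos,
                theta,
                origin_id=o.id,
                masks=chrom_masks,
                grid_step=profiles.grid_step,
                **walk_kwargs,
            )
        )
    return PeakTable(genotype, records, theta, profiles)


def flag_overlaps(table: PeakTable) -> PeakTable:
    """Flag every pair of records whose traversal intervals intersect.

    Two records on the same chromosome whose [left_bp, right_bp] intervals
    share any grid point are both flagged ``overlapping``; flagged records
    are retained (for auditability) but excluded from downstream statistics
    by default. Masked records, which have no traversal, never overlap.
    """
    records = list(table.records)
    by_chrom: dict[str, list[int]] = {}
    for idx, r in enumerate(records):
        if not r.masked:
            by_chrom.setdefault(r.chrom, []).append(idx)
    overlapping = set()
    for idxs in by_chrom.values():
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                ra, rb = records[idxs[a]], records[idxs[b]]
                if ra.left_bp <= rb.right_bp and rb.left_bp <= ra.right_bp:
                    overlapping.update((idxs[a], idxs[b]))
    new_records = [
        replace(r, overlapping=True) if i in overlapping else r
        for i, r in enumerate(records)
    ]
    return PeakTable(table.genotype, new_records, table.threshold, table.profiles)
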