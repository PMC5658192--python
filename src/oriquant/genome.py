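"""Genome annotations: chromosomes, centromeres, replication origins, masks.

The annotation plays the role of the curated origin reference list (an
OriDB-style table of confirmed origins) together with centromere positions
and any intervals to exclude from signal analysis, such as the rDNA array
and its flanks on chromosome XII. Internally all coordinates are 0-based
base pairs; files are written and read as BED (0-based, half-open), with the
conversion confined to the I/O functions here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "Origin",
    "GenomeAnnotation",
    "read_bed",
    "write_origins_bed",
    "write_centromeres_bed",
    "write_masks_bed",
    "read_annotation_beds",
]


@dataclass(frozen=True)
class Origin:
    """A replication origin: unique id, chromosome, position (0-based bp)."""

    id: str
    chrom: str
    pos: int


@dataclass
class GenomeAnnotation:
    """Chromosome sizes, centromeres, origin list and masked intervals.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    centromeres
        One centromere position (bp) per chromosome name.
    origins
        Origin records; ids must be unique and positions in-bounds.
    masked_intervals
        ``(chrom, start, end)`` half-open intervals excluded from analysis
        (e.g. the rDNA locus and flanks on Chr XII).
    """

    chromosomes: list[tuple[str, int]]
    centromeres: dict[str, int]
    origins: list[Origin]
    masked_intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = self.chrom_lengths
        if len(lengths) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        ids = [o.id for o in self.origins]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate origin ids: {dupes}")
        for o in self.origins:
            if o.chrom not in lengths:
                raise ValueError(f"origin {o.id} on unknown chromosome {o.chrom}")
            if not 0 <= o.pos < lengths[o.chrom]:
                raise ValueError(f"origin {o.id} position {o.pos} outside {o.chrom}")
        for chrom, pos in self.centromeres.items():
            if chrom not in lengths:
                raise ValueError(f"centromere on unknown chromosome {chrom}")
            if not 0 <= pos < lengths[chrom]:
                raise ValueError(f"centromere position {pos} outside {chrom}")
        for chrom, start, end in self.masked_intervals:
            if chrom not in lengths:
                raise ValueError(f"mask on unknown chromosome {chrom}")
            if not (0 <= start <= end <= lengths[chrom]):
                raise ValueError(f"mask ({chrom}, {start}, {end}) out of bounds")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def origin_ids(self) -> list[str]:
        return [o.id for o in self.origins]

    def origins_by_id(self) -> dict[str, Origin]:
        return {o.id: o for o in self.origins}

    def masks_on(self, chrom: str) -> list[tuple[int, int]]:
        return [(s, e) for c, s, e in self.masked_intervals if c == chrom]

    def is_masked(self, chrom: str, pos: int) -> bool:
        """Whether a 0-based position falls inside a masked interval."""
        return any(s <= pos < e for s, e in self.masks_on(chrom))


# --- BED I/O -----------------------------------------------------------------
# BED is 0-based half-open; internal positions are already 0-based bp, so a
# point feature at pos p is the interval [p, p+1).

_BED_COLS = ["chrom", "start", "end", "name"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a headerless 3- or 4-column BED file into a DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.assign(name=".")
    df.columns = _BED_COLS
    return df


def _write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def write_origins_bed(annotation: GenomeAnnotation, path: str | Path) -> None:
    df = pd.DataFrame(
        [(o.chrom, o.pos, o.pos + 1, o.id) for o in annotation.origins],
        columns=_BED_COLS,
    )
    _write_bed(df, path)


def write_centromeres_bed(annotation: GenomeAnnotation, path: str | Path) -> None:
    df = pd.DataFrame(
        [(c, p, p + 1, f"CEN_{c}") for c, p in annotation.centromeres.items()],
        columns=_BED_COLS,
    )
    _write_bed(df, path)


def write_masks_bed(annotation: GenomeAnnotation, path: str | Path) -> None:
    df = pd.DataFrame(
        [(c, s, e, "mask") for c, s, e in annotation.masked_intervals],
        columns=_BED_COLS,
    )
    _write_bed(df, path)


def read_annotation_beds(
    chromosomes: list[tuple[str, int]],
    origins_bed: str | Path,
    centromeres_bed: str | Path,
    masks_bed: str | Path | None = None,
) -> GenomeAnnotation:
    """Assemble a :class:`GenomeAnnotation` from BED files plus sizes.

    Point features (origins, centromeres) are taken as the interval start.
    """
    ori = read_bed(origins_bed)
    cen = read_bed(centromeres_bed)
    origins = [
        Origin(str(r.name), str(r.chrom), int(r.start))
        for r in ori.itertuples(index=False)
    ]
    centromeres = {str(r.chrom): int(r.start) for r in cen.itertuples(index=False)}
    masks: list[tuple[str, int, int]] = []
    if masks_bed is not None:
        m = read_bed(masks_bed)
        masks = [(str(r.chrom), int(r.start), int(r.end)) for r in m.itertuples(index=False)]
    return GenomeAnnotation(chromosomes, centromeres, origins, masks)
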