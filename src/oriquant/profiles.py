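"""S/G1 ratio tracks: probe-table I/O, Loess smoothing, genome-mean threshold.

The ssDNA assay reports, per microarray probe, the fluorescence of an
S-phase sample (cells released into S in hydroxyurea, which stalls forks
near origins) and a G1 control. The per-probe S/G1 ratio peaks over early,
efficient origins. This module reads those probe tables, smooths the ratio
onto a fixed 500-bp grid with a local-linear (degree-1) tricube-weighted
regression, and computes the genome-wide mean of the smoothed track — the
threshold used by the peak-area walk, reflecting that most of the genome is
double-stranded background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GRID_STEP",
    "DEFAULT_SPAN_BP",
    "ChromosomeProfile",
    "SmoothedProfileSet",
    "read_probe_table",
    "write_probe_table",
    "form_ratios",
    "loess_smooth",
    "genome_mean_threshold",
    "write_bedgraph",
    "read_bedgraph",
]

GRID_STEP = 500
#: Smoothing window half-width in bp (~10 probes at 300-bp spacing): wide
#: enough to denoise, narrow relative to ~10-kb origin peaks.
DEFAULT_SPAN_BP = 3000

_PROBE_COLUMNS = ["probe_id", "chrom", "position", "signal_S", "signal_G1"]


def read_probe_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated probe table.

    The file dialect is: header ``probe_id chrom position signal_S
    signal_G1`` with 1-based positions. Returned positions are 0-based.
    Malformed rows (non-numeric fields) raise with their line numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[_PROBE_COLUMNS].copy()
    bad_lines: list[int] = []
    for col in ("position", "signal_S", "signal_G1"):
        vals = pd.to_numeric(df[col], errors="coerce")
        # +2: 1 for the header line, 1 for 1-based file lines
        bad_lines.extend((np.flatnonzero(vals.isna() & df[col].notna()) + 2).tolist())
        df[col] = vals
    if bad_lines:
        raise ValueError(
            f"{path}: non-numeric values on lines {sorted(set(bad_lines))}"
        )
    if df["position"].isna().any() or (df["position"] < 1).any():
        raise ValueError(f"{path}: positions must be positive integers (1-based)")
    df["position"] = df["position"].astype(np.int64) - 1
    df[["signal_S", "signal_G1"]] = df[["signal_S", "signal_G1"]].astype(float)
    df = df.sort_values(["chrom", "position"], kind="stable").reset_index(drop=True)
    return df


def write_probe_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a probe table (internal 0-based positions) as 1-based TSV."""
    out = table[_PROBE_COLUMNS].copy()
    out["position"] = out["position"].astype(np.int64) + 1
    out.to_csv(path, sep="\t", index=False)


def form_ratios(table: pd.DataFrame) -> pd.DataFrame:
    """Attach the per-probe S/G1 ratio, excluding probes with G1 <= 0."""
    bad = table["signal_G1"] <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} probe(s) with signal_G1 <= 0 excluded from "
            "ratio formation",
            stacklevel=2,
        )
    out = table.loc[~bad].copy()
    out["ratio"] = out["signal_S"] / out["signal_G1"]
    return out


@dataclass
class ChromosomeProfile:
    """Smoothed ratio values on the grid of one chromosome.

    ``positions`` holds only unmasked grid coordinates (exact multiples of
    the step, strictly increasing); masked intervals appear as gaps.
    """

    chrom: str
    positions: np.ndarray
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class SmoothedProfileSet:
    """Per-chromosome smoothed tracks plus the genome-mean threshold θ."""

    profiles: dict[str, ChromosomeProfile]
    grid_step: int = GRID_STEP
    masks: list[tuple[str, int, int]] = field(default_factory=list)
    threshold: float = field(init=False)

    def __post_init__(self) -> None:
        self.threshold = genome_mean_threshold(self)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.profiles

    def __getitem__(self, chrom: str) -> ChromosomeProfile:
        return self.profiles[chrom]


def genome_mean_threshold(profiles: SmoothedProfileSet) -> float:
    """Unweighted mean over all unmasked grid values of all chromosomes."""
    chunks = [p.values for p in profiles.profiles.values() if len(p)]
    if not chunks:
        raise ValueError("no unmasked grid values: threshold undefined")
    return float(np.concatenate(chunks).mean())


def _in_masks(positions: np.ndarray, masks: list[tuple[int, int]]) -> np.ndarray:
    hit = np.zeros(len(positions), dtype=bool)
    for start, end in masks:
        hit |= (positions >= start) & (positions < end)
    return hit


def _loess_fit(x: np.ndarray, y: np.ndarray, grid: np.ndarray, span: float) -> np.ndarray:
    """Degree-1 local regression with tricube weights, window half-width span."""
    out = np.empty(len(grid))
    lo = np.searchsorted(x, grid - span, side="left")
    hi = np.searchsorted(x, grid + span, side="right")
    for i, g in enumerate(grid):
        xs = x[lo[i]:hi[i]]
        ys = y[lo[i]:hi[i]]
        if len(xs) == 0:
            out[i] = np.nan
            continue
        d = np.abs(xs - g) / span
        w = (1.0 - d**3) ** 3
        sw = w.sum()
        if sw <= 0:  # only zero-weight (boundary) probes in window
            out[i] = np.nan
            continue
        xc = xs - g
        swx = w @ xc
        swxx = w @ (xc * xc)
        swy = w @ ys
        swxy = w @ (xc * ys)
        denom = sw * swxx - swx * swx
        if denom <= 1e-12 * sw * max(swxx, 1e-300):
            out[i] = swy / sw  # degenerate design: weighted mean
        else:
            slope = (sw * swxy - swx * swy) / denom
            intercept = (swy - slope * swx) / sw
            out[i] = intercept  # fit evaluated at the centered point g
    return out


def loess_smooth(
    table: pd.DataFrame,
    span_bp: float = DEFAULT_SPAN_BP,
    grid_step: int = GRID_STEP,
    masks: list[tuple[str, int, int]] | None = None,
    chrom_lengths: dict[str, int] | None = None,
    min_probes: int = 3,
) -> SmoothedProfileSet:
    """Smooth per-probe S/G1 ratios onto the fixed grid, per chromosome.

    Each chromosome is smoothed independently by local linear regression
    with tricube weights over a window of half-width ``span_bp`` centered on
    each grid point (0, ``grid_step``, 2·``grid_step``, …). Grid points
    inside ``masks`` are omitted. Chromosomes with fewer than ``min_probes``
    probes are skipped with a warning.
    """
    if span_bp <= grid_step:
        raise ValueError("span_bp must exceed grid_step")
    masks = list(masks or [])
    if "ratio" not in table.columns:
        table = form_ratios(table)
    profiles: dict[str, ChromosomeProfile] = {}
    for chrom, sub in table.groupby("chrom", sort=False):
        x = sub["position"].to_numpy(dtype=float)
        y = sub["ratio"].to_numpy(dtype=float)
        if len(x) < min_probes:
            warnings.warn(
                f"chromosome {chrom}: only {len(x)} probes, skipped", stacklevel=2
            )
            continue
        top = (chrom_lengths[chrom] - 1) if chrom_lengths else int(x.max())
        grid = np.arange(0, top + 1, grid_step, dtype=np.int64)
        chrom_masks = [(s, e) for c, s, e in masks if c == chrom]
        keep = ~_in_masks(grid, chrom_masks)
        grid = grid[keep]
        vals = _loess_fit(x, y, grid.astype(float), float(span_bp))
        ok = ~np.isnan(vals)
        profiles[str(chrom)] = ChromosomeProfile(str(chrom), grid[ok], vals[ok])
    return SmoothedProfileSet(profiles, grid_step=grid_step, masks=masks)


# --- bedGraph I/O ------------------------------------------------------------

def write_bedgraph(profiles: SmoothedProfileSet, path: str | Path) -> None:
    """Export smoothed tracks as bedGraph (chrom, start, start+step, value)."""
    step = profiles.grid_step
    frames = [
        pd.DataFrame(
            {
                "chrom": p.chrom,
                "start": p.positions,
                "end": p.positions + step,
                "value": p.values,
            }
        )
        for p in profiles.profiles.values()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(
    path: str | Path,
    masks: list[tuple[str, int, int]] | None = None,
) -> SmoothedProfileSet:
    """Import an externally smoothed track in bedGraph format.

    The grid step is inferred from the interval widths; the genome-mean
    threshold is recomputed from the imported values.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    widths = (df["end"] - df["start"]).unique()
    if len(widths) != 1:
        raise ValueError(f"{path}: non-uniform interval widths {sorted(widths)}")
    step = int(widths[0])
    df = df.sort_values(["chrom", "start"], kind="stable")
    profiles = {
        str(chrom): ChromosomeProfile(
            str(chrom),
            sub["start"].to_numpy(dtype=np.int64),
            sub["value"].to_numpy(dtype=float),
        )
        for chrom, sub in df.groupby("chrom", sort=False)
    }
    return SmoothedProfileSet(profiles, grid_step=step, masks=list(masks or []))
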