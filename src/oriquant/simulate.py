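"""Synthetic ssDNA study generator with known ground truth.

Emulates the data a two-channel tiling microarray would report for cells
released into S phase in hydroxyurea: probes a few hundred bp apart across
16 chromosomes, S/G1 ratio peaks of finite width centered on active
origins, genotype-dependent per-origin amplitudes, multiplicative noise,
and optional masked regions standing in for the rDNA array. Every
stochastic operation takes an explicit seed and identical seeds give
byte-identical tables, so the full downstream pipeline is testable against
planted truth without any download.

The expected S/G1 ratio at position x is

    baseline + sum over origins of amplitude * exp(-(x - pos)^2 / (2 sigma^2))

with a Gaussian peak shape (default sigma 5 kb, reflecting the short fork
travel under HU) and, when the noise CV is positive, a multiplicative
lognormal factor with unit mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import proximal_origin_ids
from .genome import GenomeAnnotation, Origin
from .peaks import peak_area
from .profiles import GRID_STEP, ChromosomeProfile

__all__ = [
    "SimulationTruth",
    "make_genome",
    "simulate_probe_table",
    "simulate_enrichment_scenario",
    "expected_profile",
    "true_peak_areas",
]

DEFAULT_PEAK_WIDTH_BP = 5_000.0
DEFAULT_BASELINE = 1.0
DEFAULT_NOISE_CV = 0.1
DEFAULT_PROBE_SPACING = 300
DEFAULT_JITTER_BP = 50


@dataclass
class SimulationTruth:
    """Ground truth behind a simulated probe table.

    ``amplitudes`` maps genotype -> origin id -> true peak amplitude (ratio
    units above baseline; exactly 0 for an origin inactive in that
    genotype). ``true_areas`` holds, per genotype, the area the peak-area
    walk yields on the *noiseless expected* profile evaluated on the
    analysis grid, using that profile's own genome mean as threshold — the
    target the noisy pipeline should recover up to grid and smoothing
    error. Its above-baseline part scales linearly with the amplitudes
    (the walk's traversal depends only on the sign of value - threshold,
    which amplitude scaling preserves).
    """

    amplitudes: dict[str, dict[str, float]]
    peak_width_bp: float = DEFAULT_PEAK_WIDTH_BP
    baseline: float = DEFAULT_BASELINE
    noise_cv: float = DEFAULT_NOISE_CV
    true_areas: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.peak_width_bp <= 0 or self.baseline < 0 or self.noise_cv < 0:
            raise ValueError("width must be positive, baseline and CV non-negative")
        for genotype, amps in self.amplitudes.items():
            bad = [i for i, a in amps.items() if a < 0]
            if bad:
                raise ValueError(f"negative amplitudes for {genotype}: {bad}")


def make_genome(
    n_chromosomes: int = 16,
    chromosome_length: int = 750_000,
    n_origins: int = 213,
    n_centromere_proximal: int = 16,
    proximity_window: int = 10_000,
    seed: int | None = None,
    masked_intervals: list[tuple[str, int, int]] | None = None,
    min_spacing: int | None = None,
    edge_margin: int = 0,
) -> GenomeAnnotation:
    """Build a stand-in genome with a controlled number of proximal origins.

    Exactly ``n_centromere_proximal`` origins lie within
    ``proximity_window`` bp (inclusive) of their centromere; all others lie
    strictly farther. Origins are kept at least ``min_spacing`` apart
    (default twice the window, so proximity statuses never interact; raise
    it when simulating wide peaks that must not overlap), and at least
    ``edge_margin`` bp from chromosome ends (set it when truncated
    peak-area walks must not occur). One centromere
    per chromosome at a seeded interior position. Infeasible requests (more
    origins than the genome can hold at that spacing) raise rather than
    truncate.
    """
    if n_centromere_proximal > n_origins:
        raise ValueError("n_centromere_proximal cannot exceed n_origins")
    if proximity_window <= 0:
        raise ValueError("proximity_window must be positive")
    rng = np.random.default_rng(seed)
    w = proximity_window
    s = max(min_spacing or 0, 2 * w)
    per_cen = 2 if s == 2 * w else 1  # cen-w / cen+w are only 2w apart
    if n_centromere_proximal > per_cen * n_chromosomes:
        raise ValueError(
            f"at most {per_cen} proximal origin(s) fit per centromere at "
            f"{s}-bp spacing: requested {n_centromere_proximal} on "
            f"{n_chromosomes} chromosomes"
        )
    names = [f"chr{i + 1:02d}" for i in range(n_chromosomes)]
    chromosomes = [(name, chromosome_length) for name in names]
    lo, hi = int(0.25 * chromosome_length), int(0.75 * chromosome_length)
    if hi - lo < 1 or chromosome_length < 6 * w:
        raise ValueError("chromosome_length too small for the proximity window")
    centromeres = {name: int(rng.integers(lo, hi)) for name in names}
    masked_intervals = list(masked_intervals or [])

    def unmasked(chrom: str, pos: int) -> bool:
        return not any(
            c == chrom and s <= pos < e for c, s, e in masked_intervals
        )

    # proximal slots: cen - w and cen + w (distance exactly w); distal
    # slots: cen +/- (s + w + j*s) — strictly farther than w from the
    # centromere, and >= s from each other and from the proximal slots
    positions: list[tuple[str, int]] = []
    side = rng.integers(0, 2, size=n_chromosomes)
    for k in range(n_centromere_proximal):
        chrom = names[k % n_chromosomes]
        cen = centromeres[chrom]
        if k < n_chromosomes:
            pos = cen + (w if side[k] else -w)
        else:
            prev = positions[k - n_chromosomes][1]
            pos = cen + (cen - prev)  # the opposite slot
        if not (0 <= pos < chromosome_length) or not unmasked(chrom, pos):
            raise ValueError(f"cannot place proximal origin near {chrom} centromere")
        positions.append((chrom, pos))

    distal: list[tuple[str, int]] = []
    for chrom in names:
        cen = centromeres[chrom]
        for sign in (-1, +1):
            offset = s + w
            while edge_margin <= cen + sign * offset < chromosome_length - edge_margin:
                pos = cen + sign * offset
                if unmasked(chrom, pos):
                    distal.append((chrom, pos))
                offset += s
    n_distal = n_origins - n_centromere_proximal
    if n_distal > len(distal):
        raise ValueError(
            f"genome too small: {n_distal} non-proximal origins requested but "
            f"only {len(distal)} placements available at 2x-window spacing"
        )
    pick = rng.choice(len(distal), size=n_distal, replace=False)
    positions.extend(distal[i] for i in sorted(pick))

    order = {name: i for i, name in enumerate(names)}
    positions.sort(key=lambda cp: (order[cp[0]], cp[1]))
    width = len(str(n_origins))
    origins = [
        Origin(f"ORI_{i + 1:0{width}d}", chrom, pos)
        for i, (chrom, pos) in enumerate(positions)
    ]
    return GenomeAnnotation(chromosomes, centromeres, origins, masked_intervals)


def expected_profile(
    positions: np.ndarray,
    chrom: str,
    annotation: GenomeAnnotation,
    truth: SimulationTruth,
    genotype: str,
) -> np.ndarray:
    """Noise-free expected S/G1 ratio at the given positions on one chromosome."""
    amps = truth.amplitudes[genotype]
    x = np.asarray(positions, dtype=float)
    y = np.full(len(x), truth.baseline, dtype=float)
    sigma = truth.peak_width_bp
    for o in annotation.origins:
        if o.chrom != chrom:
            continue
        a = amps.get(o.id, 0.0)
        if a == 0.0:
            continue
        lo, hi = np.searchsorted(x, [o.pos - 6 * sigma, o.pos + 6 * sigma])
        y[lo:hi] += a * np.exp(-((x[lo:hi] - o.pos) ** 2) / (2 * sigma**2))
    return y


def simulate_probe_table(
    annotation: GenomeAnnotation,
    truth: SimulationTruth,
    genotype: str,
    probe_spacing: int = DEFAULT_PROBE_SPACING,
    jitter_bp: int = DEFAULT_JITTER_BP,
    g1_level: float = 1000.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate one genotype's two-channel probe table.

    Probes are placed every ``probe_spacing`` bp with uniform jitter of up
    to ``jitter_bp``; probes falling in masked intervals are omitted. The
    G1 channel fluctuates around ``g1_level`` and the S channel is the
    (noisy) ratio times the G1 signal, so the per-probe ratio carries
    exactly the specified multiplicative lognormal noise with unit mean and
    coefficient of variation ``truth.noise_cv``.
    """
    if probe_spacing <= 0:
        raise ValueError("probe_spacing must be positive")
    for o in annotation.origins:
        if o.id not in truth.amplitudes[genotype]:
            raise ValueError(f"no amplitude defined for origin {o.id}")
    rng = np.random.default_rng(seed)
    frames = []
    counter = 0
    for chrom, length in annotation.chromosomes:
        x = np.arange(0, length, probe_spacing, dtype=np.int64)
        if jitter_bp:
            x = x + rng.integers(-jitter_bp, jitter_bp + 1, size=len(x))
            x = np.unique(np.clip(x, 0, length - 1))
        keep = np.ones(len(x), dtype=bool)
        for s, e in annotation.masks_on(chrom):
            keep &= ~((x >= s) & (x < e))
        x = x[keep]
        ratio = expected_profile(x, chrom, annotation, truth, genotype)
        if truth.noise_cv > 0:
            s_ln = np.sqrt(np.log1p(truth.noise_cv**2))
            ratio = ratio * rng.lognormal(-0.5 * s_ln**2, s_ln, size=len(x))
        g1 = g1_level * rng.lognormal(-0.5 * 0.05**2, 0.05, size=len(x))
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": [f"P{counter + i:06d}" for i in range(len(x))],
                    "chrom": chrom,
                    "position": x,
                    "signal_S": ratio * g1,
                    "signal_G1": g1,
                }
            )
        )
        counter += len(x)
    table = pd.concat(frames, ignore_index=True)
    truth.true_areas.setdefault(
        genotype, true_peak_areas(annotation, truth, genotype)
    )
    return table


def true_peak_areas(
    annotation: GenomeAnnotation,
    truth: SimulationTruth,
    genotype: str,
    grid_step: int = GRID_STEP,
) -> dict[str, float]:
    """Analytic target areas: the peak-area walk on the noiseless grid profile.

    The expected ratio is evaluated exactly on the analysis grid (masked
    grid points omitted), the threshold is that profile's genome-wide mean,
    and the walk is run per origin. Masked origins get NaN.
    """
    grids: dict[str, ChromosomeProfile] = {}
    all_vals = []
    for chrom, length in annotation.chromosomes:
        g = np.arange(0, length, grid_step, dtype=np.int64)
        keep = np.ones(len(g), dtype=bool)
        for s, e in annotation.masks_on(chrom):
            keep &= ~((g >= s) & (g < e))
        g = g[keep]
        v = expected_profile(g, chrom, annotation, truth, genotype)
        grids[chrom] = ChromosomeProfile(chrom, g, v)
        all_vals.append(v)
    theta = float(np.concatenate(all_vals).mean())
    areas: dict[str, float] = {}
    for o in annotation.origins:
        rec = peak_area(
            grids[o.chrom],
            o.pos,
            theta,
            origin_id=o.id,
            masks=annotation.masks_on(o.chrom),
            grid_step=grid_step,
        )
        areas[o.id] = rec.area
    return areas


def simulate_enrichment_scenario(
    N: int,
    K: int,
    n_labeled: int,
    enriched: bool,
    seed: int | None = None,
    proximity_window: int = 10_000,
    enriched_overlap: int = 11,
    n_chromosomes: int = 16,
    chromosome_length: int = 750_000,
) -> tuple[GenomeAnnotation, set[str]]:
    """Build a genome with K proximal origins and a labeled subset of size n.

    Under ``enriched=False`` the labeled set is a uniform random subset of
    all origins (the permutation test's null); under ``enriched=True`` at
    least ``min(enriched_overlap, n_labeled)`` labeled origins are
    centromere-proximal, which requires K to be at least that large.
    """
    if n_labeled > N:
        raise ValueError("n_labeled cannot exceed N")
    rng = np.random.default_rng(seed)
    annotation = make_genome(
        n_chromosomes=n_chromosomes,
        chromosome_length=chromosome_length,
        n_origins=N,
        n_centromere_proximal=K,
        proximity_window=proximity_window,
        seed=int(rng.integers(2**31)),
    )
    ids = np.array(annotation.origin_ids)
    if enriched:
        target = min(enriched_overlap, n_labeled)
        if K < target:
            raise ValueError(
                f"enriched scenario needs at least {target} proximal origins, got K={K}"
            )
        proximal = np.array(proximal_origin_ids(annotation, proximity_window))
        rest = np.array(sorted(set(ids) - set(proximal)))
        chosen = list(rng.choice(proximal, size=target, replace=False))
        pool = np.array(sorted(set(ids) - set(chosen)))
        chosen += list(rng.choice(pool, size=n_labeled - target, replace=False))
        labeled = set(chosen)
    else:
        labeled = set(rng.choice(ids, size=n_labeled, replace=False))
    return annotation, labeled
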