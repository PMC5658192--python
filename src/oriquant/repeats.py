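"""Tandem-repeat copy-number accounting.

Bookkeeping around multi-copy DNA species in budding yeast — the rDNA
array on chromosome XII (9.1-kb unit, normally ~150 copies), the 2-micron
plasmid (6.3 kb, ~50 copies) and mitochondrial DNA — and the arithmetic
that connects copy-number changes to flow-cytometry genome-content shifts,
CHEF-gel chromosome sizes, predicted breakage-fragment sizes, Southern-blot
signal normalization, and serial-passage generation counts.

All sizes are carried in kb as real numbers; rounding (half away from zero)
happens only at presentation, and operations that the lab would read as a
rounded figure return the exact value alongside its rounded companion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import yaml

__all__ = [
    "RepeatLocus",
    "ChromosomeModel",
    "HybridizationMeasurement",
    "locus_size",
    "content_deficit",
    "chromosome_size",
    "breakage_fragments",
    "normalize_hybridization",
    "copies_from_retention",
    "generations_per_passage",
    "doubling_time_delta",
    "load_models",
    "RDNA_UNIT_KB",
    "TWO_MICRON_UNIT_KB",
    "MTDNA_KB",
    "GENOME_KB",
    "WT_RDNA_COPIES",
    "CHRXII_LEFT_ARM_KB",
    "CHRXII_RIGHT_ARM_KB",
]

RDNA_UNIT_KB = 9.1          #: one rDNA repeat unit
TWO_MICRON_UNIT_KB = 6.3    #: the 2-micron plasmid
MTDNA_KB = 85.0             #: mitochondrial genome
GENOME_KB = 13_000.0        #: haploid nuclear genome, ~13 Mb
WT_RDNA_COPIES = 150        #: typical wild-type rDNA copy number
#: Unique chromosome XII arm sizes flanking the rDNA array. Model inputs
#: mirroring the predicted breakage-fragment sizes, not derived from a
#: reference assembly.
CHRXII_LEFT_ARM_KB = 450.0
CHRXII_RIGHT_ARM_KB = 590.0


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class RepeatLocus:
    """A tandem array: repeat unit length (kb) and integer copy number."""

    name: str
    unit_kb: float
    copies: int

    def __post_init__(self) -> None:
        if self.unit_kb <= 0:
            raise ValueError("unit_kb must be positive")
        if self.copies < 0:
            raise ValueError("copies must be non-negative")

    @property
    def size_kb(self) -> float:
        return self.unit_kb * self.copies


@dataclass(frozen=True)
class ChromosomeModel:
    """A chromosome as unique left arm + embedded tandem array + unique right arm."""

    name: str
    left_arm_kb: float
    right_arm_kb: float
    locus: RepeatLocus

    def __post_init__(self) -> None:
        if self.left_arm_kb < 0 or self.right_arm_kb < 0:
            raise ValueError("arm sizes must be non-negative")

    @property
    def size_kb(self) -> float:
        return self.left_arm_kb + self.right_arm_kb + self.locus.size_kb


@dataclass(frozen=True)
class HybridizationMeasurement:
    """Blot signals for a repetitive target with single-copy (ACT1) controls."""

    target: float
    act1: float
    wt_target: float
    wt_act1: float

    def __post_init__(self) -> None:
        if min(self.target, self.act1, self.wt_target, self.wt_act1) <= 0:
            raise ValueError("all hybridization signals must be positive")


def locus_size(locus: RepeatLocus) -> float:
    """Array size in kb: unit length times copy number."""
    return locus.size_kb


class Deficit(NamedTuple):
    total_kb: float
    percent_of_genome: float


def content_deficit(
    changes: Iterable[tuple[float, float]], genome_kb: float = GENOME_KB
) -> Deficit:
    """Total genome content (kb and % of genome) tied up in copy-number changes.

    ``changes`` is a list of (delta_copies, unit_kb) pairs, e.g. the ~120
    lost rDNA copies at 9.1 kb plus ~40 lost 2-micron copies at 6.3 kb.
    """
    if genome_kb <= 0:
        raise ValueError("genome_kb must be positive")
    total = sum(dc * u for dc, u in changes)
    return Deficit(total, 100.0 * total / genome_kb)


def chromosome_size(model: ChromosomeModel) -> float:
    """Chromosome size in kb: both unique arms plus the embedded array."""
    return model.size_kb


def breakage_fragments(
    model: ChromosomeModel, retained_left_copies: int, retained_right_copies: int
) -> tuple[float, float]:
    """Fragment sizes (kb) if the chromosome breaks within the tandem array.

    Each fragment keeps its unique arm plus the repeat copies retained on
    its side; the copies between the retained flanks are lost with the
    break. Retained copies cannot exceed the array's copy number.
    """
    if retained_left_copies < 0 or retained_right_copies < 0:
        raise ValueError("retained copies must be non-negative")
    if retained_left_copies + retained_right_copies > model.locus.copies:
        raise ValueError("retained copies exceed the array's copy number")
    u = model.locus.unit_kb
    return (
        model.left_arm_kb + u * retained_left_copies,
        model.right_arm_kb + u * retained_right_copies,
    )


def normalize_hybridization(m: HybridizationMeasurement) -> float:
    """Retained fraction of a repetitive sequence relative to wild type.

    Signals are first normalized to the single-copy ACT1 control and then
    to the wild-type sample: (target/ACT1) / (wt_target/wt_ACT1).
    """
    return (m.target / m.act1) / (m.wt_target / m.wt_act1)


class Copies(NamedTuple):
    exact: float
    rounded: int


def copies_from_retention(fraction: float, wt_copies: float) -> Copies:
    """Copy number implied by a retained fraction of the wild-type array."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    exact = fraction * wt_copies
    return Copies(exact, _round_half_away(exact))


class Generations(NamedTuple):
    exact: float
    rounded: int


def generations_per_passage(dilution_factor: float) -> Generations:
    """Doublings needed to regrow a 1/dilution_factor inoculum to saturation."""
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must exceed 1")
    exact = math.log2(dilution_factor)
    return Generations(exact, _round_half_away(exact))


class DoublingDelta(NamedTuple):
    minutes: float
    percent: float


def doubling_time_delta(t_wt_min: float, t_mut_min: float) -> DoublingDelta:
    """Doubling-time difference in minutes and as percent of the wild type."""
    if t_wt_min <= 0 or t_mut_min <= 0:
        raise ValueError("doubling times must be positive")
    delta = t_mut_min - t_wt_min
    return DoublingDelta(delta, 100.0 * delta / t_wt_min)


def load_models(path: str | Path) -> dict:
    """Load repeat loci and chromosome models from a YAML file.

    Layout::

        loci:
          - {name: rDNA, unit_kb: 9.1, copies: 150}
        chromosomes:
          - {name: chrXII, left_arm_kb: 450, right_arm_kb: 590, locus: rDNA}

    Returns ``{"loci": {name: RepeatLocus}, "chromosomes": {name: ChromosomeModel}}``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    loci = {
        d["name"]: RepeatLocus(d["name"], float(d["unit_kb"]), int(d["copies"]))
        for d in raw.get("loci", [])
    }
    chromosomes = {}
    for d in raw.get("chromosomes", []):
        locus = loci[d["locus"]]
        chromosomes[d["name"]] = ChromosomeModel(
            d["name"], float(d["left_arm_kb"]), float(d["right_arm_kb"]), locus
        )
    return {"loci": loci, "chromosomes": chromosomes}
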