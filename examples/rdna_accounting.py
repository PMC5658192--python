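"""Copy-number accounting: where did ~1.3 Mb of genome content go?

A mutant whose flow-cytometry profile sits ~10% below the wild type on a
~13 Mb genome is missing ~1.3 Mb of DNA. The ledger below shows that losing
~120 rDNA repeats (9.1 kb each) plus ~40 copies of the 2-micron plasmid
(6.3 kb each) accounts for it, and what the residual rDNA array does to
chromosome XII's size and predicted breakage fragments.
"""

from oriquant.repeats import (
    CHRXII_LEFT_ARM_KB,
    CHRXII_RIGHT_ARM_KB,
    GENOME_KB,
    RDNA_UNIT_KB,
    TWO_MICRON_UNIT_KB,
    WT_RDNA_COPIES,
    ChromosomeModel,
    HybridizationMeasurement,
    RepeatLocus,
    breakage_fragments,
    chromosome_size,
    content_deficit,
    copies_from_retention,
    doubling_time_delta,
    generations_per_passage,
    locus_size,
    normalize_hybridization,
)

print(f"expected missing content at a 10% shift: {0.10 * GENOME_KB:.0f} kb")
rdna = content_deficit([(120, RDNA_UNIT_KB)])
two_micron = content_deficit([(40, TWO_MICRON_UNIT_KB)])
combined = content_deficit([(120, RDNA_UNIT_KB), (40, TWO_MICRON_UNIT_KB)])
print(f"120 rDNA copies x {RDNA_UNIT_KB} kb      = {rdna.total_kb:.0f} kb")
print(f"40 2-micron copies x {TWO_MICRON_UNIT_KB} kb  = {two_micron.total_kb:.0f} kb")
print(f"combined deficit: {combined.total_kb:.0f} kb "
      f"= {combined.percent_of_genome:.1f}% of the genome\n")

# a blot signal of 46 vs 200 (both against equal ACT1 controls) means 23%
# of the wild-type rDNA is retained: ~34.5 copies of the ~150-copy array
m = HybridizationMeasurement(target=46, act1=100, wt_target=200, wt_act1=100)
fraction = normalize_hybridization(m)
copies = copies_from_retention(fraction, WT_RDNA_COPIES)
print(f"blot retention fraction: {fraction:.2f} -> "
      f"{copies.exact:.1f} copies (~{copies.rounded})")

residual = RepeatLocus("rDNA", RDNA_UNIT_KB, 10)
chr12 = ChromosomeModel("chrXII", CHRXII_LEFT_ARM_KB, CHRXII_RIGHT_ARM_KB, residual)
print(f"\n10-copy residual array: {locus_size(residual):.0f} kb")
print(f"chromosome XII with it: {chromosome_size(chr12):.0f} kb (~1.13 Mb)")
left, right = breakage_fragments(chr12, 0, 0)
print(f"breakage at the array predicts fragments of {left:.0f} kb and {right:.0f} kb")

g = generations_per_passage(100)
d = doubling_time_delta(2.4 * 60, 2.7 * 60)
print(f"\none 1/100 passage = {g.exact:.2f} generations (~{g.rounded})")
print(f"doubling-time penalty 2.4 -> 2.7 hr: {d.minutes:.0f} min ({d.percent:.1f}%)")
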