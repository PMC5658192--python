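"""Simulate a two-genotype ssDNA origin-activity study and compare peak areas.

Two strains share most early origins, but 31 origins fire only in genotype
"wt" and 24 only in genotype "mut". We simulate each strain's S/G1 probe
table, Loess-smooth onto the 500-bp grid, run the peak-area walk per origin,
and compare: R² measures genome-wide concordance of origin usage, and the
classification counts how many origins are shared versus genotype-specific.
"""

import numpy as np

import oriquant as oq
from oriquant.compare import compare_peak_tables
from oriquant.simulate import SimulationTruth, simulate_probe_table

rng = np.random.default_rng(11)

annotation = oq.make_genome(
    n_chromosomes=16,
    chromosome_length=1_500_000,
    n_origins=213,
    n_centromere_proximal=16,
    proximity_window=10_000,
    seed=1,
    min_spacing=60_000,   # keep 5-kb-wide peak territories disjoint
    edge_margin=40_000,   # keep walks away from chromosome ends
)

ids = annotation.origin_ids
chosen = list(rng.choice(ids, 55, replace=False))
wt_only, mut_only = set(chosen[:31]), set(chosen[31:])
amps_wt, amps_mut = {}, {}
for i in ids:
    if i in wt_only:
        amps_wt[i], amps_mut[i] = rng.uniform(1.5, 3.0), 0.0
    elif i in mut_only:
        amps_wt[i], amps_mut[i] = 0.0, rng.uniform(1.5, 3.0)
    else:  # shared-active origin
        amps_wt[i], amps_mut[i] = rng.uniform(1.0, 3.0), rng.uniform(1.0, 3.0)

truth = SimulationTruth({"wt": amps_wt, "mut": amps_mut}, noise_cv=0.1)
peak_tables = {}
for genotype, seed in (("wt", 21), ("mut", 22)):
    probes = simulate_probe_table(annotation, truth, genotype, seed=seed)
    profiles = oq.loess_smooth(probes, chrom_lengths=annotation.chrom_lengths)
    table = oq.flag_overlaps(oq.call_all_origins(profiles, annotation, genotype))
    peak_tables[genotype] = table
    print(f"{genotype}: {len(probes)} probes, genome-mean threshold "
          f"θ = {profiles.threshold:.3f}")

result = compare_peak_tables(peak_tables["wt"], peak_tables["mut"])
print(f"\nR² of per-origin peak areas: {result.r_squared:.3f}")
print("  (low R² = discordant early-origin programs between the genotypes)")
print(f"classification at activity threshold {result.theta_act:.1f} "
      "(area of a flat at-threshold walk):")
for cls, count in result.class_counts.items():
    print(f"  {cls:20s} {count}")
print("\nThe genotype-specific counts recover the planted 31/24 split;")
print("'excluded' origins were flagged for overlap, masking or truncation.")
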