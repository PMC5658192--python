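# oriquant

Tools for quantifying early DNA-replication-origin activity from ssDNA
S/G1 microarray tracks in budding yeast, and for the genome bookkeeping
that follows when origin usage changes — rDNA tandem-repeat copy-number
accounting, centromere-proximity enrichment testing, and serial-passage
selective-sweep simulation.

## The problem

When S. cerevisiae cells are released into S phase in hydroxyurea (HU),
replication forks stall near the origins that fired, exposing
single-stranded DNA. Co-hybridizing an S-phase sample against a G1 control
on a tiling microarray gives a per-probe **S/G1 ratio** whose peaks mark
early, efficient origins. Comparing these profiles between genotypes — for
instance a wild-type strain and an ORC mutant — reveals reprogramming of
origin usage; and because initiation defects put pressure on large
origin-poor regions, they can drive dramatic copy-number changes in the
rDNA tandem array on chromosome XII, visible as whole-percent shifts in
genome content.

`oriquant` implements the analysis end of such a study as a reusable,
fully tested library:

1. **Peak-area statistic.** Probe ratios are Loess-smoothed onto a 500-bp
   grid (local linear regression, tricube weights, fixed bp window). With
   θ the genome-wide mean of the smoothed track, the activity of an origin
   at grid point *i₀* is the running sum of grid values walked outward from
   *i₀*, each side stopping after accumulating three values strictly below
   θ. Overlapping walk territories are flagged and excluded.
2. **Cross-genotype comparison.** Squared Pearson correlation (R²) of raw
   per-origin areas, plus a four-way classification (shared-active /
   specific to either genotype / inactive) against an activity threshold.
3. **Proximity enrichment.** A permutation test for whether a labeled
   origin subset lies unexpectedly close to centromeres, with the exact
   hypergeometric tail P(X ≥ x) = Σⱼ C(K,j)C(N−K,n−j)/C(N,n) as closed-form
   oracle.
4. **Copy-number accounting.** Locus size u·c, genome-content deficits
   Σ Δc·u, chromosome-size and breakage-fragment prediction, blot-signal
   normalization (target/ACT1 relative to wild type), and passage
   arithmetic (log₂ of the dilution factor per passage).
5. **Sweep simulation.** Two subpopulations with doubling times τ_fit and
   τ_unfit under fixed-fold serial batch expansion; the deterministic
   trajectory obeys f(t) = f₀2^(t/τ_fit) / (f₀2^(t/τ_fit) + (1−f₀)2^(t/τ_unfit)),
   with optional binomial bottleneck noise.
6. **Synthetic data.** A generator of genomes, probe tables and labeled
   origin sets with planted ground truth, so the whole pipeline is testable
   without any array download.

## Worked example

`python examples/quantify_origin_activity.py` simulates a 213-origin
two-genotype study in which 31 origins fire only in genotype 1 and 24 only
in genotype 2, runs the full pipeline on each strain, and prints:

```
wt: 80000 probes, genome-mean threshold θ = 1.198
mut: 80000 probes, genome-mean threshold θ = 1.190

R² of per-origin peak areas: 0.056
  (low R² = discordant early-origin programs between the genotypes)
classification at activity threshold 8.4 (area of a flat at-threshold walk):
  shared-active        158
  genotype1-specific   31
  genotype2-specific   24
  inactive             0
  excluded             0
```

The low R² reflects the planted discordance between the two origin
programs, and the classifier recovers the 31/24 genotype-specific split
exactly. The other examples cover the permutation test
(`centromere_enrichment.py`: 11 of 31 labeled origins proximal, zero
exceedances in 10,000 trials, p < 10⁻⁴, exact tail 2.9×10⁻⁷), the
copy-number ledger (`rdna_accounting.py`: 120×9.1 kb + 40×6.3 kb =
1344 kb ≈ 10.3% of a 13-Mb genome) and the sweep simulator
(`passage_sweep.py`).

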