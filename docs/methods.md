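# Methods

## Signal model and smoothing

The unit of analysis is the per-probe S/G1 fluorescence ratio from a
two-channel tiling array hybridized with an HU-arrested S-phase sample
against a G1 control. Ratios are formed per probe *before* smoothing
(probes with non-positive G1 signal are excluded with a warning), because
the downstream statistic is defined on the ratio track, not on the
channels.

Each chromosome is smoothed independently onto a fixed grid at 0, 500,
1000, … bp by degree-1 local regression: at grid point *g*, probes within
a window of half-width `span_bp` get tricube weights
(1 − (|x−g|/span)³)³ and a weighted straight line is fitted and evaluated
at *g*. Local linear fitting is exact on linear trends (so there is no
boundary bending toward the mean at chromosome ends) and reproduces
constants bitwise-nearly, which the tests assert. Where the weighted
design is degenerate (all probes at one coordinate) the fit falls back to
the weighted mean. The window is a fixed physical width, not a fraction of
the data, so probe-density fluctuations do not change the effective
bandwidth; this is why the smoother is implemented here rather than
delegated to a fraction-bandwidth Loess.

`span_bp` defaults to 3,000 (≈10 probes at the default 300-bp spacing):
wide enough to suppress probe-level noise, narrow relative to ~10-kb peak
widths so peak heights are attenuated by only a few percent. It is a
configuration knob, as is per-chromosome smoothing.

The threshold θ is the unweighted arithmetic mean of all unmasked grid
values across all chromosomes, computed per sample (never pooled across
genotypes). Its rationale is physical: most of the genome is
double-stranded and contributes only background, so the genome mean sits
just above background and below peaks.

Masked intervals — regions like the rDNA array whose repetitive content
makes the ratio uninterpretable — contribute no probes, no grid points, no
share of θ, and no area.

## The peak-area walk

For an origin at position *p*, the walk starts at the grid point nearest
*p* (an exact tie between two grid points goes to the lower coordinate —
a documented, deterministic convention) and proceeds outward one grid
point at a time, independently to the left and right. Every traversed
value is added to the area A; a side stops immediately after its count of
values strictly below θ reaches three. Values exactly equal to θ do not
count toward the stop rule (equality is measure-zero on real data; a
convention is still required and this one is tested). The origin's own
grid point is added exactly once and does not feed either side's counter —
on a track entirely below threshold the walk therefore spans exactly
7 grid points.

Two semantic choices are parameterized because reasonable readings differ:
the stop counter may be **cumulative** (default) or **consecutive**, and
below-threshold values may be **included** in (default) or excluded from
the sum. The defaults read the statistic as a running sum with a stop
condition; the alternatives are one keyword away and share all tests'
machinery.

Boundary handling: a walk reaching a chromosome end, or a gap in the grid
left by a masked interval, stops there with the partial area kept and a
`truncated` flag set; an origin *inside* a mask gets a `masked` flag and
no area. Truncation-at-mask mirrors truncation-at-end because in both
cases the territory is cut by missing data, not by the stop rule.
Downstream statistics exclude flagged records but the records are retained
in output for audit.

Overlap handling replaces manual curation: any two records on a chromosome
whose [left, right] walk territories share a grid point are both flagged
`overlapping`. This is deliberately conservative — no attempt is made to
deconvolve shared territory between adjacent early origins.

Useful invariants (all property-tested): A ≥ 0 on non-negative tracks;
adding a constant to both track and θ shifts A by exactly
constant × traversed-points while leaving the traversal unchanged (the
stop rule sees only value − θ); and the walk agrees exactly with an
independent brute-force walker on randomized tracks.

## Cross-genotype comparison

Peak tables computed against the same annotation are inner-joined on
origin id; a pair is comparable only if unflagged in both tables.
Concordance is the squared Pearson correlation of **raw** areas (the
scatter is read on linear axes; a log-scale option would be a one-line
change but is not the default). Classification uses one activity threshold
θ_act on both axes: specific to genotype 1 iff A₁ ≥ θ_act > A₂, and
symmetrically; shared-active if both pass; inactive if neither.

θ_act defaults to θ × 7, the area a flat exactly-at-threshold track would
produce over the minimal walk: dimensionally an area, and reducing to
"above background" in the flat limit. Because the two samples have their
own θ, the default uses the mean of the two thresholds. The choice is
exposed; on well-separated synthetic data classification is insensitive to
it across a wide range.

## Proximity enrichment

Distance is to the origin's own chromosome's centromere, and "within
*w*" is inclusive (≤ *w*). The permutation test draws n origin labels
uniformly without replacement from the N-origin universe (optionally
restricted to the comparable, unflagged set) T times, counting trials
whose proximal count reaches the observed x_obs. The empirical p is k/T;
when k = 0 the result carries the resolution bound 1/T — reported in the
"p < 1/T" style — and the conservative (k+1)/(T+1) companion is always
available. Under uniform labeling the proximal count is exactly
hypergeometric, so `hypergeom_tail` (scipy's stable implementation) acts
as a closed-form oracle; the suite checks agreement within four binomial
standard errors at T = 50,000 across a parameter grid.

## Copy-number accounting

Pure arithmetic made explicit and unit-checked: locus size u·c (kb);
content deficit Σ Δc·u and its percent of a supplied genome size
(13 Mb default); chromosome size as left arm + array + right arm;
breakage fragments as each arm plus its retained repeat copies, with mass
conservation (fragments + lost repeats = whole chromosome) property-tested
over all valid splits. The chromosome XII arm sizes (450/590 kb) are model
inputs, not derived from a reference assembly, keeping the module
download-free. Blot normalization is (target/ACT1)/(wt_target/wt_ACT1);
copy numbers inferred from retention fractions are reported unrounded with
a rounded companion (half away from zero). Passage arithmetic counts
log₂(dilution factor) generations per passage (~6.64, i.e. ~7, for 1/100).

## Sweep simulation

Serial batch passaging is modeled as fixed fold-expansion E per passage
(only the dilution factor is observable; saturation is not modeled
logistically). Within a passage both types grow exponentially at ln2/τ;
the passage's wall time solves f·2^(t/τ_fit) + (1−f)·2^(t/τ_unfit) = E by
Brent root-finding on the log-scale residual (bracketed between the two
single-type times, relative tolerance 1e-14). Generations are log₂ of
cumulative expansion, so each passage contributes exactly log₂E. Because
batch growth is piecewise the continuous two-type process, the
deterministic trajectory must equal the closed-form frequency at every
passage boundary; the suite requires agreement to 1e-8. An optional
bottleneck samples Binomial(B, f)/B founders at each dilution from the
seeded generator; at B = 10⁶ the stochastic trajectory stays within 0.01
of the deterministic one. Fixation (f ≥ 0.99 by default) is linearly
interpolated in (generations, frequency) between passage boundaries.

The fitness parameters of a sweeping clone are free inputs: the simulator
is used for qualitative back-inference (what doubling-time gap fixes a
rare variant within ~N generations), not to reproduce any particular
culture's timeline.

## Synthetic data: what it emulates, and what it does not

The generator emulates: ~40k probes at 300-bp spacing with ±50-bp jitter
over 16 chromosomes; Gaussian expected peaks (σ = 5 kb by default,
configurable — HU-stalled forks travel only a few kb, and no functional
form is observable at this resolution, so a smooth unimodal shape is the
natural stand-in); genotype-dependent per-origin amplitudes over a
baseline of 1; multiplicative lognormal ratio noise with unit mean
(two-channel ratios are strictly positive with roughly constant CV;
default CV 0.1 as a plausible array-noise stand-in, a configuration value
rather than an inferred fact); and masked intervals which simply produce
no probes.

It does **not** emulate dye bias, spatial array artifacts, background
subtraction, replicate structure, or the time course (only a single
snapshot); passing tests therefore demonstrate correctness of the
algorithms under the stated generative model, not robustness to real
array pathology.

Ground-truth areas are defined as what the peak-area walk returns on the
*noiseless expected* profile evaluated exactly on the analysis grid, with
that profile's own genome mean as threshold. This definition makes the two
key recovery properties exact and testable: the full noiseless pipeline
recovers each origin's true area within 5% (grid discretization plus
smoothing attenuation only), and doubling all amplitudes exactly doubles
the above-baseline part of every true area, because amplitude scaling
preserves the sign of value − θ everywhere and hence the traversal.

Genome construction places origins on a lattice: proximal origins at
centromere ± w (inclusive boundary), distal candidates starting at
centromere ± (s + w) in steps of the spacing s = max(min_spacing, 2w), so
proximity statuses are unambiguous by construction and the requested
proximal count is exact. `min_spacing` and `edge_margin` exist because
wide peaks near each other or near chromosome ends legitimately trigger
overlap/truncation flags — the honest behavior of the method, and exactly
what manual curation dealt with on real arrays; planted-truth recovery
tests use spacing 60 kb and margin 40 kb so that no flags fire and
classification can be checked exactly. Study-scale defaults (16
chromosomes, 213 origins, 16 proximal, 10-kb window) mirror the motivating
study's counts.

## Problem sizes

The test suite and the acceptance script run at the study's own scales:
213-origin genomes, ~40–80k probes per simulated strain, 10,000-trial
permutation tests (50,000 for the oracle-agreement grid). These are
seconds-scale workloads on one CPU.

## Known limitations

- The smoother evaluates only at grid points; sub-grid peak positions are
  resolved to the nearest 500 bp.
- Overlap flagging excludes both members of a pair; no deconvolution.
- The activity classification has no per-origin significance test — the
  assay provides no replicate variance to base one on.
- The sweep model has exactly two types and no mutational influx of new
  array lengths.
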