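import numpy as np
import pytest

import oriquant as oq
from oriquant.profiles import ChromosomeProfile, SmoothedProfileSet
from oriquant.simulate import SimulationTruth, simulate_probe_table


def flat_profile(chrom="chr01", n=101, value=1.0, step=500):
    pos = np.arange(n, dtype=np.int64) * step
    return ChromosomeProfile(chrom, pos, np.full(n, float(value)))


@pytest.fixture
def small_annotation():
    """Two short chromosomes, three well-separated origins, one mask."""
    return oq.GenomeAnnotation(
        chromosomes=[("chrA", 200_000), ("chrB", 150_000)],
        centromeres={"chrA": 100_000, "chrB": 60_000},
        origins=[
            oq.Origin("ori1", "chrA", 40_000),
            oq.Origin("ori2", "chrA", 160_000),
            oq.Origin("ori3", "chrB", 30_000),
        ],
        masked_intervals=[("chrB", 100_000, 120_000)],
    )


def planted_two_genotype_study(
    n_wt_specific=31,
    n_mut_specific=24,
    noise_cv=0.0,
    seed=11,
):
    """A 213-origin two-genotype study with planted genotype-specific origins.

    Origins are spaced widely enough (and kept off chromosome ends) that no
    peak territories overlap or truncate, so classification can be checked
    against the planted truth exactly.
    """
    rng = np.random.default_rng(seed)
    ann = oq.make_genome(
        n_chromosomes=16,
        chromosome_length=1_500_000,
        n_origins=213,
        n_centromere_proximal=16,
        proximity_window=10_000,
        seed=int(rng.integers(2**31)),
        min_spacing=60_000,
        edge_margin=40_000,
    )
    ids = ann.origin_ids
    chosen = list(rng.choice(ids, n_wt_specific + n_mut_specific, replace=False))
    wt_only = set(chosen[:n_wt_specific])
    mut_only = set(chosen[n_wt_specific:])
    amps_wt, amps_mut = {}, {}
    for i in ids:
        if i in wt_only:
            amps_wt[i], amps_mut[i] = rng.uniform(1.5, 3.0), 0.0
        elif i in mut_only:
            amps_wt[i], amps_mut[i] = 0.0, rng.uniform(1.5, 3.0)
        else:
            amps_wt[i] = rng.uniform(1.0, 3.0)
            amps_mut[i] = rng.uniform(1.0, 3.0)
    truth = SimulationTruth({"wt": amps_wt, "mut": amps_mut}, noise_cv=noise_cv)
    table_wt = simulate_probe_table(ann, truth, "wt", seed=int(rng.integers(2**31)))
    table_mut = simulate_probe_table(ann, truth, "mut", seed=int(rng.integers(2**31)))
    return ann, truth, wt_only, mut_only, table_wt, table_mut


@pytest.fixture(scope="session")
def planted_study():
    return planted_two_genotype_study()


def run_pipeline(ann, probe_table, genotype):
    profiles = oq.loess_smooth(probe_table, chrom_lengths=ann.chrom_lengths)
    return oq.flag_overlaps(oq.call_all_origins(profiles, ann, genotype))
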