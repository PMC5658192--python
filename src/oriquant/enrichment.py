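"""Centromere-proximity permutation test with a hypergeometric oracle.

Given a set of origins singled out by some comparison (e.g. origins whose
early firing is specific to one genotype), the test asks whether they sit
closer to centromeres than a random draw of the same size would. Labels are
permuted uniformly without replacement over the origin universe; the
empirical p-value is the fraction of trials whose proximal count reaches
the observed one. Because uniform labeling without replacement makes the
proximal count hypergeometric, the exact tail probability serves as a
closed-form cross-check of the permutation machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .genome import GenomeAnnotation, Origin

__all__ = [
    "EnrichmentTask",
    "EnrichmentResult",
    "nearest_centromere_distance",
    "count_proximal",
    "proximal_origin_ids",
    "permutation_test",
    "hypergeom_tail",
]


@dataclass(frozen=True)
class EnrichmentTask:
    """Parameters of one proximity-enrichment question.

    N origins in the universe, of which K are within ``window`` bp of a
    centromere; n labeled origins, of which ``x_obs`` are proximal;
    T permutation trials.
    """

    N: int
    n: int
    K: int
    x_obs: int
    window: int
    trials: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.x_obs <= min(self.n, self.K)):
            raise ValueError("x_obs must lie in [0, min(n, K)]")
        if self.n > self.N or self.K > self.N:
            raise ValueError("n and K cannot exceed N")
        if self.trials < 1 or self.window <= 0:
            raise ValueError("trials >= 1 and window > 0 required")


@dataclass
class EnrichmentResult:
    """Permutation-test outcome.

    ``p_empirical`` is k/T; when no trial reaches the observed count the
    result additionally reports the resolution bound 1/T (the style
    "p < 1/T"). ``p_corrected`` is the conservative (k+1)/(T+1) companion.
    ``histogram[j]`` counts trials with proximal count exactly j.
    """

    task: EnrichmentTask
    exceedances: int
    histogram: np.ndarray

    @property
    def p_empirical(self) -> float:
        return self.exceedances / self.task.trials

    @property
    def p_bound(self) -> float | None:
        """Upper bound 1/T reported when no exceedance was seen."""
        return 1.0 / self.task.trials if self.exceedances == 0 else None

    @property
    def p_corrected(self) -> float:
        return (self.exceedances + 1) / (self.task.trials + 1)

    def summary(self) -> str:
        t = self.task
        p = f"p < {self.p_bound:g}" if self.p_bound is not None else f"p = {self.p_empirical:g}"
        return (
            f"{t.x_obs}/{t.n} labeled origins within {t.window} bp of a "
            f"centromere (universe {t.N}, {t.K} proximal); "
            f"{self.exceedances}/{t.trials} trials reached {t.x_obs}: {p}"
        )


def nearest_centromere_distance(origin: Origin, annotation: GenomeAnnotation) -> int:
    """Absolute distance (bp) from an origin to its chromosome's centromere."""
    if origin.chrom not in annotation.centromeres:
        raise ValueError(f"chromosome {origin.chrom} has no centromere")
    return abs(origin.pos - annotation.centromeres[origin.chrom])


def count_proximal(
    origin_ids: Iterable[str], annotation: GenomeAnnotation, window: int
) -> int:
    """Number of the given origins within ``window`` bp (inclusive) of a centromere."""
    by_id = annotation.origins_by_id()
    ids = list(origin_ids)
    unknown = [i for i in ids if i not in by_id]
    if unknown:
        raise ValueError(f"unknown origin ids: {unknown}")
    return sum(
        nearest_centromere_distance(by_id[i], annotation) <= window for i in ids
    )


def proximal_origin_ids(annotation: GenomeAnnotation, window: int) -> list[str]:
    """Ids of all annotated origins within ``window`` bp of a centromere."""
    return [
        o.id
        for o in annotation.origins
        if nearest_centromere_distance(o, annotation) <= window
    ]


def permutation_test(
    annotation: GenomeAnnotation,
    labeled_ids: Sequence[str],
    window: int = 10_000,
    trials: int = 10_000,
    seed: int | None = None,
    x_obs: int | None = None,
    universe_ids: Sequence[str] | None = None,
) -> EnrichmentResult:
    """Permutation test for centromere proximity of a labeled origin set.

    Each trial draws ``len(labeled_ids)`` origins uniformly without
    replacement from the universe (all annotated origins by default;
    restrict with ``universe_ids`` to mirror exclusion of flagged origins)
    and counts how many fall within ``window`` bp of a centromere. The
    exceedance count k is the number of trials reaching the observed count
    ``x_obs`` (computed from the labeled set if not given).
    """
    universe = list(universe_ids) if universe_ids is not None else annotation.origin_ids
    universe_set = set(universe)
    missing = [i for i in labeled_ids if i not in universe_set]
    if missing:
        raise ValueError(f"labeled ids outside the universe: {missing}")
    n = len(labeled_ids)
    if x_obs is None:
        x_obs = count_proximal(labeled_ids, annotation, window)
    by_id = annotation.origins_by_id()
    proximal = np.array(
        [nearest_centromere_distance(by_id[i], annotation) <= window for i in universe]
    )
    N = len(universe)
    K = int(proximal.sum())
    task = EnrichmentTask(N, n, K, x_obs, window, trials, seed)

    rng = np.random.default_rng(seed)
    histogram = np.zeros(n + 1, dtype=np.int64)
    if n == 0:
        histogram[0] = trials
        return EnrichmentResult(task, int(histogram[x_obs:].sum()), histogram)
    chunk = 20_000
    done = 0
    while done < trials:
        t = min(chunk, trials - done)
        # uniform without-replacement subsets: n smallest of N random keys
        keys = rng.random((t, N))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        counts = proximal[idx].sum(axis=1)
        histogram += np.bincount(counts, minlength=n + 1)
        done += t
    exceedances = int(histogram[x_obs:].sum())
    return EnrichmentResult(task, exceedances, histogram)


def hypergeom_tail(N: int, K: int, n: int, x: int) -> float:
    """Exact tail P(X >= x) for X ~ Hypergeometric(N, K, n).

    Closed-form null of the proximal count under uniform labeling without
    replacement; zero above min(n, K), one at or below zero.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K, n <= N")
    if x <= 0:
        return 1.0
    if x > min(n, K):
        return 0.0
    return float(stats.hypergeom.sf(x - 1, N, K, n))
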