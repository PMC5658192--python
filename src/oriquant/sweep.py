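"""Serial-passage selective-sweep simulator with a closed-form oracle.

Models a batch-passaged culture containing two subpopulations that differ
only in doubling time — e.g. cells carrying a contracted rDNA array with a
growth advantage over the ancestral long-array cells. Each passage, the
culture expands by a fixed factor E (the reciprocal of the dilution, e.g.
100-fold for a 1/100 dilution grown back to saturation) with both types
growing exponentially; generations are counted as log2 of the cumulative
expansion, so one 100-fold passage contributes log2(100) ~ 6.6 generations.

Because batch growth is piecewise the continuous two-type exponential
process, the deterministic simulator must agree at passage boundaries with
the closed form

    f(t) = f0 2^(t/tau_fit) / (f0 2^(t/tau_fit) + (1 - f0) 2^(t/tau_unfit)),

i.e. the odds of the fit type multiply by 2^(t (1/tau_fit - 1/tau_unfit)).
An optional finite bottleneck adds binomial founder sampling at each
dilution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SweepParams",
    "SweepTrajectory",
    "simulate_passages",
    "closed_form_frequency",
    "fixation_generation",
]


@dataclass(frozen=True)
class SweepParams:
    """Two-type serial-passage competition parameters.

    f0: initial frequency of the fit (shorter doubling time) type;
    tau_fit / tau_unfit: doubling times in minutes; expansion: fold-growth
    per passage (dilution factor); bottleneck: number of founder cells
    sampled at each dilution (None = deterministic, infinite-population).
    """

    f0: float
    tau_fit: float
    tau_unfit: float
    expansion: float = 100.0
    n_passages: int = 10
    bottleneck: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.f0 < 1.0:
            raise ValueError("f0 must lie strictly inside (0, 1)")
        if self.tau_fit <= 0 or self.tau_unfit <= 0:
            raise ValueError("doubling times must be positive")
        if self.expansion <= 1:
            raise ValueError("expansion factor must exceed 1")
        if self.n_passages < 1:
            raise ValueError("need at least one passage")
        if self.bottleneck is not None and self.bottleneck < 1:
            raise ValueError("bottleneck must be a positive founder count")


@dataclass
class SweepTrajectory:
    """Frequency of the fit type at each passage boundary.

    Index 0 is the initial culture: generations[0] = 0, frequency[0] = f0.
    ``wall_times`` holds cumulative growth time in minutes.
    """

    params: SweepParams
    generations: np.ndarray
    frequencies: np.ndarray
    wall_times: np.ndarray = field(default=None)  # type: ignore[assignment]


def _passage_time(f: float, p: SweepParams) -> float:
    """Wall time for one passage: solves f 2^(t/tf) + (1-f) 2^(t/tu) = E."""
    tf, tu, E = p.tau_fit, p.tau_unfit, p.expansion
    target = math.log2(E)
    lo = min(tf, tu) * target
    hi = max(tf, tu) * target
    if hi - lo < 1e-12 * hi:  # equal doubling times: exact
        return tf * target

    def g(t: float) -> float:
        return math.log2(f * 2 ** (t / tf) + (1 - f) * 2 ** (t / tu)) - target

    return brentq(g, lo, hi, rtol=1e-14, maxiter=200)


def simulate_passages(params: SweepParams) -> SweepTrajectory:
    """Run the serial-passage competition.

    Within each passage both types grow exponentially at rate ln2/tau; the
    passage's wall time is root-found so that the total expansion equals
    the dilution factor exactly, then frequencies are updated from the two
    types' expansions. With a finite ``bottleneck`` B, each dilution
    samples Binomial(B, f)/B founders using the seeded generator;
    otherwise the trajectory is deterministic.
    """
    rng = np.random.default_rng(params.seed) if params.bottleneck else None
    log2E = math.log2(params.expansion)
    f = params.f0
    freqs = [f]
    gens = [0.0]
    times = [0.0]
    for _ in range(params.n_passages):
        dt = _passage_time(f, params)
        grown_fit = f * 2 ** (dt / params.tau_fit)
        f = grown_fit / params.expansion
        f = min(max(f, 0.0), 1.0)
        if rng is not None:
            f = rng.binomial(params.bottleneck, f) / params.bottleneck
        freqs.append(f)
        gens.append(gens[-1] + log2E)
        times.append(times[-1] + dt)
    return SweepTrajectory(
        params,
        np.array(gens),
        np.array(freqs),
        np.array(times),
    )


def closed_form_frequency(params: SweepParams, t: float) -> float:
    """Fit-type frequency after continuous competitive growth for t minutes."""
    lf = t / params.tau_fit
    lu = t / params.tau_unfit
    # factor out the larger exponent for stability at long times
    m = max(lf, lu)
    num = params.f0 * 2 ** (lf - m)
    den = num + (1 - params.f0) * 2 ** (lu - m)
    return num / den


def fixation_generation(
    trajectory: SweepTrajectory, threshold: float = 0.99
) -> float | None:
    """First generation count at which the fit type reaches ``threshold``.

    Linearly interpolated between passage boundaries; ``None`` if the
    trajectory never reaches the threshold.
    """
    g = trajectory.generations
    f = trajectory.frequencies
    if f[0] >= threshold:
        return 0.0
    above = np.flatnonzero(f >= threshold)
    if len(above) == 0:
        return None
    i = int(above[0])
    frac = (threshold - f[i - 1]) / (f[i] - f[i - 1])
    return float(g[i - 1] + frac * (g[i] - g[i - 1]))
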