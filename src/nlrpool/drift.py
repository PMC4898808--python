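"""Heterozygosity decay under partial selfing and serial small-population
regeneration, and its inversion to initial heterozygosity.

The model describes a germplasm-bank propagation history: a founder step
(one selfing generation from a single plant, or a cross among founders
with selfing rate ``s``) followed by rounds of random mating in a small
population of N diploid plants (2N chromosomes).  Heterozygosity H — the
probability that two alleles sampled from the population differ — loses
a factor 0.5 (single founder) or (1 − 0.5·s) in the founder step and a
factor (1 − 1/2N) in every subsequent round:

    H_1 = f · H_0,        f = 0.5 or (1 − 0.5·s)
    H_{t+1} = (1 − 1/2N) · H_t

Given the observed proportion of polymorphic loci at sampling time and a
propagation scenario, the recursion inverts to the initial
heterozygosity H_0.  ``t_total`` counts the founder step as the first of
the total rounds of multiplication, so ``t_total`` rounds comprise the
founder step plus ``t_total − 1`` random-mating rounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "PropagationScenario",
    "founder_factor",
    "decay",
    "invert_H0",
    "InversionResult",
    "simulate_propagation",
    "PropagationSimResult",
]


@dataclass(frozen=True)
class PropagationScenario:
    """Parameters of a selfing/bottleneck propagation history.

    H0 and H_sample are proportions of polymorphic loci in [0, 1]; ``s``
    is the selfing rate; ``N`` the number of plants regenerated per
    round (2N chromosomes); ``t_total`` the total rounds of
    multiplication including the founder step.
    """

    H0: float | None = None
    s: float = 1.0
    single_plant: bool = False
    N: int = 12
    t_total: int = 10
    H_sample: float | None = None

    def __post_init__(self) -> None:
        for name in ("H0", "H_sample"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"selfing rate must lie in [0, 1], got {self.s}")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.t_total < 1:
            raise ValueError("t_total must be >= 1")

    @property
    def two_N(self) -> int:
        return 2 * self.N

    @property
    def final_heterozygosity(self) -> float:
        """Expected heterozygosity at sampling time given H0."""
        if self.H0 is None:
            raise ValueError("scenario has no H0")
        f = founder_factor(self.s, self.single_plant)
        return decay(f * self.H0, self.two_N, self.t_total - 1)


def founder_factor(s: float, single_plant: bool = False) -> float:
    """Heterozygosity retained through the founder generation.

    A single selfed founder halves heterozygosity; a cross among several
    founders with selfing rate ``s`` loses the proportion 0.5·s.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"selfing rate must lie in [0, 1], got {s}")
    if single_plant:
        return 0.5
    return 1.0 - 0.5 * s


def decay(H: float, two_N: int, g: int) -> float:
    """Expected heterozygosity after ``g`` rounds of random mating among
    ``two_N`` chromosomes: H · (1 − 1/2N)^g."""
    if not 0.0 <= H <= 1.0:
        raise ValueError(f"H must lie in [0, 1], got {H}")
    if two_N < 2:
        raise ValueError(f"two_N must be >= 2, got {two_N}")
    if g < 0:
        raise ValueError("g must be >= 0")
    return H * (1.0 - 1.0 / two_N) ** g


class InversionResult(NamedTuple):
    H0: float
    feasible: bool  # False when the implied H0 exceeds 1


def invert_H0(
    H_sample: float,
    s: float = 1.0,
    single_plant: bool = False,
    two_N: int = 24,
    t_total: int = 10,
) -> InversionResult:
    """Initial heterozygosity implied by the observed proportion of
    polymorphic loci.

    Inverts H_sample = f · (1 − 1/2N)^(t_total − 1) · H0, the founder
    step being the first of ``t_total`` rounds of multiplication.  An
    implied H0 above one is returned with ``feasible=False``: no initial
    population could have produced the observation under the scenario.
    """
    if H_sample <= 0.0 or H_sample > 1.0:
        raise ValueError(f"H_sample must lie in (0, 1], got {H_sample}")
    if t_total < 1:
        raise ValueError("t_total must be >= 1")
    f = founder_factor(s, single_plant)
    denom = f * (1.0 - 1.0 / two_N) ** (t_total - 1)
    if two_N < 2:
        raise ValueError(f"two_N must be >= 2, got {two_N}")
    h0 = H_sample / denom
    return InversionResult(H0=h0, feasible=h0 <= 1.0)


class PropagationSimResult(NamedTuple):
    mean_heterozygosity: float
    per_replicate: np.ndarray
    per_generation_mean: np.ndarray  # index g: after founder + g WF rounds


def simulate_propagation(
    H0: float,
    s: float = 1.0,
    single_plant: bool = False,
    N: int = 12,
    t_total: int = 10,
    n_loci: int = 220,
    n_replicates: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> PropagationSimResult:
    """Monte-Carlo forward simulation of the propagation history.

    Each locus is polymorphic at founding with probability 2·H0, with
    founder allele frequency p = 1/2, so that the expected heterozygosity
    2p(1 − p) equals H0 at the start.  The founder step is applied as a
    deterministic multiplication of expected heterozygosity by the
    founder factor (the model's founder generation is an expectation
    recursion, not a mating event), followed by ``t_total − 1``
    Binomial(2N, p) Wright–Fisher resamplings.  Returns the mean of
    f · 2p(1 − p) across loci, per replicate and overall, together with
    the per-generation trajectory of the mean.
    """
    if not 0.0 <= H0 <= 0.5:
        raise ValueError(
            "simulate_propagation requires H0 in [0, 0.5] "
            "(founding polymorphism probability is 2*H0)"
        )
    if n_loci < 1 or n_replicates < 1:
        raise ValueError("n_loci and n_replicates must be >= 1")
    if N < 1 or t_total < 1:
        raise ValueError("N and t_total must be >= 1")
    rng = np.random.default_rng(rng)
    f = founder_factor(s, single_plant)
    two_N = 2 * N

    poly = rng.random((n_replicates, n_loci)) < 2.0 * H0
    p = np.where(poly, 0.5, 0.0)
    het_by_gen = [f * np.mean(2.0 * p * (1.0 - p))]
    for _ in range(t_total - 1):
        p = rng.binomial(two_N, p) / two_N
        het_by_gen.append(f * np.mean(2.0 * p * (1.0 - p)))
    per_rep = f * np.mean(2.0 * p * (1.0 - p), axis=1)
    return PropagationSimResult(
        mean_heterozygosity=float(per_rep.mean()),
        per_replicate=per_rep,
        per_generation_mean=np.asarray(het_by_gen),
    )
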