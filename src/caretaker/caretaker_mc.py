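"""Monte-Carlo model of random mutation accumulation in a diploid genome.

The genome has G genes (2G alleles), H of which are haploinsufficient
(hRPG).  Mutations hit alleles uniformly at random with replacement; a
repeat hit on an already-mutated allele is a no-op.  The *race* asks which
comes first: the first hit on any hRPG allele (heterozygosity, which is
phenotypically visible and triggers elimination), or the second-allele hit
on some non-hRPG gene (silent homozygous disruption).

An exact backward recursion over the number of heterozygous non-hRPG genes
serves as the oracle for the simulation.  No-op repeat hits cancel from the
numerator and denominator of each transition, so the race probability is
identical with or without them.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
from scipy.stats import binomtest

from .errors import ConfigError, EstimateError

__all__ = [
    "Event",
    "MCConfig",
    "MCOutcome",
    "RaceEstimate",
    "BoundedRaceEstimate",
    "DisturbedDistribution",
    "simulate_race",
    "race_probability_exact",
    "race_probability_mc",
    "race_probability_bounded",
    "disturbed_count_distribution",
    "EXACT_ENUMERATION_LIMIT",
]

EXACT_ENUMERATION_LIMIT = 1_000_000


class Event(str, Enum):
    HRPG_HET_FIRST = "HRPG_HET_FIRST"
    HOMOZYGOUS_FIRST = "HOMOZYGOUS_FIRST"
    UNRESOLVED = "UNRESOLVED"


@dataclass(frozen=True)
class MCConfig:
    G: int
    H: int
    reps: int
    seed: int = 0
    M: int | None = None  # mutation budget; None = run to absorption

    def __post_init__(self) -> None:
        _validate_gh(self.G, self.H)
        if self.reps < 1:
            raise ConfigError(f"reps must be >= 1, got {self.reps}")
        if self.M is not None and self.M < 1:
            raise ConfigError(f"M must be >= 1 when given, got {self.M}")


@dataclass(frozen=True)
class MCOutcome:
    event: Event
    mutations_used: int


@dataclass(frozen=True)
class RaceEstimate:
    p_hat: float
    ci_low: float
    ci_high: float
    reps: int
    exact_p: float | None = None
    n_unresolved: int = 0


@dataclass(frozen=True)
class BoundedRaceEstimate:
    p_hrpg_first: float
    p_homozygous_first: float
    p_unresolved: float
    reps: int
    M: int
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class DisturbedDistribution:
    """Distribution of the number of genes with both alleles hit after M hits."""

    M: int
    probs: Mapping[int, float]
    method: str = "mc"

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"probabilities sum to {total}, expected 1")

    def mean(self) -> float:
        return sum(j * p for j, p in self.probs.items())


def _validate_gh(G: int, H: int) -> None:
    if G < 1:
        raise ConfigError(f"G must be >= 1, got {G}")
    if not 0 <= H <= G:
        raise ConfigError(f"need 0 <= H <= G, got H={H}, G={G}")


def simulate_race(
    G: int, H: int, rng: np.random.Generator, budget: int | None = None
) -> MCOutcome:
    """One trajectory of the mutation race (scalar reference implementation).

    Draws alleles uniformly with replacement from the 2G alleles until an
    hRPG allele is hit (HRPG_HET_FIRST), a non-hRPG gene collects hits on
    both alleles (HOMOZYGOUS_FIRST), or the budget runs out (UNRESOLVED).
    """
    _validate_gh(G, H)
    hit: set[int] = set()  # non-hRPG allele indices already mutated
    draws = 0
    while budget is None or draws < budget:
        draws += 1
        allele = int(rng.integers(0, 2 * G))
        if allele < 2 * H:
            return MCOutcome(Event.HRPG_HET_FIRST, draws)
        partner = allele ^ 1
        if partner in hit:
            return MCOutcome(Event.HOMOZYGOUS_FIRST, draws)
        hit.add(allele)
    return MCOutcome(Event.UNRESOLVED, draws)


def _simulate_races_vectorized(
    G: int, H: int, reps: int, rng: np.random.Generator, budget: int | None
) -> np.ndarray:
    """Batched race simulation; returns an array of Event codes (0/1/2).

    State per replicate is a bitmask over the 2(G-H) non-hRPG alleles, so
    this path requires 2(G-H) <= 63.  Distributionally identical to
    :func:`simulate_race`.
    """
    events = np.full(reps, 2, dtype=np.int8)  # 2 = UNRESOLVED
    masks = np.zeros(reps, dtype=np.uint64)
    active = np.arange(reps)
    step = 0
    while active.size and (budget is None or step < budget):
        step += 1
        draws = rng.integers(0, 2 * G, size=active.size)
        is_hrpg = draws < 2 * H
        events[active[is_hrpg]] = 0  # HRPG_HET_FIRST
        rest = active[~is_hrpg]
        if rest.size == 0:
            active = rest
            continue
        alleles = (draws[~is_hrpg] - 2 * H).astype(np.uint64)
        bit = np.uint64(1) << alleles
        partner = np.uint64(1) << (alleles ^ np.uint64(1))
        homo = (masks[rest] & partner) != 0
        events[rest[homo]] = 1  # HOMOZYGOUS_FIRST
        cont = rest[~homo]
        masks[cont] |= bit[~homo]
        active = cont
    return events


def _count_events(
    G: int, H: int, reps: int, seed: int, budget: int | None
) -> tuple[int, int, int]:
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if 2 * (G - H) <= 63:
        events = _simulate_races_vectorized(G, H, reps, rng, budget)
        wins = int(np.sum(events == 0))
        losses = int(np.sum(events == 1))
    else:
        wins = losses = 0
        for _ in range(reps):
            out = simulate_race(G, H, rng, budget)
            if out.event is Event.HRPG_HET_FIRST:
                wins += 1
            elif out.event is Event.HOMOZYGOUS_FIRST:
                losses += 1
    return wins, losses, reps - wins - losses


def _wilson_ci(k: int, n: int) -> tuple[float, float]:
    ci = binomtest(k, n).proportion_ci(confidence_level=0.95, method="wilson")
    return float(ci.low), float(ci.high)


def race_probability_exact(G: int, H: int) -> float:
    """Exact P(HRPG_HET_FIRST) by backward recursion.

    With k non-hRPG genes currently heterozygous, the next *effective* hit
    is an hRPG allele (2H ways, win), the partner of a heterozygous gene
    (k ways, loss) or a fresh non-hRPG gene (2(G-H-k) ways):

        P(k) = [2H + 2(G-H-k) P(k+1)] / [2H + k + 2(G-H-k)],
        P(G-H) = 2H / (2H + G - H).
    """
    _validate_gh(G, H)
    if H == 0:
        return 0.0
    n = G - H
    p = 2.0 * H / (2.0 * H + n)  # boundary: every non-hRPG gene heterozygous
    for k in range(n - 1, -1, -1):
        fresh = 2.0 * (n - k)
        p = (2.0 * H + fresh * p) / (2.0 * H + k + fresh)
    return p


def race_probability_mc(config: MCConfig) -> RaceEstimate:
    """Estimate the race probability from repeated seeded simulations.

    p_hat is the HRPG_HET_FIRST fraction among resolved runs, with a 95%
    Wilson interval.  The exact recursion value is attached when the run is
    unbudgeted (absorption guaranteed).
    """
    wins, losses, unresolved = _count_events(
        config.G, config.H, config.reps, config.seed, config.M
    )
    resolved = wins + losses
    if resolved == 0:
        raise EstimateError(
            f"all {config.reps} runs unresolved within M={config.M}; "
            "increase the mutation budget"
        )
    low, high = _wilson_ci(wins, resolved)
    exact = race_probability_exact(config.G, config.H) if config.M is None else None
    return RaceEstimate(
        p_hat=wins / resolved,
        ci_low=low,
        ci_high=high,
        reps=config.reps,
        exact_p=exact,
        n_unresolved=unresolved,
    )


def race_probability_bounded(
    G: int, H: int, M: int, reps: int, seed: int = 0
) -> BoundedRaceEstimate:
    """Race outcome probabilities within a finite budget of M mutations."""
    config = MCConfig(G=G, H=H, reps=reps, seed=seed, M=M)  # validates
    wins, losses, unresolved = _count_events(G, H, reps, seed, M)
    low, high = _wilson_ci(wins, reps)
    return BoundedRaceEstimate(
        p_hrpg_first=wins / reps,
        p_homozygous_first=losses / reps,
        p_unresolved=unresolved / reps,
        reps=config.reps,
        M=M,
        ci_low=low,
        ci_high=high,
    )


def _disturbed_exact(G: int, M: int) -> dict[int, float]:
    # Enumerate all (2G)^M equally likely hit sequences.
    total = (2 * G) ** M
    counter: Counter[int] = Counter()
    for seq in itertools.product(range(2 * G), repeat=M):
        hit = set(seq)
        disturbed = sum(1 for g in range(G) if 2 * g in hit and 2 * g + 1 in hit)
        counter[disturbed] += 1
    return {j: c / total for j, c in sorted(counter.items())}


def _disturbed_mc(
    G: int, M: int, reps: int, rng: np.random.Generator
) -> dict[int, float]:
    if M == 0:
        return {0: 1.0}
    # Dense boolean hit table when it fits; per-replicate bincount otherwise.
    if reps * 2 * G <= 50_000_000:
        draws = rng.integers(0, 2 * G, size=(reps, M))
        hits = np.zeros((reps, 2 * G), dtype=bool)
        hits[np.arange(reps)[:, None], draws] = True
        disturbed = (hits[:, 0::2] & hits[:, 1::2]).sum(axis=1)
    else:
        disturbed = np.empty(reps, dtype=np.int64)
        for i in range(reps):
            hit = np.bincount(rng.integers(0, 2 * G, size=M),
                              minlength=2 * G) > 0
            disturbed[i] = int(np.sum(hit[0::2] & hit[1::2]))
    counts = Counter(disturbed.tolist())
    return {j: c / reps for j, c in sorted(counts.items())}


def disturbed_count_distribution(
    G: int,
    M: int,
    reps: int = 100_000,
    rng: np.random.Generator | None = None,
    method: str = "auto",
) -> DisturbedDistribution:
    """Distribution of the number of disturbed genes after M allele hits.

    A gene is *disturbed* when both of its alleles have been hit.  With
    ``method="auto"`` the full outcome space is enumerated exactly whenever
    (2G)^M <= 10^6; otherwise ``reps`` sequences are simulated.
    """
    _validate_gh(G, 0)
    if M < 0:
        raise ConfigError(f"M must be >= 0, got {M}")
    if method not in ("auto", "exact", "mc"):
        raise ConfigError(f"unknown method {method!r}")
    space = (2 * G) ** M
    if method == "exact" or (method == "auto" and space <= EXACT_ENUMERATION_LIMIT):
        if space > EXACT_ENUMERATION_LIMIT:
            raise ConfigError(
                f"(2G)^M = {space} exceeds exact-enumeration limit "
                f"{EXACT_ENUMERATION_LIMIT}"
            )
        return DisturbedDistribution(M=M, probs=_disturbed_exact(G, M),
                                     method="exact")
    if reps < 1:
        raise ConfigError(f"reps must be >= 1, got {reps}")
    if rng is None:
        rng = np.random.default_rng(0)
    return DisturbedDistribution(M=M, probs=_disturbed_mc(G, M, reps, rng),
                                 method="mc")
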