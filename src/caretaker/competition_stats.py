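"""Twin-spot clone quantification statistics and the suppressor decision rule.

A genotype is summarised by per-disc loser/winner area ratios; a candidate
genotype is called a suppressor of loser-cell elimination when (i) its
ratios are stochastically larger than the loser control (one-sided rank
test) and (ii) they are compatible with a normal distribution (omnibus
skewness/kurtosis test does not reject).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import InputError, SampleSizeError

__all__ = [
    "CloneMeasurement",
    "GenotypeSummary",
    "NormalityResult",
    "SuppressorCall",
    "PairedRatioResult",
    "per_disc_ratio",
    "summarize_genotype",
    "dagostino_pearson",
    "rank_group_test",
    "call_suppressor",
    "paired_ratio_test",
]

MIN_NORMALITY_N = 8


@dataclass(frozen=True)
class CloneMeasurement:
    """Measured areas of one twin-spot pair in one imaginal disc."""

    disc_id: str
    genotype: str
    loser_area: float
    winner_area: float

    def __post_init__(self) -> None:
        if self.winner_area <= 0:
            raise InputError(
                f"disc {self.disc_id}: winner_area must be > 0, got {self.winner_area}"
            )
        if self.loser_area < 0:
            raise InputError(
                f"disc {self.disc_id}: loser_area must be >= 0, got {self.loser_area}"
            )


@dataclass
class GenotypeSummary:
    genotype: str
    ratios: list[float]
    mean_ratio: float
    sem: float
    n: int


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    n: int


@dataclass(frozen=True)
class SuppressorCall:
    genotype: str
    is_suppressor: bool
    ratio_test_p: float
    normality_p: float
    alpha_ratio: float
    alpha_norm: float


@dataclass(frozen=True)
class PairedRatioResult:
    statistic: float
    p_value: float
    n: int
    degenerate: bool = False


def per_disc_ratio(m: CloneMeasurement) -> float:
    """Loser/winner area ratio for a single disc."""
    if m.winner_area <= 0:
        raise InputError(f"disc {m.disc_id}: winner_area must be > 0")
    return m.loser_area / m.winner_area


def summarize_genotype(measurements: Iterable[CloneMeasurement]) -> GenotypeSummary:
    """Mean ratio, SEM (sample SD / sqrt(n)) and n over per-disc ratios."""
    ms = list(measurements)
    if not ms:
        raise InputError("empty genotype group: no measurements to summarize")
    genotypes = {m.genotype for m in ms}
    if len(genotypes) != 1:
        raise InputError(f"mixed genotypes in one group: {sorted(genotypes)}")
    ratios = [per_disc_ratio(m) for m in ms]
    n = len(ratios)
    mean = float(np.mean(ratios))
    sem = float(np.std(ratios, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return GenotypeSummary(genotype=genotypes.pop(), ratios=ratios,
                           mean_ratio=mean, sem=sem, n=n)


def _skew_z(x: np.ndarray) -> float:
    # D'Agostino (1970) transformed sample skewness.
    n = x.size
    m2 = np.mean((x - x.mean()) ** 2)
    m3 = np.mean((x - x.mean()) ** 3)
    b1 = m3 / m2 ** 1.5
    y = b1 * math.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = (3.0 * (n ** 2 + 27 * n - 70) * (n + 1) * (n + 3)
             / ((n - 2) * (n + 5) * (n + 7) * (n + 9)))
    w2 = -1.0 + math.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / math.sqrt(0.5 * math.log(w2))
    alpha = math.sqrt(2.0 / (w2 - 1.0))
    t = y / alpha
    return delta * math.log(t + math.sqrt(t * t + 1.0))


def _kurt_z(x: np.ndarray) -> float:
    # Anscombe & Glynn (1983) transformed sample kurtosis.
    n = x.size
    m2 = np.mean((x - x.mean()) ** 2)
    m4 = np.mean((x - x.mean()) ** 4)
    b2 = m4 / m2 ** 2
    e_b2 = 3.0 * (n - 1) / (n + 1)
    var_b2 = (24.0 * n * (n - 2) * (n - 3)
              / ((n + 1) ** 2 * (n + 3) * (n + 5)))
    xx = (b2 - e_b2) / math.sqrt(var_b2)
    sqrt_beta1 = (6.0 * (n * n - 5 * n + 2) / ((n + 7) * (n + 9))
                  * math.sqrt(6.0 * (n + 3) * (n + 5) / (n * (n - 2) * (n - 3))))
    a = 6.0 + 8.0 / sqrt_beta1 * (2.0 / sqrt_beta1
                                  + math.sqrt(1.0 + 4.0 / sqrt_beta1 ** 2))
    term = (1.0 - 2.0 / a) / (1.0 + xx * math.sqrt(2.0 / (a - 4.0)))
    term = math.copysign(abs(term) ** (1.0 / 3.0), term)
    return ((1.0 - 2.0 / (9.0 * a)) - term) / math.sqrt(2.0 / (9.0 * a))


def dagostino_pearson(ratios: Sequence[float]) -> NormalityResult:
    """Omnibus normality test: K2 = Z_skew**2 + Z_kurt**2, chi-square 2 df."""
    x = np.asarray(ratios, dtype=float)
    if x.size < MIN_NORMALITY_N:
        raise SampleSizeError(
            f"normality test needs n >= {MIN_NORMALITY_N}, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise InputError("constant sample: normality test undefined (zero variance)")
    k2 = _skew_z(x) ** 2 + _kurt_z(x) ** 2
    p = float(stats.chi2.sf(k2, df=2))
    return NormalityResult(statistic=float(k2), p_value=p, n=int(x.size))


def rank_group_test(groups: Sequence[Sequence[float]]) -> float:
    """Tie-corrected k-sample rank test (Kruskal-Wallis), two-sided p-value.

    With two groups this is equivalent to the asymptotic two-sided
    Mann-Whitney test without continuity correction.  When every
    observation across all groups is identical, p = 1 by convention.
    """
    if len(groups) < 2:
        raise InputError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 1:
            raise InputError("every group needs at least one observation")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 1.0
    return float(stats.kruskal(*arrays).pvalue)


def call_suppressor(
    candidate: GenotypeSummary,
    loser_control: GenotypeSummary,
    alpha_ratio: float = 0.05,
    alpha_norm: float = 0.05,
) -> SuppressorCall:
    """Two-criterion suppressor decision.

    is_suppressor is true iff the candidate's ratios are larger than the
    loser control's (one-sided Mann-Whitney, p < alpha_ratio) AND the
    candidate's ratios are compatible with normality (omnibus test
    p >= alpha_norm).
    """
    if candidate.n < MIN_NORMALITY_N:
        raise SampleSizeError(
            f"candidate {candidate.genotype!r}: n={candidate.n} < "
            f"{MIN_NORMALITY_N}; refusing to call (normality test undefined)"
        )
    if loser_control.n < 1:
        raise InputError("loser control group is empty")
    cand = np.asarray(candidate.ratios, dtype=float)
    ctrl = np.asarray(loser_control.ratios, dtype=float)
    if np.ptp(np.concatenate([cand, ctrl])) == 0:
        ratio_p = 1.0
    else:
        ratio_p = float(stats.mannwhitneyu(cand, ctrl, alternative="greater").pvalue)
    norm_p = dagostino_pearson(cand).p_value
    return SuppressorCall(
        genotype=candidate.genotype,
        is_suppressor=(ratio_p < alpha_ratio) and (norm_p >= alpha_norm),
        ratio_test_p=ratio_p,
        normality_p=norm_p,
        alpha_ratio=alpha_ratio,
        alpha_norm=alpha_norm,
    )


def paired_ratio_test(
    paired_intensities: Sequence[tuple[float, float]],
) -> PairedRatioResult:
    """Paired ratio t-test: one-sample t of log(treated/control) against 0.

    Two-sided.  If every pair has an identical log-ratio the t statistic is
    undefined (zero SD); the result is then flagged degenerate, with p = 1
    when the common ratio is 1 and p = 0 otherwise.
    """
    pairs = list(paired_intensities)
    if len(pairs) < 2:
        raise InputError("need at least 2 pairs")
    for treated, control in pairs:
        if treated <= 0 or control <= 0:
            raise InputError(
                f"intensities must be > 0, got pair ({treated}, {control})"
            )
    logr = np.array([math.log(t / c) for t, c in pairs])
    if np.ptp(logr) == 0:
        if logr[0] == 0.0:
            return PairedRatioResult(0.0, 1.0, len(pairs), degenerate=True)
        return PairedRatioResult(math.inf if logr[0] > 0 else -math.inf,
                                 0.0, len(pairs), degenerate=True)
    res = stats.ttest_1samp(logr, popmean=0.0)
    return PairedRatioResult(float(res.statistic), float(res.pvalue), len(pairs))
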