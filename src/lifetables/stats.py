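"""Life-table descriptive statistics and distribution diagnostics.

The classical life-table row reports a stage's mean development time with
its standard error.  That pair fully describes the data only if development
times are Gaussian, which real cohorts routinely violate (skewed and
multimodal distributions are common).  This module computes the extended
set of per-stage statistics that exposes the shape of the distribution:

* mean, standard error, and the SE -> SD bridge ``sd = SE * sqrt(n)``;
* median and mode(s);
* kurtosis and skewness as population moment ratios — the non-excess
  convention, so a Gaussian has kurtosis 3 and skewness 0;
* Shapiro-Wilk normality test at the 0.05 threshold and normal Q-Q points;
* the development rate ``G = 1/D`` and, for fecundity schedules, the net
  reproduction rate ``R0 = sum l_x m_x`` and mean generation time
  ``T_G = (1/R0) sum x l_x m_x``.

All stage statistics are computed over the individuals that survived the
stage of interest, the standard life-table convention.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .cohort import Cohort

__all__ = [
    "StatsError",
    "DurationSample",
    "StageSummary",
    "NormalityResult",
    "FecunditySchedule",
    "PopulationParameters",
    "stage_duration_sample",
    "summarize",
    "sd_from_se",
    "moment_kurtosis",
    "moment_skewness",
    "shapiro_wilk",
    "qq_points",
    "development_rate",
    "net_reproduction_rate",
    "mean_generation_time",
]

#: the significance threshold used for every normality verdict
NORMALITY_ALPHA = 0.05


class StatsError(ValueError):
    """Raised on statistically undefined requests (empty/constant samples...)."""


@dataclass(frozen=True)
class DurationSample:
    """Development times (integer days) of the survivors of one stage."""

    stage: str
    temperature: float
    values: tuple[int, ...]

    def __post_init__(self) -> None:
        vals = tuple(int(v) for v in self.values)
        if any(v < 1 for v in vals):
            raise StatsError("durations must be >= 1 day")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class StageSummary:
    """One life-table row plus the distribution-shape diagnostics.

    ``sd`` always equals ``se * sqrt(n)`` exactly (the published-SE bridge).
    ``modes`` lists every most-frequent value ascending; the smallest is the
    primary mode for single-number tables.  ``kurtosis``/``skewness`` are
    population moment ratios; both are NaN for n < 2, as is ``se``.
    """

    stage: str
    temperature: float
    n: int
    mean: float
    se: float
    sd: float
    median: float
    modes: tuple[int, ...]
    kurtosis: float
    skewness: float
    development_rate: float

    @property
    def mode(self) -> int:
        return self.modes[0]


@dataclass(frozen=True)
class NormalityResult:
    """Shapiro-Wilk verdict at the 0.05 threshold."""

    W: float
    p_value: float

    @property
    def is_normal_at_0_05(self) -> bool:
        return self.p_value >= NORMALITY_ALPHA


@dataclass(frozen=True)
class FecunditySchedule:
    """Age-indexed survival l_x and fecundity m_x, ages x = 1..k."""

    l_x: tuple[float, ...]
    m_x: tuple[float, ...]

    def __post_init__(self) -> None:
        lx = tuple(float(v) for v in self.l_x)
        mx = tuple(float(v) for v in self.m_x)
        if len(lx) != len(mx):
            raise StatsError(
                f"l_x (len {len(lx)}) and m_x (len {len(mx)}) must align"
            )
        if any(v < 0 for v in lx + mx):
            raise StatsError("l_x and m_x entries must be >= 0")
        if any(lx[i + 1] > lx[i] for i in range(len(lx) - 1)):
            raise StatsError("l_x must be non-increasing with age")
        object.__setattr__(self, "l_x", lx)
        object.__setattr__(self, "m_x", mx)

    @property
    def ages(self) -> tuple[int, ...]:
        return tuple(range(1, len(self.l_x) + 1))


@dataclass(frozen=True)
class PopulationParameters:
    R0: float
    T_G: float


def stage_duration_sample(cohort: Cohort, stage: str) -> DurationSample:
    """Collect the durations of exactly the individuals that completed ``stage``."""
    if stage not in cohort.stage_sequence:
        raise StatsError(
            f"stage {stage!r} not in cohort stage sequence {cohort.stage_sequence}"
        )
    values = tuple(
        ind.durations[stage] for ind in cohort.individuals if stage in ind.durations
    )
    return DurationSample(stage, cohort.temperature, values)


def moment_skewness(values: Sequence[float]) -> float:
    """Population-moment skewness m3 / m2^(3/2) (divide-by-N, no correction)."""
    x = np.asarray(values, dtype=float)
    d = x - x.mean()
    m2 = np.mean(d**2)
    if m2 == 0.0:
        return float("nan")
    return float(np.mean(d**3) / m2**1.5)


def moment_kurtosis(values: Sequence[float]) -> float:
    """Population-moment (non-excess) kurtosis m4 / m2^2; Gaussian -> 3."""
    x = np.asarray(values, dtype=float)
    d = x - x.mean()
    m2 = np.mean(d**2)
    if m2 == 0.0:
        return float("nan")
    return float(np.mean(d**4) / m2**2)


def summarize(sample: DurationSample) -> StageSummary:
    """Compute the full extended life-table row for one stage sample.

    The SE uses the n-1 sample standard deviation, so that multiplying the
    reported SE back by sqrt(n) recovers the sample SD exactly.  Moment
    statistics (SE, SD, kurtosis, skewness) are NaN for n = 1.
    """
    if sample.n == 0:
        raise StatsError(f"stage {sample.stage!r}: empty sample, nothing to summarize")
    x = np.asarray(sample.values, dtype=float)
    mean = float(x.mean())
    if sample.n >= 2:
        sd_sample = float(x.std(ddof=1))
        se = sd_sample / math.sqrt(sample.n)
        kurt = moment_kurtosis(x)
        skew = moment_skewness(x)
    else:
        se = sd_sample = kurt = skew = float("nan")
    counts = Counter(sample.values)
    top = max(counts.values())
    modes = tuple(sorted(v for v, c in counts.items() if c == top))
    return StageSummary(
        stage=sample.stage,
        temperature=sample.temperature,
        n=sample.n,
        mean=mean,
        se=se,
        sd=sd_from_se(se, sample.n) if sample.n >= 2 else float("nan"),
        median=float(np.median(x)),
        modes=modes,
        kurtosis=kurt,
        skewness=skew,
        development_rate=development_rate(mean),
    )


def sd_from_se(st_err: float, n: int) -> float:
    """Recover the standard deviation from a published standard error."""
    if n < 1:
        raise StatsError(f"n must be >= 1, got {n}")
    if st_err < 0:
        raise StatsError(f"standard error must be >= 0, got {st_err}")
    return float(st_err * math.sqrt(n))


def _as_values(sample: "DurationSample | Sequence[float]") -> np.ndarray:
    values = sample.values if isinstance(sample, DurationSample) else sample
    return np.asarray(values, dtype=float)


def shapiro_wilk(sample: "DurationSample | Sequence[float]") -> NormalityResult:
    """Shapiro-Wilk normality test; verdict at the 0.05 threshold.

    Accepts a :class:`DurationSample` or any numeric sequence.  Requires
    3 <= n <= 5000 (the procedure's validated range) and a non-constant
    sample.
    """
    x = _as_values(sample)
    if not 3 <= x.size <= 5000:
        raise StatsError(f"Shapiro-Wilk needs 3 <= n <= 5000, got n = {x.size}")
    if np.all(x == x[0]):
        raise StatsError("Shapiro-Wilk is undefined for a constant sample")
    res = sps.shapiro(x)
    return NormalityResult(W=float(res.statistic), p_value=float(res.pvalue))


def qq_points(
    sample: "DurationSample | Sequence[float]",
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Normal Q-Q coordinates plus the quartile reference line.

    Returns ``(theoretical, observed, (slope, intercept))``: standard-normal
    quantiles at plotting positions (i - 0.5)/n against the sorted data, and
    the straight line through the first- and third-quartile points, the
    conventional reference for judging linearity by eye.
    """
    x = _as_values(sample)
    if x.size < 2:
        raise StatsError(f"Q-Q plot needs n >= 2, got n = {x.size}")
    observed = np.sort(x)
    positions = (np.arange(1, x.size + 1) - 0.5) / x.size
    theoretical = sps.norm.ppf(positions)
    q1_data, q3_data = np.quantile(observed, [0.25, 0.75])
    q1_theo, q3_theo = sps.norm.ppf([0.25, 0.75])
    if q3_data == q1_data:
        slope = 0.0
    else:
        slope = float((q3_data - q1_data) / (q3_theo - q1_theo))
    intercept = float(q1_data - slope * q1_theo)
    return theoretical, observed, (slope, intercept)


def development_rate(mean_dev_time: float) -> float:
    """Development rate G = 1/D from a mean development time in days."""
    if not mean_dev_time > 0:
        raise StatsError(
            f"mean development time must be positive, got {mean_dev_time}"
        )
    return 1.0 / float(mean_dev_time)


def net_reproduction_rate(schedule: FecunditySchedule) -> float:
    """Net reproduction rate R0 = sum over ages of l_x * m_x."""
    return float(
        sum(l * m for l, m in zip(schedule.l_x, schedule.m_x))
    )


def mean_generation_time(schedule: FecunditySchedule) -> float:
    """Mean generation time T_G = (1/R0) sum over ages of x * l_x * m_x."""
    r0 = net_reproduction_rate(schedule)
    if r0 == 0.0:
        raise StatsError("mean generation time is undefined when R0 = 0")
    weighted = sum(
        x * l * m for x, l, m in zip(schedule.ages, schedule.l_x, schedule.m_x)
    )
    return float(weighted / r0)


def population_parameters(schedule: FecunditySchedule) -> PopulationParameters:
    """Convenience: both R0 and T_G from one schedule."""
    return PopulationParameters(
        R0=net_reproduction_rate(schedule), T_G=mean_generation_time(schedule)
    )
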