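"""Stage-structured population dynamics as discrete-time impulse responses.

A life-table rearing experiment is, from a system-identification viewpoint,
an impulse-response experiment: placing N eggs in a chamber on day 0 is the
input ``u(t) = N delta(t)`` (Kronecker impulse), and the daily counts of
individuals emerging into the next stage are the system's response.  Each
stage is a linear time-invariant block fully described by

* a normalized kernel ``w(t)`` — the fraction of stage survivors that take
  exactly ``t`` days to complete the stage — and
* a survival fraction ``S`` — the proportion of entrants that complete it.

The raw per-day emergence fractions of the experiment equal ``S * w(t)``;
storing the kernel and the survival separately keeps mortality from being
double-counted when stages are chained.  Multi-stage models compose by
discrete convolution of kernels and multiplication of survivals — the
time-domain equivalent of multiplying transfer functions in the Z domain,
and identical for the finite sequences involved.

The Gaussian counterpart implied by a classical life-table row (mean, SE, n)
is built by integrating the normal density over unit day bins
(:func:`gaussian_kernel`); comparing its dynamics against the empirical
kernel quantifies what the mean-and-SE summary loses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .stats import DurationSample

__all__ = [
    "ImpulseError",
    "ImpulseResponse",
    "ModelComparison",
    "impulse_input",
    "empirical_impulse",
    "compose",
    "respond",
    "gaussian_kernel",
    "peak_day",
    "compare_models",
]

_KERNEL_TOL = 1e-9


class ImpulseError(ValueError):
    """Raised for invalid kernels, inputs, or incompatible compositions."""


@dataclass(frozen=True)
class ImpulseResponse:
    """A normalized day-indexed kernel plus a survival fraction.

    ``kernel[t]`` is the probability a stage survivor completes the stage in
    exactly ``t`` days; entries are non-negative and sum to 1.  ``survival``
    scales the response amplitude; composed responses multiply survivals.
    """

    kernel: np.ndarray
    survival: float
    from_stage: str
    to_stage: str

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=float)
        object.__setattr__(self, "kernel", k)
        if k.ndim != 1 or k.size == 0:
            raise ImpulseError("kernel must be a non-empty 1-D sequence")
        if (k < 0).any():
            raise ImpulseError("kernel entries must be >= 0")
        if abs(k.sum() - 1.0) > _KERNEL_TOL:
            raise ImpulseError(f"kernel must sum to 1 (got {k.sum()!r})")
        if not 0.0 <= self.survival <= 1.0:
            raise ImpulseError(f"survival must lie in [0, 1], got {self.survival}")

    @property
    def raw_response(self) -> np.ndarray:
        """The experiment's raw per-day emergence fractions, S * w(t)."""
        return self.survival * self.kernel

    def mean_day(self) -> float:
        """First moment of the kernel (mean completion day)."""
        return float(np.sum(np.arange(self.kernel.size) * self.kernel))


@dataclass(frozen=True)
class ModelComparison:
    """Peak/shape discrepancy between two day-indexed mass sequences."""

    empirical_peak_day: int
    gaussian_peak_day: int
    peak_shift: int  # gaussian - empirical, days
    l1_distance: float  # in [0, 2] for normalized sequences
    support_empirical: tuple[int, int]
    support_gaussian: tuple[int, int]


def impulse_input(N: int, horizon: int) -> np.ndarray:
    """The cohort-start input N * delta(t) on a day grid of length ``horizon``."""
    if N < 1:
        raise ImpulseError(f"cohort size N must be >= 1, got {N}")
    if horizon < 1:
        raise ImpulseError(f"horizon must be >= 1 day, got {horizon}")
    u = np.zeros(horizon, dtype=float)
    u[0] = float(N)
    return u


def empirical_impulse(sample: DurationSample, n_entrants: int) -> ImpulseResponse:
    """Identify one stage's impulse response from observed durations.

    Durations are measured from each individual's own entry into the stage
    (the cohort is "shifted to time zero" per stage).  ``kernel[t]`` is the
    fraction of stage survivors with duration exactly ``t``; ``survival`` is
    survivors / entrants.  The raw experiment sequence is ``S * kernel``.
    """
    if sample.n == 0:
        raise ImpulseError(
            f"stage {sample.stage!r}: no survivors, cannot normalize a kernel"
        )
    if n_entrants < sample.n:
        raise ImpulseError(
            f"stage {sample.stage!r}: {sample.n} survivors exceed "
            f"{n_entrants} entrants"
        )
    counts = np.bincount(np.asarray(sample.values, dtype=int))
    kernel = counts / sample.n
    return ImpulseResponse(
        kernel=kernel,
        survival=sample.n / n_entrants,
        from_stage=sample.stage,
        to_stage=f"post_{sample.stage}",
    )


def compose(a: ImpulseResponse, b: ImpulseResponse) -> ImpulseResponse:
    """Chain two stage blocks: convolve kernels, multiply survivals.

    ``a`` feeds ``b`` (``a.to_stage`` must equal ``b.from_stage``); the
    result maps ``a.from_stage`` entrants to ``b.to_stage`` emergences.
    """
    if a.to_stage != b.from_stage:
        raise ImpulseError(
            f"cannot compose: {a.from_stage}->{a.to_stage} does not feed "
            f"{b.from_stage}->{b.to_stage}"
        )
    kernel = np.convolve(a.kernel, b.kernel)
    # renormalize the floating-point drift of long convolutions
    kernel = kernel / kernel.sum()
    return ImpulseResponse(
        kernel=kernel,
        survival=a.survival * b.survival,
        from_stage=a.from_stage,
        to_stage=b.to_stage,
    )


def respond(ir: ImpulseResponse, u: np.ndarray) -> np.ndarray:
    """Drive a stage block with an arbitrary entrant sequence.

    ``y(t) = S * sum_tau w(t - tau) u(tau)``; for ``u = N delta`` the output
    is ``N * S * w``.  The output grid extends to cover the full response.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 1 or u.size == 0:
        raise ImpulseError("input must be a non-empty 1-D sequence")
    if (u < 0).any():
        raise ImpulseError("input counts must be >= 0")
    return ir.survival * np.convolve(u, ir.kernel)


def gaussian_kernel(
    mean: float,
    sd: float,
    horizon: int | None = None,
    *,
    from_stage: str = "stage",
    to_stage: str = "post_stage",
) -> ImpulseResponse:
    """The day-binned Gaussian kernel implied by a life-table (mean, SD) row.

    The normal density with the given mean and SD is integrated over unit
    bins [t - 1/2, t + 1/2) for t = 0..horizon and renormalized over that
    truncated support — mass-preserving and well-behaved for small SD.
    ``sd = 0`` degenerates to a point mass on the nearest integer day.
    Survival is 1; the caller scales mortality separately.
    """
    if not mean > 0:
        raise ImpulseError(f"mean development time must be positive, got {mean}")
    if sd < 0:
        raise ImpulseError(f"sd must be >= 0, got {sd}")
    if horizon is None:
        horizon = int(np.ceil(mean + 6 * sd))
    if horizon < mean + 6 * sd - 1:
        raise ImpulseError(
            f"horizon {horizon} too short for mean {mean}, sd {sd}; "
            f"need >= mean + 6 sd"
        )
    days = np.arange(horizon + 1)
    if sd == 0:
        kernel = np.zeros(horizon + 1)
        kernel[int(round(mean))] = 1.0
    else:
        edges = np.concatenate((days - 0.5, [horizon + 0.5]))
        mass = np.diff(sps.norm.cdf(edges, loc=mean, scale=sd))
        kernel = mass / mass.sum()
    return ImpulseResponse(
        kernel=kernel, survival=1.0, from_stage=from_stage, to_stage=to_stage
    )


def peak_day(seq: np.ndarray) -> int:
    """Earliest day attaining the maximum of a non-negative day sequence."""
    seq = np.asarray(seq, dtype=float)
    if seq.size == 0 or not (seq > 0).any():
        raise ImpulseError("peak of an empty or all-zero sequence is undefined")
    return int(np.argmax(seq))


def _support(seq: np.ndarray) -> tuple[int, int]:
    nz = np.nonzero(seq)[0]
    return int(nz[0]), int(nz[-1])


def compare_models(
    empirical: np.ndarray, gaussian: np.ndarray, normalize: bool = True
) -> ModelComparison:
    """Quantify the gap between empirical and Gaussian-implied dynamics.

    With ``normalize`` on (the standard comparison, which removes mortality
    scaling) each sequence is rescaled to total mass 1 before computing peak
    days, the peak shift (gaussian minus empirical, in days), the L1
    distance and the supports.
    """
    a = np.asarray(empirical, dtype=float)
    b = np.asarray(gaussian, dtype=float)
    for name, s in (("empirical", a), ("gaussian", b)):
        if s.size == 0 or not (s > 0).any():
            raise ImpulseError(f"{name} sequence has no positive mass")
        if (s < 0).any():
            raise ImpulseError(f"{name} sequence has negative entries")
    if normalize:
        a = a / a.sum()
        b = b / b.sum()
    width = max(a.size, b.size)
    a = np.pad(a, (0, width - a.size))
    b = np.pad(b, (0, width - b.size))
    e_peak, g_peak = peak_day(a), peak_day(b)
    return ModelComparison(
        empirical_peak_day=e_peak,
        gaussian_peak_day=g_peak,
        peak_shift=g_peak - e_peak,
        l1_distance=float(np.abs(a - b).sum()),
        support_empirical=_support(a),
        support_gaussian=_support(b),
    )
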