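"""Pipeline orchestration: summary tables, Q-Q sidecars, figures, dynamics.

`run_pipeline` ties the layers together for one cohort (read from CSV or
simulated on the fly): per stage it writes the extended life-table row, the
normal Q-Q points, a distribution-overlay figure (observed histogram, the
Gaussian curve implied by mean and SE, the sample median), and the
egg-origin impulse-response dynamics compared against their Gaussian
counterpart.  Figures are presentation artifacts; every number they show is
also written to a CSV/JSON sidecar, which is what tests inspect.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Cohort, read_cohort, write_cohort
from .impulse import (
    ImpulseResponse,
    compare_models,
    compose,
    empirical_impulse,
    gaussian_kernel,
    impulse_input,
    respond,
)
from .stats import (
    NormalityResult,
    StageSummary,
    StatsError,
    shapiro_wilk,
    qq_points,
    stage_duration_sample,
    summarize,
)
from .synthetic import CohortConfig, generate_cohort

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "render_summary_table",
    "stage_entrants",
    "cohort_dynamics",
]

logger = logging.getLogger("lifetables")


class PipelineError(ValueError):
    """Raised on invalid pipeline configurations."""


@dataclass
class PipelineConfig:
    """Exactly one of ``input_path`` (analyse an existing cohort CSV) or
    ``simulation`` (simulate-then-analyse) must be provided."""

    out_dir: Path
    input_path: Path | None = None
    simulation: CohortConfig | None = None
    normalize: bool = True
    make_figures: bool = True

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise PipelineError(
                "provide exactly one of input_path or simulation config"
            )
        self.out_dir = Path(self.out_dir)
        if self.input_path is not None:
            self.input_path = Path(self.input_path)
            if not self.input_path.exists():
                raise PipelineError(f"input file not found: {self.input_path}")


def stage_entrants(cohort: Cohort) -> dict[str, int]:
    """Number of individuals entering each stage (all eggs enter stage 1)."""
    entrants: dict[str, int] = {}
    alive = cohort.n_initial
    for stage in cohort.stage_sequence:
        entrants[stage] = alive
        alive = sum(1 for ind in cohort.individuals if stage in ind.durations)
    return entrants


def _fmt(x: float, digits: int = 6) -> float | str:
    return "" if x != x else round(float(x), digits)  # NaN -> empty cell


def render_summary_table(
    rows: list[tuple[StageSummary, NormalityResult | None]], path: str | Path
) -> Path:
    """Write the extended life-table CSV (classical row + shape diagnostics).

    The ``mean`` column carries the familiar ``mean±se`` string rounded to
    one decimal, as life tables print it; ``se`` and the rest stay numeric.
    """
    if not rows:
        raise PipelineError("summary table needs at least one row")
    records = []
    for summary, normality in rows:
        se_str = "nan" if summary.se != summary.se else f"{summary.se:.1f}"
        records.append(
            {
                "stage": summary.stage,
                "temperature_C": summary.temperature,
                "mean": f"{summary.mean:.1f}±{se_str}",
                "se": _fmt(summary.se),
                "n": summary.n,
                "mode": summary.mode,
                "median": _fmt(summary.median),
                "kurtosis": _fmt(summary.kurtosis),
                "skewness": _fmt(summary.skewness),
                "sw_W": _fmt(normality.W) if normality else "",
                "sw_p": _fmt(normality.p_value, 10) if normality else "",
                "normal_at_0_05": normality.is_normal_at_0_05 if normality else "",
            }
        )
    frame = pd.DataFrame.from_records(records)
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def cohort_dynamics(
    cohort: Cohort, normalize: bool = True
) -> dict[str, dict]:
    """Egg-origin dynamics per stage: empirical vs Gaussian-implied models.

    For each stage boundary, the empirical kernels of all stages up to and
    including it are composed by convolution and driven by the N*delta(t)
    cohort input; the Gaussian model does the same with day-binned normal
    kernels built from each stage's own mean and SE-derived SD.  Returns a
    JSON-ready mapping stage -> kernels, survivals, peaks and comparison.
    """
    entrants = stage_entrants(cohort)
    u = impulse_input(cohort.n_initial, 1)
    emp_chain: ImpulseResponse | None = None
    gauss_chain: ImpulseResponse | None = None
    out: dict[str, dict] = {}
    for stage in cohort.stage_sequence:
        sample = stage_duration_sample(cohort, stage)
        if sample.n == 0:
            logger.warning("stage %s: no survivors, dynamics stop here", stage)
            break
        emp = empirical_impulse(sample, entrants[stage])
        summary = summarize(sample)
        sd = summary.sd if summary.sd == summary.sd else 0.0
        horizon = max(len(emp.kernel) - 1, int(np.ceil(summary.mean + 6 * sd)))
        gauss = gaussian_kernel(
            summary.mean,
            sd,
            horizon,
            from_stage=emp.from_stage,
            to_stage=emp.to_stage,
        )
        if emp_chain is None:
            emp_chain, gauss_chain = emp, gauss
        else:
            emp = ImpulseResponse(
                emp.kernel, emp.survival, emp_chain.to_stage, emp.to_stage
            )
            gauss = ImpulseResponse(
                gauss.kernel, gauss.survival, gauss_chain.to_stage, gauss.to_stage
            )
            emp_chain = compose(emp_chain, emp)
            gauss_chain = compose(gauss_chain, gauss)
        y_emp = respond(emp_chain, u)
        y_gauss = respond(
            ImpulseResponse(
                gauss_chain.kernel,
                emp_chain.survival,  # same mortality; the comparison is shape
                gauss_chain.from_stage,
                gauss_chain.to_stage,
            ),
            u,
        )
        cmp_result = compare_models(y_emp, y_gauss, normalize=normalize)
        out[stage] = {
            "n_entrants": entrants[stage],
            "n_survivors": sample.n,
            "stage_survival": emp.survival,
            "cumulative_survival": emp_chain.survival,
            "empirical_kernel": [round(v, 12) for v in emp_chain.kernel],
            "gaussian_kernel": [round(v, 12) for v in gauss_chain.kernel],
            "empirical_peak_day": cmp_result.empirical_peak_day,
            "gaussian_peak_day": cmp_result.gaussian_peak_day,
            "peak_shift_days": cmp_result.peak_shift,
            "l1_distance": round(cmp_result.l1_distance, 12),
            "support_empirical": list(cmp_result.support_empirical),
            "support_gaussian": list(cmp_result.support_gaussian),
        }
    return out


def _overlay_figure(summary: StageSummary, sample_values, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    values = np.asarray(sample_values)
    bins = np.arange(values.min() - 0.5, values.max() + 1.5)
    ax.hist(values, bins=bins, density=True, color="0.6", label="observed")
    if summary.sd == summary.sd and summary.sd > 0:
        t = np.linspace(values.min() - 3, values.max() + 3, 400)
        ax.plot(
            t,
            sps.norm.pdf(t, summary.mean, summary.sd),
            "r-",
            label="Gaussian (mean, SE-derived SD)",
        )
    ax.axvline(summary.median, color="green", label="median")
    ax.set_xlabel("development time (days)")
    ax.set_ylabel("fraction of individuals")
    ax.set_title(f"{summary.stage} at {summary.temperature:g} °C")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _dynamics_figure(stage: str, entry: dict, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    emp = np.asarray(entry["empirical_kernel"])
    gauss = np.asarray(entry["gaussian_kernel"])
    ax.stem(np.arange(emp.size), emp, basefmt=" ", label="impulse response")
    ax.plot(np.arange(gauss.size), gauss, "r-", label="Gaussian model")
    ax.set_xlabel("days since egg laying")
    ax.set_ylabel("normalized emergence")
    ax.set_title(f"dynamics to end of {stage}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis for one cohort; returns the report bundle.

    Writes into ``config.out_dir``: ``cohort.csv`` (simulate mode only),
    ``summary.csv``, ``qq_<stage>.csv``, ``dynamics.json`` and, unless
    figures are disabled, ``dist_<stage>.png`` / ``dynamics_<stage>.png``.
    Stages with no survivors are skipped with a warning, not a crash.
    """
    out_dir = config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.simulation is not None:
        cohort = generate_cohort(config.simulation)
        write_cohort(cohort, out_dir / "cohort.csv")
    else:
        cohort = read_cohort(config.input_path)

    rows: list[tuple[StageSummary, NormalityResult | None]] = []
    for stage in cohort.stage_sequence:
        sample = stage_duration_sample(cohort, stage)
        if sample.n == 0:
            logger.warning(
                "stage %s at %g C: empty sample, skipped", stage, cohort.temperature
            )
            continue
        summary = summarize(sample)
        try:
            normality = shapiro_wilk(sample)
        except StatsError as exc:
            logger.warning("stage %s: Shapiro-Wilk unavailable (%s)", stage, exc)
            normality = None
        rows.append((summary, normality))
        logger.info(
            "stage %s at %g C: n=%d mean=%.2f normal_at_0.05=%s",
            stage,
            cohort.temperature,
            sample.n,
            summary.mean,
            normality.is_normal_at_0_05 if normality else "n/a",
        )
        if sample.n >= 2:
            theo, obs, (slope, intercept) = qq_points(sample)
            qq = pd.DataFrame(
                {"theoretical_quantile": theo, "observed_days": obs}
            )
            qq["line_slope"] = slope
            qq["line_intercept"] = intercept
            qq.to_csv(out_dir / f"qq_{stage}.csv", index=False)
        if config.make_figures:
            _overlay_figure(summary, sample.values, out_dir / f"dist_{stage}.png")

    if not rows:
        raise PipelineError("no stage had any survivor; nothing to report")
    render_summary_table(rows, out_dir / "summary.csv")

    dynamics = cohort_dynamics(cohort, normalize=config.normalize)
    with (out_dir / "dynamics.json").open("w", encoding="utf-8") as fh:
        json.dump(dynamics, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if config.make_figures:
        for stage, entry in dynamics.items():
            _dynamics_figure(stage, entry, out_dir / f"dynamics_{stage}.png")

    return {
        "cohort": cohort,
        "summaries": rows,
        "dynamics": dynamics,
        "out_dir": out_dir,
    }
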