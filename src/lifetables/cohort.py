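"""Individual-level life-table data model and CSV input/output.

A *cohort* is a group of same-aged individuals (eggs laid on the same day)
reared at one constant temperature and inspected daily until death or adult
emergence.  Each :class:`LifeHistory` records the integer number of census
days the individual spent in every stage it completed, and the stage it died
in (if any).  This individual-level representation is strictly richer than
the classical day-by-stage occupancy matrix of Chi & Liu: the matrix can be
derived from it (:func:`to_stage_frequency_matrix`) but not the reverse.

The on-disk format is a plain UTF-8 comma-separated file::

    individual_id,temperature_C,<stage1>_days,...,<stageK>_days,death_stage

with empty duration cells for stages the individual did not complete and
``death_stage`` either a stage name or ``none``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortError",
    "CohortParseError",
    "LifeHistory",
    "Cohort",
    "StageFrequencyMatrix",
    "read_cohort",
    "write_cohort",
    "to_stage_frequency_matrix",
]

#: death_stage sentinel used on disk for individuals that completed all stages
SURVIVED = "none"


class CohortError(ValueError):
    """Raised when cohort data violate the data-model invariants."""


class CohortParseError(CohortError):
    """Raised when a cohort CSV cannot be parsed into a valid cohort."""


@dataclass(frozen=True)
class LifeHistory:
    """One reared individual.

    Parameters
    ----------
    individual_id:
        Opaque identifier, unique within a cohort.
    durations:
        Ordered mapping stage name -> integer days, present exactly for the
        contiguous prefix of stages the individual completed.  Every duration
        is >= 1: an individual is observed in a stage on at least one census
        day.
    death_stage:
        Name of the stage the individual died in, or ``None`` if it survived
        through the final stage.
    """

    individual_id: str
    durations: Mapping[str, int]
    death_stage: str | None = None

    def __post_init__(self) -> None:
        durs = dict(self.durations)
        object.__setattr__(self, "durations", durs)
        for stage, d in durs.items():
            if not (isinstance(d, (int, np.integer)) and not isinstance(d, bool)):
                raise CohortError(
                    f"individual {self.individual_id!r}: duration for stage "
                    f"{stage!r} must be an integer, got {d!r}"
                )
            if d < 1:
                raise CohortError(
                    f"individual {self.individual_id!r}: duration for stage "
                    f"{stage!r} must be >= 1 day, got {d}"
                )

    @property
    def survived(self) -> bool:
        return self.death_stage is None

    def total_days(self) -> int:
        """Total observed development time over completed stages."""
        return sum(self.durations.values())


@dataclass
class Cohort:
    """A set of life histories reared at one constant temperature.

    ``observation_step`` is the census interval; the whole package assumes
    daily inspections (1 day), the standard life-table protocol.
    """

    temperature: float
    stage_sequence: Sequence[str]
    individuals: list[LifeHistory] = field(default_factory=list)
    observation_step: int = 1

    def __post_init__(self) -> None:
        self.stage_sequence = tuple(self.stage_sequence)
        if len(set(self.stage_sequence)) != len(self.stage_sequence):
            raise CohortError("stage_sequence contains duplicate stage names")
        self.validate()

    @property
    def n_initial(self) -> int:
        return len(self.individuals)

    def validate(self) -> None:
        """Check every invariant; raise :class:`CohortError` on violation."""
        seen: set[str] = set()
        stages = tuple(self.stage_sequence)
        for ind in self.individuals:
            if ind.individual_id in seen:
                raise CohortError(f"duplicate individual_id {ind.individual_id!r}")
            seen.add(ind.individual_id)
            recorded = tuple(ind.durations.keys())
            if ind.death_stage is None:
                expected = stages
            else:
                if ind.death_stage not in stages:
                    raise CohortError(
                        f"individual {ind.individual_id!r}: death_stage "
                        f"{ind.death_stage!r} not in stage sequence"
                    )
                expected = stages[: stages.index(ind.death_stage)]
            if recorded != expected:
                raise CohortError(
                    f"individual {ind.individual_id!r}: durations recorded for "
                    f"{recorded}, expected the contiguous prefix {expected} "
                    f"preceding death_stage={ind.death_stage!r}"
                )


@dataclass
class StageFrequencyMatrix:
    """Day-by-stage occupancy counts (the Chi & Liu representation).

    ``grid[t, j]`` is the number of individuals occupying stage ``j`` on
    census day ``t`` (0-based: an egg laid at t=0 occupies the egg stage on
    day 0).  ``horizon`` is the last day with any occupancy, or -1 when no
    individual was ever observed alive in a recorded stage.
    """

    stage_sequence: tuple[str, ...]
    grid: np.ndarray  # shape (horizon + 1, n_stages), non-negative ints

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=int)
        if self.grid.ndim != 2 or self.grid.shape[1] != len(self.stage_sequence):
            raise CohortError("grid shape inconsistent with stage_sequence")
        if (self.grid < 0).any():
            raise CohortError("occupancy counts must be non-negative")

    @property
    def horizon(self) -> int:
        return self.grid.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.grid, columns=list(self.stage_sequence))
        frame.insert(0, "day", np.arange(self.grid.shape[0]))
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _stage_columns(stage_sequence: Sequence[str]) -> list[str]:
    return [f"{s}_days" for s in stage_sequence]


def read_cohort(path: str | Path, stage_sequence: Sequence[str] | None = None) -> Cohort:
    """Read a cohort CSV.

    When ``stage_sequence`` is omitted the stage order is inferred from the
    ``<stage>_days`` header columns, in file order.  Parse errors name the
    offending row or individual id.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames
        if header is None:
            raise CohortParseError(f"{path}: empty file, expected a header row")
        if header[0] != "individual_id" or header[-1] != "death_stage" or "temperature_C" not in header:
            raise CohortParseError(
                f"{path}: header must be "
                "individual_id,temperature_C,<stage>_days,...,death_stage; "
                f"got {header}"
            )
        file_stages = [c[: -len("_days")] for c in header if c.endswith("_days")]
        if stage_sequence is None:
            stage_sequence = file_stages
        elif list(stage_sequence) != file_stages:
            raise CohortParseError(
                f"{path}: stage columns {file_stages} do not match requested "
                f"stage sequence {list(stage_sequence)}"
            )
        if not file_stages:
            raise CohortParseError(f"{path}: no <stage>_days columns in header")

        individuals: list[LifeHistory] = []
        seen_ids: set[str] = set()
        temperature: float | None = None
        for lineno, row in enumerate(reader, start=2):
            ind_id = (row.get("individual_id") or "").strip()
            if not ind_id:
                raise CohortParseError(f"{path}:{lineno}: missing individual_id")
            if ind_id in seen_ids:
                raise CohortParseError(
                    f"{path}:{lineno}: duplicate individual_id {ind_id!r}"
                )
            seen_ids.add(ind_id)
            try:
                row_temp = float(row["temperature_C"])
            except (KeyError, TypeError, ValueError):
                raise CohortParseError(
                    f"{path}:{lineno}: invalid temperature_C for {ind_id!r}"
                ) from None
            if temperature is None:
                temperature = row_temp
            elif row_temp != temperature:
                raise CohortParseError(
                    f"{path}:{lineno}: temperature {row_temp} differs from "
                    f"cohort temperature {temperature}; one cohort per file"
                )
            death_raw = (row.get("death_stage") or "").strip()
            death_stage = None if death_raw == SURVIVED else death_raw
            if death_stage is not None and death_stage not in stage_sequence:
                raise CohortParseError(
                    f"{path}:{lineno}: unknown death_stage {death_stage!r} "
                    f"for {ind_id!r}"
                )
            durations: dict[str, int] = {}
            past_death = False
            for stage in stage_sequence:
                cell = (row.get(f"{stage}_days") or "").strip()
                if stage == death_stage:
                    past_death = True
                if cell == "":
                    continue
                if past_death:
                    raise CohortParseError(
                        f"{path}:{lineno}: individual {ind_id!r} has a "
                        f"duration for stage {stage!r} at or after its death "
                        f"stage {death_stage!r}"
                    )
                try:
                    value = int(cell)
                except ValueError:
                    raise CohortParseError(
                        f"{path}:{lineno}: non-integer duration {cell!r} for "
                        f"stage {stage!r} of {ind_id!r}"
                    ) from None
                if value < 1:
                    raise CohortParseError(
                        f"{path}:{lineno}: duration must be >= 1 day, got "
                        f"{value} for stage {stage!r} of {ind_id!r}"
                    )
                durations[stage] = value
            try:
                individuals.append(
                    LifeHistory(ind_id, durations, death_stage=death_stage)
                )
            except CohortError as exc:
                raise CohortParseError(f"{path}:{lineno}: {exc}") from None

    if temperature is None:
        temperature = float("nan")
    try:
        return Cohort(temperature, tuple(stage_sequence), individuals)
    except CohortError as exc:
        raise CohortParseError(f"{path}: {exc}") from None


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort CSV such that ``read_cohort`` reproduces it exactly."""
    cohort.validate()
    path = Path(path)
    temp = cohort.temperature
    temp_str = str(int(temp)) if float(temp).is_integer() else repr(float(temp))
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["individual_id", "temperature_C"]
            + _stage_columns(cohort.stage_sequence)
            + ["death_stage"]
        )
        for ind in cohort.individuals:
            cells = [
                str(ind.durations[s]) if s in ind.durations else ""
                for s in cohort.stage_sequence
            ]
            writer.writerow(
                [ind.individual_id, temp_str]
                + cells
                + [SURVIVED if ind.death_stage is None else ind.death_stage]
            )
    return path


def to_stage_frequency_matrix(cohort: Cohort) -> StageFrequencyMatrix:
    """Derive the Chi & Liu day-by-stage occupancy matrix.

    An individual with completed durations (d1, ..., ds) occupies stage 1 on
    days [0, d1), stage 2 on days [d1, d1 + d2), and so on.  Individuals
    contribute no occupancy to the stage they died in: the CSV records no
    duration there, and downstream statistics use survivors of each stage
    only, so the omission never feeds any statistic.
    """
    if cohort.n_initial == 0:
        raise CohortError("cannot build a stage-frequency matrix from an empty cohort")
    cohort.validate()
    n_days = max((ind.total_days() for ind in cohort.individuals), default=0)
    grid = np.zeros((n_days, len(cohort.stage_sequence)), dtype=int)
    stage_index = {s: j for j, s in enumerate(cohort.stage_sequence)}
    for ind in cohort.individuals:
        start = 0
        for stage, d in ind.durations.items():
            grid[start : start + d, stage_index[stage]] += 1
            start += d
    # trim trailing all-zero days (possible only when every individual died
    # before completing any stage, giving an empty grid)
    return StageFrequencyMatrix(tuple(cohort.stage_sequence), grid)
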