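"""Outcome measures: per-target navigation errors, run and rating summaries.

The primary outcome of the tracked-necrosectomy experiment is the
navigation error — the Euclidean distance between the registered tip
position and each of the seven target markers when the operator believes
the tip is on the target.  Secondary outcomes are the fiducial
registration error, the procedure time, and a four-investigator rating
of the assistance system on a 1–5 scale (usefulness, realistic
implementation, accuracy level).  Runs are compared with a classical
one-way analysis of variance.

Published per-run measurements from the original bench experiment ship
as packaged CSV fixtures (``data/table1_runs.csv``,
``data/table2_ratings.csv``) and serve as worked examples: every summary
statistic here is recomputed from the per-target values, never copied.
Navigation errors are reported half-up-rounded to one decimal mm and
ratings to two decimals, matching the published formatting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    EmptyErrors,
    InsufficientData,
    OutOfRangeScore,
)
from .geometry import Point3
from .navigation import distance_to_target
from .phantom import MarkerSpec

__all__ = [
    "RUN_MODES",
    "RATING_CRITERIA",
    "RunRecord",
    "RunSummary",
    "RatingMatrix",
    "EvaluationReport",
    "navigation_error",
    "summarize_run",
    "rating_summary",
    "anova_one_way",
    "build_report",
    "round_half_up",
    "load_table1_runs",
    "load_table2_ratings",
]

RUN_MODES = ("EC", "AS", "EC+AS")  # endoscopic camera / assistance system
RATING_CRITERIA = ("usefulness", "realistic_implementation", "accuracy_level")


def round_half_up(value: float, decimals: int) -> float:
    """Decimal half-up rounding (2.85 -> 2.9 at one decimal)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def navigation_error(tip_image: Point3, target: MarkerSpec) -> float:
    """Primary outcome: Euclidean tip-to-target distance (mm)."""
    return distance_to_target(tip_image, target)


@dataclass(frozen=True)
class RunRecord:
    """One necrosectomy run: mode, per-target errors (mm), FRE, duration."""

    run_id: int
    investigator: int
    mode: str
    errors: Tuple[float, ...]
    fre: float = float("nan")
    time_s: float = float("nan")

    def __post_init__(self) -> None:
        if self.mode not in RUN_MODES:
            raise ValueError(f"mode must be one of {RUN_MODES}, got {self.mode!r}")
        errors = tuple(float(e) for e in self.errors)
        if any(e < 0 for e in errors):
            raise ValueError("navigation errors must be >= 0")
        object.__setattr__(self, "errors", errors)


@dataclass(frozen=True)
class RunSummary:
    """Half-up one-decimal mean plus raw min/max of the per-target errors."""

    run_id: int
    mean_mm: float
    min_mm: float
    max_mm: float


def summarize_run(record: RunRecord) -> RunSummary:
    """Arithmetic mean of per-target errors, half-up rounded to 1 decimal."""
    if len(record.errors) == 0:
        raise EmptyErrors(f"run {record.run_id} has no per-target errors")
    e = np.asarray(record.errors)
    return RunSummary(
        run_id=record.run_id,
        mean_mm=round_half_up(float(e.mean()), 1),
        min_mm=float(e.min()),
        max_mm=float(e.max()),
    )


@dataclass(frozen=True)
class RatingMatrix:
    """Per-investigator 1-5 scores for each assessment criterion."""

    scores: Dict[str, Tuple[int, ...]]

    def __post_init__(self) -> None:
        cleaned = {}
        for criterion, values in self.scores.items():
            vals = tuple(int(v) for v in values)
            bad = [v for v in vals if not 1 <= v <= 5]
            if bad:
                raise OutOfRangeScore(
                    f"scores for {criterion!r} outside [1, 5]: {bad}"
                )
            cleaned[str(criterion)] = vals
        object.__setattr__(self, "scores", cleaned)


def rating_summary(matrix: RatingMatrix) -> Dict[str, float]:
    """Per-criterion arithmetic means, half-up rounded to 2 decimals."""
    return {
        criterion: round_half_up(float(np.mean(values)), 2)
        for criterion, values in matrix.scores.items()
    }


def anova_one_way(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Classical equal-variance one-way ANOVA: ``(F, upper-tail p)``.

    Degenerate all-identical input (zero within- and between-group
    variance) is reported as ``F = 0, p = 1`` rather than NaN.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InsufficientData("need >= 2 groups with >= 2 values each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if np.ptp(np.concatenate(arrays)) == 0.0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


@dataclass(frozen=True)
class EvaluationReport:
    """Run-by-run summary in the shape of the published results table."""

    records: Tuple[RunRecord, ...]
    summaries: Tuple[RunSummary, ...]
    min_run_mean: float
    max_run_mean: float
    rating_means: Optional[Dict[str, float]] = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec, s in zip(self.records, self.summaries):
            row = {
                "run": rec.run_id,
                "investigator": rec.investigator,
                "mode": rec.mode,
            }
            for i, e in enumerate(rec.errors, start=1):
                row[f"target_{i}_mm"] = round_half_up(e, 1)
            row["mean_mm"] = s.mean_mm
            row["min_mm"] = round_half_up(s.min_mm, 1)
            row["max_mm"] = round_half_up(s.max_mm, 1)
            row["fre_mm"] = rec.fre
            row["time_s"] = rec.time_s
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def format_text(self) -> str:
        lines = [self.to_frame().to_string(index=False)]
        lines.append(
            f"run means range: {self.min_run_mean:.1f} - {self.max_run_mean:.1f} mm"
        )
        if self.rating_means is not None:
            lines.append("ratings (mean / 5): " + ", ".join(
                f"{k}={v:g}" for k, v in self.rating_means.items()
            ))
        return "\n".join(lines)


def build_report(
    records: Sequence[RunRecord], ratings: Optional[RatingMatrix] = None
) -> EvaluationReport:
    """Assemble the evaluation report, recomputing every summary statistic."""
    if not records:
        raise EmptyErrors("no runs to report")
    summaries = tuple(summarize_run(r) for r in records)
    means = [s.mean_mm for s in summaries]
    return EvaluationReport(
        records=tuple(records),
        summaries=summaries,
        min_run_mean=min(means),
        max_run_mean=max(means),
        rating_means=rating_summary(ratings) if ratings is not None else None,
    )


# ---------------------------------------------------------------------------
# packaged worked-example fixtures (published per-run measurements)


def _data_path(name: str) -> Path:
    return Path(resources.files("emnav").joinpath("data", name))


def load_table1_runs() -> List[RunRecord]:
    """Published per-target navigation errors, FRE and times for 6 runs."""
    df = pd.read_csv(_data_path("table1_runs.csv"))
    records = []
    for _, row in df.iterrows():
        errors = tuple(float(row[f"target_{i}"]) for i in range(1, 8))
        records.append(
            RunRecord(
                run_id=int(row["run"]),
                investigator=int(row["investigator"]),
                mode=str(row["mode"]),
                errors=errors,
                fre=float(row["fre_mm"]),
                time_s=float(row["time_s"]),
            )
        )
    return records


def load_table2_ratings() -> RatingMatrix:
    """Published four-investigator ratings for the three criteria."""
    df = pd.read_csv(_data_path("table2_ratings.csv"))
    return RatingMatrix(
        {c: tuple(int(v) for v in df[c]) for c in RATING_CRITERIA}
    )
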