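"""Cohort QC reports: verdict tables, summaries and scatter coordinates."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

CATEGORIES = ("correct", "misclassified", "unconfident", "unannotated")
MISLABEL_DIRECTIONS = ("female_as_male", "male_as_female")


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """``100 * count / total`` rounded half-up to ``decimals`` places.

    An empty denominator yields 0.0.
    """
    if total == 0:
        return 0.0
    quantum = Decimal(1).scaleb(-decimals)
    value = Decimal(count) * 100 / Decimal(total)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SampleVerdict:
    """Per-sample outcome of the sex classifier vs. the annotation."""

    sample_id: str
    annotated_sex: str
    predicted_sex: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"invalid category {self.category!r}")


@dataclass(frozen=True)
class CohortReport:
    """Aggregated classification outcome for one cohort.

    ``mislabel_directions['female_as_male']`` counts misclassified samples
    whose expression-predicted sex is female but whose annotation says male
    (a female sample filed under a male label), and vice versa.
    """

    cohort_id: str
    n_samples: int
    counts: dict[str, int]
    mislabel_directions: dict[str, int] = field(
        default_factory=lambda: {d: 0 for d in MISLABEL_DIRECTIONS}
    )
    verdicts: tuple[SampleVerdict, ...] = ()

    def __post_init__(self) -> None:
        counts = {c: int(self.counts.get(c, 0)) for c in CATEGORIES}
        object.__setattr__(self, "counts", counts)
        if sum(counts.values()) != self.n_samples:
            raise ValueError(
                f"category counts {counts} do not sum to n_samples={self.n_samples}"
            )
        directions = {
            d: int(self.mislabel_directions.get(d, 0)) for d in MISLABEL_DIRECTIONS
        }
        object.__setattr__(self, "mislabel_directions", directions)

    @property
    def percentages(self) -> dict[str, float]:
        return {c: percentage(self.counts[c], self.n_samples) for c in CATEGORIES}

    @classmethod
    def from_verdicts(
        cls, cohort_id: str, verdicts: Sequence[SampleVerdict]
    ) -> "CohortReport":
        counts = {c: 0 for c in CATEGORIES}
        directions = {d: 0 for d in MISLABEL_DIRECTIONS}
        for v in verdicts:
            counts[v.category] += 1
            if v.category == "misclassified":
                if v.predicted_sex == "female" and v.annotated_sex == "male":
                    directions["female_as_male"] += 1
                elif v.predicted_sex == "male" and v.annotated_sex == "female":
                    directions["male_as_female"] += 1
        return cls(
            cohort_id=cohort_id,
            n_samples=len(verdicts),
            counts=counts,
            mislabel_directions=directions,
            verdicts=tuple(verdicts),
        )


def write_cohort_report(
    report: CohortReport, path: str | Path, format: str = "json"
) -> None:
    """Write a cohort report as JSON or as a TSV verdict table.

    The TSV layout stores the summary in "#"-prefixed header lines followed
    by one verdict row per sample; both formats round-trip through
    :func:`read_cohort_report`.
    """
    path = Path(path)
    if format == "json":
        payload = {
            "cohort_id": report.cohort_id,
            "n_samples": report.n_samples,
            "counts": report.counts,
            "percentages": report.percentages,
            "mislabel_directions": report.mislabel_directions,
            "verdicts": [
                {
                    "sample_id": v.sample_id,
                    "annotated_sex": v.annotated_sex,
                    "predicted_sex": v.predicted_sex,
                    "category": v.category,
                }
                for v in report.verdicts
            ],
        }
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    elif format == "tsv":
        with open(path, "w", encoding="utf-8") as out:
            out.write(f"# cohort_id={report.cohort_id}\n")
            out.write(f"# n_samples={report.n_samples}\n")
            for cat in CATEGORIES:
                out.write(
                    f"# {cat}={report.counts[cat]} ({report.percentages[cat]:.1f})\n"
                )
            for direction in MISLABEL_DIRECTIONS:
                out.write(f"# {direction}={report.mislabel_directions[direction]}\n")
            out.write("sample_id\tannotated_sex\tpredicted_sex\tcategory\n")
            for v in report.verdicts:
                out.write(
                    f"{v.sample_id}\t{v.annotated_sex}\t{v.predicted_sex}\t{v.category}\n"
                )
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_cohort_report(path: str | Path, format: str | None = None) -> CohortReport:
    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "tsv"
    if format == "json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        verdicts = tuple(
            SampleVerdict(
                sample_id=v["sample_id"],
                annotated_sex=v["annotated_sex"],
                predicted_sex=v["predicted_sex"],
                category=v["category"],
            )
            for v in payload.get("verdicts", [])
        )
        return CohortReport(
            cohort_id=payload["cohort_id"],
            n_samples=payload["n_samples"],
            counts=payload["counts"],
            mislabel_directions=payload.get("mislabel_directions", {}),
            verdicts=verdicts,
        )
    if format == "tsv":
        cohort_id = "cohort"
        verdicts: list[SampleVerdict] = []
        with open(path, encoding="utf-8") as handle:
            for line in handle:
                line = line.rstrip("\n")
                if line.startswith("# cohort_id="):
                    cohort_id = line.split("=", 1)[1]
                    continue
                if line.startswith("#") or line.startswith("sample_id\t") or not line:
                    continue
                sid, annotated, predicted, category = line.split("\t")
                verdicts.append(SampleVerdict(sid, annotated, predicted, category))
        return CohortReport.from_verdicts(cohort_id, verdicts)
    raise ValueError(f"unknown report format {format!r}")


def export_sex_scatter(
    x_means: Sequence[float],
    y_means: Sequence[float],
    verdicts: Sequence[SampleVerdict],
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Per-sample scatter coordinates: mean normalized female-evidence
    (x axis) vs. male-evidence (y axis) marker values plus the category.

    Samples with no usable marker on an axis carry missing coordinates.
    """
    if not (len(x_means) == len(y_means) == len(verdicts)):
        raise ValueError("x, y and verdicts must have equal length")
    frame = pd.DataFrame(
        {
            "sample_id": [v.sample_id for v in verdicts],
            "x_female_markers": np.asarray(x_means, dtype=float),
            "y_male_markers": np.asarray(y_means, dtype=float),
            "category": [v.category for v in verdicts],
        }
    )
    if path is not None:
        frame.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return frame
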