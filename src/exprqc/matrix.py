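"""Expression matrices, sex annotations and their TSV readers."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_SEX_SYNONYMS

logger = logging.getLogger(__name__)

SEX_LABELS = ("female", "male", "unknown")


class PairingError(ValueError):
    """Raised when a matrix and an annotation share no sample IDs."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for name in ids:
        if name in seen:
            raise ValueError(f"duplicate {what} ID: {name!r}")
        seen.add(name)


@dataclass(frozen=True, eq=False)
class ExpressionMatrix:
    """Probe-by-sample grid of log-scale expression values.

    Missing measurements are NaN; all other entries must be finite. Input
    matrices are assumed to already be on a log scale (no further
    transformation is applied anywhere in the pipeline).
    """

    probe_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.probe_ids) == 0 or len(self.sample_ids) == 0:
            raise ValueError("expression matrix must be non-empty")
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.sample_ids, "sample")
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if np.isinf(values).any():
            raise ValueError("expression values must be finite or missing (NaN)")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def probe_index(self, probe_id: str) -> int:
        try:
            return self.probe_ids.index(probe_id)
        except ValueError:
            raise KeyError(f"probe {probe_id!r} not in matrix") from None

    def probe_values(self, probe_id: str) -> np.ndarray:
        """Row of values for one probe, aligned with ``sample_ids``."""
        return self.values[self.probe_index(probe_id)]

    def subset_probes(self, probe_ids: Iterable[str]) -> "ExpressionMatrix":
        wanted = list(probe_ids)
        rows = [self.probe_index(p) for p in wanted]
        return ExpressionMatrix(tuple(wanted), self.sample_ids, self.values[rows])

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        wanted = list(sample_ids)
        lookup = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [lookup[s] for s in wanted]
        return ExpressionMatrix(self.probe_ids, tuple(wanted), self.values[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.probe_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            tuple(str(p) for p in frame.index),
            tuple(str(s) for s in frame.columns),
            frame.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class SexAnnotation:
    """Map from sample ID to a canonical sex label.

    Labels are restricted to ``female`` / ``male`` / ``unknown``; anything
    the reader cannot interpret becomes ``unknown``.
    """

    labels: Mapping[str, str]
    survival: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for sample, label in self.labels.items():
            if label not in SEX_LABELS:
                raise ValueError(
                    f"invalid sex label {label!r} for sample {sample!r}"
                )

    def __len__(self) -> int:
        return len(self.labels)

    def label_of(self, sample_id: str) -> str:
        return self.labels.get(sample_id, "unknown")

    def align(self, sample_ids: Sequence[str]) -> list[str]:
        """Labels aligned to ``sample_ids``; absent samples are unknown.

        Raises :class:`PairingError` when the annotation is non-empty but
        shares no IDs at all with the requested samples.
        """
        if self.labels and not set(sample_ids) & set(self.labels):
            missing = sorted(sample_ids)[:10]
            extra = sorted(self.labels)[:10]
            raise PairingError(
                "annotation and matrix share no sample IDs; "
                f"matrix has e.g. {missing}, annotation has e.g. {extra}"
            )
        return [self.label_of(s) for s in sample_ids]


def _read_table_lines(path: Path, dialect: str) -> list[str]:
    raw = path.read_text(encoding="utf-8").splitlines()
    if dialect == "plain":
        return [line for line in raw if line.strip()]
    if dialect != "series_matrix":
        raise ValueError(f"unknown dialect {dialect!r}")
    begin = [i for i, l in enumerate(raw) if l.startswith("!series_matrix_table_begin")]
    end = [i for i, l in enumerate(raw) if l.startswith("!series_matrix_table_end")]
    if begin and end:
        raw = raw[begin[0] + 1 : end[0]]
    lines = [l for l in raw if l.strip() and not l.startswith("!")]
    return lines


def read_expression_tsv(
    path: str | Path, dialect: str = "plain"
) -> ExpressionMatrix:
    """Read a tab-delimited expression table.

    The first column holds probe IDs and the header row sample IDs. The
    ``series_matrix`` dialect additionally skips "!"-prefixed metadata lines
    and the ``!series_matrix_table_begin`` / ``_end`` guards. Non-numeric
    cells become missing (NaN); duplicate probe or sample IDs are a hard
    error.
    """
    path = Path(path)
    lines = _read_table_lines(path, dialect)
    if len(lines) < 2:
        raise ValueError(f"{path}: no expression table found")
    header = lines[0].rstrip("\n").split("\t")
    sample_ids = [h.strip().strip('"') for h in header[1:]]
    if not sample_ids:
        raise ValueError(f"{path}: header row contains no sample IDs")
    _check_unique(sample_ids, "sample")
    probe_ids: list[str] = []
    rows: list[list[float]] = []
    for line in lines[1:]:
        cells = line.rstrip("\n").split("\t")
        probe = cells[0].strip().strip('"')
        row = []
        for cell in cells[1 : len(sample_ids) + 1]:
            try:
                row.append(float(cell.strip().strip('"')))
            except ValueError:
                row.append(np.nan)
        row.extend([np.nan] * (len(sample_ids) - len(row)))
        probe_ids.append(probe)
        rows.append(row)
    _check_unique(probe_ids, "probe")
    return ExpressionMatrix(
        tuple(probe_ids), tuple(sample_ids), np.asarray(rows, dtype=float)
    )


def write_expression_tsv(
    matrix: ExpressionMatrix, path: str | Path, dialect: str = "plain"
) -> None:
    """Write a matrix as TSV (values at 12 significant digits)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as out:
        if dialect == "series_matrix":
            out.write("!Series_title\tsynthetic\n")
            out.write("!series_matrix_table_begin\n")
        out.write("ID_REF\t" + "\t".join(matrix.sample_ids) + "\n")
        for probe, row in zip(matrix.probe_ids, matrix.values):
            cells = ["" if np.isnan(v) else format(v, ".12g") for v in row]
            out.write(probe + "\t" + "\t".join(cells) + "\n")
        if dialect == "series_matrix":
            out.write("!series_matrix_table_end\n")


def normalize_sex_label(value: object, synonyms: Mapping[str, str] | None = None) -> str:
    """Canonicalize a raw sex annotation; unrecognized values -> unknown."""
    table = DEFAULT_SEX_SYNONYMS if synonyms is None else synonyms
    text = "" if value is None or (isinstance(value, float) and np.isnan(value)) else str(value)
    label = table.get(text.strip().lower())
    if label is None:
        logger.warning("unrecognized sex label %r treated as unknown", value)
        return "unknown"
    return label


def read_annotation_tsv(
    path: str | Path, synonyms: Mapping[str, str] | None = None
) -> SexAnnotation:
    """Read a sample annotation table with columns sample_id, sex.

    Optional ``time`` and ``event`` columns are carried along as a survival
    table indexed by sample ID.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    if "sample_id" not in frame.columns:
        raise ValueError(f"{path}: required column 'sample_id' is missing")
    if "sex" not in frame.columns:
        raise ValueError(f"{path}: required column 'sex' is missing")
    sample_ids = [str(s).strip() for s in frame["sample_id"]]
    _check_unique(sample_ids, "sample")
    labels = {
        sid: normalize_sex_label(raw, synonyms)
        for sid, raw in zip(sample_ids, frame["sex"])
    }
    survival = None
    if {"time", "event"} <= set(frame.columns):
        survival = pd.DataFrame(
            {
                "time": pd.to_numeric(frame["time"], errors="coerce").to_numpy(),
                "event": pd.to_numeric(frame["event"], errors="coerce").to_numpy(),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    return SexAnnotation(labels=labels, survival=survival)


def write_annotation_tsv(annotation: SexAnnotation, path: str | Path) -> None:
    path = Path(path)
    rows = []
    for sid, label in annotation.labels.items():
        row: dict[str, object] = {"sample_id": sid, "sex": label}
        if annotation.survival is not None and sid in annotation.survival.index:
            row["time"] = annotation.survival.loc[sid, "time"]
            row["event"] = int(annotation.survival.loc[sid, "event"])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
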