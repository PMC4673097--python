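"""Marker panels for the male-female expression classifier."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd


@dataclass(frozen=True)
class MarkerProbe:
    """One sex-informative probe set.

    ``evidence_sex`` is the sex for which high expression of the probe is
    evidence: X-chromosomal markers (XIST) give female evidence, the
    Y-chromosomal markers give male evidence.
    """

    probe_id: str
    gene: str
    chromosome: str
    evidence_sex: str

    def __post_init__(self) -> None:
        if self.chromosome not in ("X", "Y"):
            raise ValueError(f"chromosome must be X or Y, got {self.chromosome!r}")
        if self.evidence_sex not in ("female", "male"):
            raise ValueError(
                f"evidence_sex must be female or male, got {self.evidence_sex!r}"
            )


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered collection of marker probes (female-evidence first)."""

    probes: tuple[MarkerProbe, ...]

    def __post_init__(self) -> None:
        ids = [p.probe_id for p in self.probes]
        if len(set(ids)) != len(ids):
            raise ValueError("marker panel contains duplicate probe IDs")

    def __iter__(self) -> Iterator[MarkerProbe]:
        return iter(self.probes)

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def probe_ids(self) -> tuple[str, ...]:
        return tuple(p.probe_id for p in self.probes)

    @property
    def female_probes(self) -> tuple[MarkerProbe, ...]:
        return tuple(p for p in self.probes if p.evidence_sex == "female")

    @property
    def male_probes(self) -> tuple[MarkerProbe, ...]:
        return tuple(p for p in self.probes if p.evidence_sex == "male")

    def get(self, probe_id: str) -> MarkerProbe:
        for probe in self.probes:
            if probe.probe_id == probe_id:
                return probe
        raise KeyError(probe_id)

    @classmethod
    def from_probes(cls, probes: Sequence[MarkerProbe]) -> "MarkerPanel":
        ordered = tuple(
            sorted(probes, key=lambda p: (p.evidence_sex != "female", p.probe_id))
        )
        return cls(ordered)


#: Default 4-probe panel: two XIST probe sets (female evidence) and one
#: probe set each for RPS4Y1 and DDX3Y (male evidence).
DEFAULT_PANEL = MarkerPanel(
    (
        MarkerProbe("221728_x_at", "XIST", "X", "female"),
        MarkerProbe("214218_s_at", "XIST", "X", "female"),
        MarkerProbe("201909_at", "RPS4Y1", "Y", "male"),
        MarkerProbe("205000_at", "DDX3Y", "Y", "male"),
    )
)

#: Published normalized-scale cut points for the default panel; used in
#: deployment mode instead of per-cohort cut estimation.
DEFAULT_FIXED_CUTS: dict[str, float] = {
    "221728_x_at": 0.389,
    "214218_s_at": 0.385,
    "201909_at": 0.431,
    "205000_at": 0.276,
}


def read_marker_panel_tsv(path: str | Path) -> MarkerPanel:
    """Read a marker panel from a TSV with columns
    probe_id, gene, chromosome, evidence_sex."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"probe_id", "gene", "chromosome", "evidence_sex"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"marker panel is missing columns: {sorted(missing)}")
    probes = [
        MarkerProbe(
            probe_id=row.probe_id.strip(),
            gene=row.gene.strip(),
            chromosome=row.chromosome.strip(),
            evidence_sex=row.evidence_sex.strip().lower(),
        )
        for row in frame.itertuples()
    ]
    return MarkerPanel(tuple(probes))
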