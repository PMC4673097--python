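"""Pipeline configuration shared across the QC steps."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

#: Accepted spellings for sex labels; anything else maps to "unknown".
DEFAULT_SEX_SYNONYMS: dict[str, str] = {
    "f": "female",
    "female": "female",
    "w": "female",
    "woman": "female",
    "m": "male",
    "male": "male",
    "man": "male",
    "unknown": "unknown",
    "na": "unknown",
    "n/a": "unknown",
    "": "unknown",
}


@dataclass
class PipelineConfig:
    """Tunable parameters for the sex-classification and duplicate pipelines.

    Attributes
    ----------
    quantile_level:
        Upper-tail probability of the normal fitted to the low-expression
        group; values above the corresponding quantile count as evidence.
    sep_min:
        Minimum separation (median gap over summed Qn scales) for a
        two-group split to be accepted as bimodal.
    min_group:
        Smallest admissible group size in the two-group split.
    single_sex_majority:
        Fraction of labelled samples of one sex above which a cohort is
        treated as single-sex when a probe is not bimodal.
    reference_scale:
        Fallback high-minus-low span used to scale single-sex cohorts when
        no pooled estimate is available.
    default_high_cut:
        Normalized-scale cut used for a probe whose only observed group is
        the high group and no pooled cut is available.
    fixed_cuts:
        Optional probe_id -> cut mapping (normalized scale) overriding the
        per-cohort cut computation (deployment mode).
    marker_missing_max_frac:
        During marker selection, probes missing in more than this fraction
        of a dataset's samples are skipped for that dataset.
    top_k_variance:
        Number of highest-variance probes used for duplicate detection.
    r_min:
        Correlations below this value are never reported as duplicates.
    max_frac:
        Upper bound on the fraction of all pairs that may sit above the
        correlation gap (at least one pair is always admissible).
    alpha:
        Unadjusted significance threshold for the survival screen.
    sex_synonyms:
        Mapping from lower-cased annotation strings to canonical labels.
    """

    quantile_level: float = 0.999
    sep_min: float = 3.0
    min_group: int = 2
    single_sex_majority: float = 0.9
    reference_scale: float = 1.0
    default_high_cut: float = 0.5
    fixed_cuts: dict[str, float] | None = None
    marker_missing_max_frac: float = 0.2
    top_k_variance: int = 1000
    r_min: float = 0.95
    max_frac: float = 0.1
    alpha: float = 0.01
    sex_synonyms: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SEX_SYNONYMS)
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.quantile_level < 1.0:
            raise ValueError("quantile_level must lie in (0, 1)")
        if self.min_group < 1:
            raise ValueError("min_group must be >= 1")
        if self.sep_min < 0:
            raise ValueError("sep_min must be >= 0")
        if self.reference_scale <= 0:
            raise ValueError("reference_scale must be > 0")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, Mapping):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_mapping(data)

    def replace(self, **changes: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **changes)


DEFAULT_CONFIG = PipelineConfig()
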