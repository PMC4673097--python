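"""Synthetic multi-cohort expression data with known ground truth.

Generates cohorts with bimodal sex-specific marker expression, background
probes, cohort-level affine shifts, injected sex mislabels, injected
near-exact duplicate measurements and optional exponential survival times
driven by designated prognostic probes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, SexAnnotation
from .panel import DEFAULT_PANEL, MarkerPanel


@dataclass(frozen=True)
class MarkerGeometry:
    """Low/high component parameters for one marker probe."""

    mu_low: float = 6.0
    mu_high: float = 10.0
    sd_low: float = 0.4
    sd_high: float = 0.4

    def __post_init__(self) -> None:
        if not self.mu_high > self.mu_low:
            raise ValueError("mu_high must exceed mu_low")
        if self.sd_low < 0 or self.sd_high < 0:
            raise ValueError("marker standard deviations must be >= 0")


@dataclass(frozen=True)
class SurvivalParams:
    """Exponential survival model: log-hazard linear in prognostic probes."""

    baseline_scale: float = 50.0
    censor_rate: float = 0.2
    prognostic_probe_ids: tuple[str, ...] = ()
    effect_sizes: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.prognostic_probe_ids) != len(self.effect_sizes):
            raise ValueError("one effect size per prognostic probe required")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must lie in [0, 1]")
        if not np.all(np.isfinite(self.effect_sizes)):
            raise ValueError("effect sizes must be finite")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one simulated cohort."""

    n_samples: int = 100
    female_fraction: float = 0.5
    n_background_probes: int = 50
    marker_geometry: Mapping[str, MarkerGeometry] = field(default_factory=dict)
    cohort_shift: float = 0.0
    cohort_scale: float = 1.0
    mislabel_rate: float = 0.0
    n_duplicates: int = 0
    duplicate_noise_sd: float = 0.01
    survival: SurvivalParams | None = None
    cohort_id: str = "SIM"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must lie in [0, 1]")
        if not self.cohort_scale > 0:
            raise ValueError("cohort_scale must be > 0")
        if not 0.0 <= self.mislabel_rate <= 1.0:
            raise ValueError("mislabel_rate must lie in [0, 1]")
        if self.n_duplicates < 0 or self.duplicate_noise_sd < 0:
            raise ValueError("duplicate parameters must be >= 0")
        if self.n_duplicates >= self.n_samples:
            raise ValueError("n_duplicates must be smaller than n_samples")


@dataclass(frozen=True)
class GroundTruth:
    """What was actually simulated, for scoring the QC methods."""

    true_sex: dict[str, str]
    mislabeled: tuple[str, ...]
    duplicate_pairs: tuple[tuple[str, str], ...]
    survival: pd.DataFrame | None = None


def _flip(label: str) -> str:
    return "male" if label == "female" else "female"


def simulate_survival(
    covariates: np.ndarray,
    effect_sizes: Sequence[float],
    baseline_scale: float,
    censor_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw exponential survival times with log-hazard linear in covariates.

    ``covariates`` is (n_probes, n_samples); each row is standardized so an
    effect size of 1 acts per standard deviation. Events are censored
    independently with probability ``censor_rate``; censored observation
    times are drawn uniformly before the event time.
    """
    beta = np.asarray(effect_sizes, dtype=float)
    n = covariates.shape[1] if covariates.ndim == 2 else len(covariates)
    if beta.size:
        z = np.asarray(covariates, dtype=float)
        sd = z.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (z - z.mean(axis=1, keepdims=True)) / sd
        log_hazard = beta @ z
    else:
        log_hazard = np.zeros(n)
    hazard = np.exp(log_hazard) / baseline_scale
    times = rng.exponential(1.0 / hazard)
    events = (rng.random(n) >= censor_rate).astype(int)
    censored = events == 0
    times[censored] = times[censored] * rng.random(int(censored.sum()))
    return times, events


def simulate_cohort(
    config: SyntheticConfig,
    panel: MarkerPanel = DEFAULT_PANEL,
) -> tuple[ExpressionMatrix, SexAnnotation, GroundTruth]:
    """Simulate one cohort with markers, mislabels, duplicates and survival.

    True sex is drawn from ``female_fraction``. Female-evidence markers are
    high in females and low in males; male-evidence markers mirror that.
    Background probes are i.i.d. standard normal. The whole matrix is then
    transformed by ``cohort_scale * x + cohort_shift``.

    Exactly ``round(mislabel_rate * n_samples)`` samples get a flipped sex
    label (record mix-up: when survival is simulated, a mislabeled sample
    also carries the survival record of another random sample). Duplicates
    re-measure a random original (copy plus noise) under a new sample ID
    with the sex label and record of a randomly chosen other sample.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    cid = config.cohort_id
    sample_ids = [f"{cid}_s{i:04d}" for i in range(n)]
    true_sex = np.where(rng.random(n) < config.female_fraction, "female", "male")

    geometry = {
        probe.probe_id: config.marker_geometry.get(probe.probe_id, MarkerGeometry())
        for probe in panel
    }
    probe_ids = list(panel.probe_ids) + [
        f"bg_{i:05d}" for i in range(config.n_background_probes)
    ]
    rows = []
    for probe in panel:
        geo = geometry[probe.probe_id]
        high = (true_sex == "female") == (probe.evidence_sex == "female")
        row = np.where(
            high,
            rng.normal(geo.mu_high, geo.sd_high, n),
            rng.normal(geo.mu_low, geo.sd_low, n),
        )
        rows.append(row)
    background = rng.normal(0.0, 1.0, (config.n_background_probes, n))
    values = np.vstack([np.vstack(rows), background]) if rows else background

    # Sex labels: true sex with a fixed number of cross-sex flips.
    labels = dict(zip(sample_ids, true_sex))
    n_flips = round(config.mislabel_rate * n)
    mislabeled = sorted(
        sample_ids[i] for i in rng.choice(n, size=n_flips, replace=False)
    )
    for sid in mislabeled:
        labels[sid] = _flip(labels[sid])

    # Survival records, driven by the designated prognostic probes.
    survival_frame = None
    if config.survival is not None:
        params = config.survival
        probe_index = {p: i for i, p in enumerate(probe_ids)}
        missing = [p for p in params.prognostic_probe_ids if p not in probe_index]
        if missing:
            raise ValueError(f"prognostic probes not simulated: {missing}")
        covariates = values[[probe_index[p] for p in params.prognostic_probe_ids]]
        times, events = simulate_survival(
            covariates,
            params.effect_sizes,
            params.baseline_scale,
            params.censor_rate,
            rng,
        )
        # Record mix-up: a mislabeled sample keeps someone else's record.
        donor = {
            sid: sample_ids[_random_other(rng, n, i)]
            for i, sid in enumerate(sample_ids)
            if sid in set(mislabeled)
        }
        record = {sid: (times[i], events[i]) for i, sid in enumerate(sample_ids)}
        for sid, other in donor.items():
            record[sid] = record[other]
        survival_rows = {sid: record[sid] for sid in sample_ids}
    else:
        survival_rows = None

    # Duplicates: copy + noise with a new ID and another sample's label.
    duplicate_pairs: list[tuple[str, str]] = []
    if config.n_duplicates:
        originals = rng.choice(n, size=config.n_duplicates, replace=False)
        for d, orig in enumerate(originals):
            dup_id = f"{cid}_dup{d:03d}"
            column = values[:, orig] + rng.normal(
                0.0, config.duplicate_noise_sd * config.cohort_scale, values.shape[0]
            )
            values = np.column_stack([values, column])
            donor_idx = _random_other(rng, n, int(orig))
            labels[dup_id] = labels[sample_ids[donor_idx]]
            sample_ids.append(dup_id)
            duplicate_pairs.append((f"{cid}_s{orig:04d}", dup_id))
            true_sex = np.append(true_sex, true_sex[orig])
            if survival_rows is not None:
                survival_rows[dup_id] = survival_rows[sample_ids[donor_idx]]

    values = config.cohort_scale * values + config.cohort_shift

    if survival_rows is not None:
        survival_frame = pd.DataFrame(
            {
                "time": [survival_rows[s][0] for s in sample_ids],
                "event": [int(survival_rows[s][1]) for s in sample_ids],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )

    matrix = ExpressionMatrix(tuple(probe_ids), tuple(sample_ids), values)
    annotation = SexAnnotation(
        labels={s: labels[s] for s in sample_ids}, survival=survival_frame
    )
    truth = GroundTruth(
        true_sex={s: str(t) for s, t in zip(sample_ids, true_sex)},
        mislabeled=tuple(mislabeled),
        duplicate_pairs=tuple(duplicate_pairs),
        survival=survival_frame,
    )
    return matrix, annotation, truth


def _random_other(rng: np.random.Generator, n: int, index: int) -> int:
    """Uniform draw from {0..n-1} excluding ``index`` (n >= 2)."""
    draw = int(rng.integers(n - 1))
    return draw + 1 if draw >= index else draw


def load_cohort_groups() -> pd.DataFrame:
    """Packaged reference composition of the 45-cohort benchmark, grouped
    by disease type (sample sizes and female/male splits)."""
    with importlib.resources.files("exprqc.data").joinpath(
        "cohort_groups.tsv"
    ).open() as handle:
        return pd.read_csv(handle, sep="\t")


def load_benchmark_cohorts() -> pd.DataFrame:
    """Packaged per-cohort female/male composition of the 45-cohort
    benchmark scenario."""
    with importlib.resources.files("exprqc.data").joinpath(
        "benchmark_cohorts.tsv"
    ).open() as handle:
        return pd.read_csv(handle, sep="\t")


def benchmark_configs(
    seed: int = 0,
    mislabel_rate: float = 0.01,
    n_background_probes: int = 20,
    shift_range: tuple[float, float] = (-3.0, 3.0),
    scale_range: tuple[float, float] = (0.8, 1.25),
) -> list[SyntheticConfig]:
    """Configs for a 45-cohort benchmark run mirroring a realistic mix of
    mixed-sex, all-female and all-male cohorts with per-cohort affine
    shifts."""
    table = load_benchmark_cohorts()
    rng = np.random.default_rng(seed)
    configs = []
    for row in table.itertuples():
        n = int(row.n_female + row.n_male)
        configs.append(
            SyntheticConfig(
                n_samples=n,
                female_fraction=row.n_female / n,
                n_background_probes=n_background_probes,
                cohort_shift=float(rng.uniform(*shift_range)),
                cohort_scale=float(rng.uniform(*scale_range)),
                mislabel_rate=mislabel_rate,
                cohort_id=str(row.cohort_id),
                seed=int(rng.integers(2**31 - 1)),
            )
        )
    return configs


def simulate_benchmark(
    seed: int = 0, **kwargs
) -> list[tuple[str, ExpressionMatrix, SexAnnotation, GroundTruth]]:
    """Simulate the full 45-cohort benchmark scenario."""
    out = []
    for config in benchmark_configs(seed=seed, **kwargs):
        matrix, annotation, truth = simulate_cohort(config)
        out.append((config.cohort_id, matrix, annotation, truth))
    return out
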