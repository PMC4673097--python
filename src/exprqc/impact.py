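"""Downstream impact of flagged samples on a per-gene survival screen.

Fits a univariate proportional-hazards model per probe (expression as the
single covariate; Efron handling of tied event times; Wald p-values) and
quantifies significance churn between the original cohort and the cohort
with flagged samples removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .matrix import ExpressionMatrix
from .report import percentage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChurnResult:
    """Significance churn after sample removal, relative to the original
    set of significant probes. Percentages are None when nothing was
    significant originally."""

    n_original_significant: int
    pct_no_longer_significant: float | None
    pct_newly_significant: float | None
    alpha: float


def _cox_newton(
    x: np.ndarray,
    order: np.ndarray,
    event_groups: list[tuple[int, np.ndarray]],
    max_iter: int = 50,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Newton-Raphson for P independent single-covariate Cox models.

    ``x`` is (P, S) with covariates already standardized; ``order`` sorts
    samples by ascending time; ``event_groups`` lists, per unique event
    time, the position of the first at-risk sample in the sorted order and
    the sorted positions of the tied events. Returns (beta, information,
    converged).
    """
    xs = x[:, order]
    P, S = xs.shape
    beta = np.zeros(P)
    converged = np.zeros(P, dtype=bool)
    info = np.full(P, np.nan)
    for _ in range(max_iter):
        eta = np.clip(beta[:, None] * xs, -500, 500)
        theta = np.exp(eta)
        tx = theta * xs
        txx = tx * xs
        # Suffix sums over the time-sorted axis: risk-set aggregates.
        s0 = np.cumsum(theta[:, ::-1], axis=1)[:, ::-1]
        s1 = np.cumsum(tx[:, ::-1], axis=1)[:, ::-1]
        s2 = np.cumsum(txx[:, ::-1], axis=1)[:, ::-1]
        score = np.zeros(P)
        information = np.zeros(P)
        for first, members in event_groups:
            d = members.size
            r0, r1, r2 = s0[:, first], s1[:, first], s2[:, first]
            score += xs[:, members].sum(axis=1)
            if d == 1:
                mean = r1 / r0
                score -= mean
                information += r2 / r0 - mean**2
            else:
                d0 = theta[:, members].sum(axis=1)
                d1 = tx[:, members].sum(axis=1)
                d2 = txx[:, members].sum(axis=1)
                for l in range(d):
                    f = l / d
                    denom = r0 - f * d0
                    num1 = r1 - f * d1
                    num2 = r2 - f * d2
                    mean = num1 / denom
                    score -= mean
                    information += num2 / denom - mean**2
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(information > 0, score / information, 0.0)
        step = np.clip(step, -5.0, 5.0)
        active = ~converged
        beta[active] += step[active]
        info = information
        newly = np.abs(step) < tol
        converged |= newly
        if converged.all():
            break
    return beta, info, converged


def univariate_survival_screen(
    matrix: ExpressionMatrix,
    survival: pd.DataFrame,
) -> tuple[pd.Series, dict[str, str]]:
    """Wald p-value of a univariate proportional-hazards fit per probe.

    ``survival`` must carry ``time`` and ``event`` columns indexed (or
    orderable) by the matrix sample IDs. Probes with zero variance, any
    missing value, or a non-converged fit are skipped; the returned dict
    maps skipped probe IDs to the reason. All fits run simultaneously via
    a vectorized Newton-Raphson (Efron approximation for ties).
    """
    if isinstance(survival.index, pd.Index) and set(matrix.sample_ids) <= set(
        map(str, survival.index)
    ):
        survival = survival.loc[list(matrix.sample_ids)]
    elif len(survival) != len(matrix.sample_ids):
        raise ValueError("survival table does not match the matrix samples")
    time = survival["time"].to_numpy(dtype=float)
    event = survival["event"].to_numpy(dtype=int)
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("survival times must be finite and > 0")
    if event.sum() < 2:
        raise ValueError("survival screen requires at least 2 events")

    skipped: dict[str, str] = {}
    values = matrix.values
    has_missing = np.isnan(values).any(axis=1)
    sds = np.nanstd(values, axis=1)
    usable = ~has_missing & (sds > 0)
    for i in np.flatnonzero(~usable):
        skipped[matrix.probe_ids[i]] = (
            "missing values" if has_missing[i] else "zero variance"
        )
    pvalues = pd.Series(np.nan, index=list(matrix.probe_ids), dtype=float)
    idx = np.flatnonzero(usable)
    if idx.size == 0:
        return pvalues, skipped

    x = values[idx]
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    order = np.argsort(time, kind="stable")
    sorted_time = time[order]
    sorted_event = event[order].astype(bool)
    event_groups: list[tuple[int, np.ndarray]] = []
    pos = 0
    S = len(order)
    while pos < S:
        end = pos
        while end + 1 < S and sorted_time[end + 1] == sorted_time[pos]:
            end += 1
        members = np.arange(pos, end + 1)[sorted_event[pos : end + 1]]
        if members.size:
            event_groups.append((pos, members))
        pos = end + 1

    beta, info, converged = _cox_newton(x, order, event_groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(info > 0, beta**2 * info, np.nan)
        p = chi2.sf(wald, df=1)
    for local, i in enumerate(idx):
        probe = matrix.probe_ids[i]
        if not converged[local] or not np.isfinite(p[local]):
            skipped[probe] = "did not converge"
        else:
            pvalues[probe] = p[local]
    return pvalues, skipped


def churn(
    p_original: Mapping[str, float] | pd.Series,
    p_reduced: Mapping[str, float] | pd.Series,
    alpha: float = 0.01,
) -> ChurnResult:
    """Significance churn between two p-value maps over the same probes.

    Probes lacking a p-value on either side (skipped or non-converged
    fits) are excluded from both significance sets symmetrically. The
    threshold is applied unadjusted.
    """
    po = pd.Series(p_original, dtype=float)
    pr = pd.Series(p_reduced, dtype=float)
    if set(po.index) != set(pr.index):
        raise ValueError("p-value maps must cover the same probe set")
    pr = pr.loc[po.index]
    valid = po.notna() & pr.notna()
    s0 = set(po.index[valid & (po < alpha)])
    s1 = set(po.index[valid & (pr < alpha)])
    if not s0:
        return ChurnResult(0, None, None, alpha)
    return ChurnResult(
        n_original_significant=len(s0),
        pct_no_longer_significant=percentage(len(s0 - s1), len(s0)),
        pct_newly_significant=percentage(len(s1 - s0), len(s0)),
        alpha=alpha,
    )
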