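"""Empirical-CDF marker criterion and per-feature distribution reports.

A channel j is a *marker* when the ion is systematically more intense
in the positive class: with P the empirical CDF of the positive-class
values, Q that of the negative class, and m_j the positive-class
median,

    delta_j = Q(m_j) - P(m_j) > beta,   0 < beta < 0.5,

together with dominance of Q over P everywhere above m_j
(Q(t) >= P(t) for all t > m_j). Because empirical CDFs are step
functions, dominance is checked exactly on the union of observed values
above m_j; no discretization grid is involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import POSITIVE_CLASS, IntensityMatrix

_DOMINANCE_EPS = 1e-12  # forgive float dust in k/n comparisons


class EmpiricalCDF:
    """Right-continuous empirical CDF: CDF(x) = fraction of values <= x."""

    def __init__(self, values: Iterable[float]):
        sorted_values = np.sort(np.asarray(list(values), dtype=float))
        if sorted_values.size == 0:
            raise ConfigError("empirical CDF needs at least one value")
        self._sorted = sorted_values

    @property
    def n(self) -> int:
        return self._sorted.size

    def __call__(self, x):
        counts = np.searchsorted(self._sorted, np.asarray(x, dtype=float), side="right")
        result = counts / self.n
        return float(result) if np.isscalar(x) or np.ndim(x) == 0 else result


def empirical_cdf(values: Iterable[float]) -> EmpiricalCDF:
    """Build the empirical CDF evaluator of ``values``."""
    return EmpiricalCDF(values)


@dataclass(frozen=True)
class MarkerDecision:
    """Marker-criterion outcome for one channel."""

    channel: int | None
    m_j: float
    p_at_m: float
    q_at_m: float
    delta: float
    dominance: bool
    beta: float
    is_marker: bool


def _check_beta(beta: float) -> None:
    if not 0 < beta < 0.5:
        raise ConfigError(f"beta must lie in (0, 0.5), got {beta}")


def marker_delta(
    pos_values: Sequence[float],
    neg_values: Sequence[float],
    beta: float = 0.4,
    channel: int | None = None,
) -> MarkerDecision:
    """Evaluate the CDF-difference marker criterion for one feature.

    ``m_j`` is the positive-class median (mean of the central pair for
    even n); ``delta = Q(m_j) - P(m_j)`` with P from the positive and Q
    from the negative sample. Dominance requires Q >= P at every
    observed value above ``m_j``.
    """
    _check_beta(beta)
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ConfigError("both class samples must be non-empty")
    p_cdf, q_cdf = EmpiricalCDF(pos), EmpiricalCDF(neg)
    m_j = float(np.median(pos))
    p_at_m, q_at_m = p_cdf(m_j), q_cdf(m_j)
    delta = q_at_m - p_at_m
    probes = np.unique(np.concatenate([pos, neg]))
    probes = probes[probes > m_j]
    dominance = bool(np.all(q_cdf(probes) + _DOMINANCE_EPS >= p_cdf(probes)))
    return MarkerDecision(
        channel=channel,
        m_j=m_j,
        p_at_m=p_at_m,
        q_at_m=q_at_m,
        delta=delta,
        dominance=dominance,
        beta=beta,
        is_marker=bool(delta > beta and dominance),
    )


def detect_markers(
    matrix: IntensityMatrix,
    channels: Sequence[int],
    beta: float = 0.4,
    patients: Iterable[str] | None = None,
) -> list[MarkerDecision]:
    """Apply the marker criterion to each channel, order preserved.

    Values are pooled across replicate vectors (one value per vector per
    channel). ``patients`` restricts the evaluation, e.g. to the fit
    partition; the default uses every row of ``matrix``.
    """
    _check_beta(beta)
    if len(channels) == 0:
        raise ConfigError("channel list must be non-empty")
    sub = matrix.subset_patients(patients) if patients is not None else matrix
    positive = sub.row_class == POSITIVE_CLASS
    decisions = []
    for mz_label in channels:
        col = sub.channel_values(mz_label)
        decisions.append(
            marker_delta(col[positive], col[~positive], beta=beta, channel=int(mz_label))
        )
    return decisions


def markers_frame(decisions: Sequence[MarkerDecision]) -> pd.DataFrame:
    """Tabulate decisions (channel, m_j, delta_j, dominance, is_marker)."""
    return pd.DataFrame(
        {
            "channel": [d.channel for d in decisions],
            "m_j": [d.m_j for d in decisions],
            "delta_j": [d.delta for d in decisions],
            "dominance": [d.dominance for d in decisions],
            "is_marker": [d.is_marker for d in decisions],
        }
    )


@dataclass
class DistributionReport:
    """Per-class histogram and CDF summary for one channel."""

    channel: int
    decision: MarkerDecision
    table: pd.DataFrame  # bin_left, bin_right, density_pos, density_neg, cdf_pos, cdf_neg


def distribution_report(
    matrix: IntensityMatrix,
    channel: int,
    beta: float = 0.4,
    bins: int = 40,
    patients: Iterable[str] | None = None,
) -> DistributionReport:
    """Tabular per-class density and CDF for plotting one channel.

    The CDF columns are evaluated at the right bin edges with the same
    empirical CDFs the marker criterion uses, so the report is
    re-derivable from :func:`empirical_cdf` at those probe points.
    """
    sub = matrix.subset_patients(patients) if patients is not None else matrix
    col = sub.channel_values(channel)
    positive = sub.row_class == POSITIVE_CLASS
    pos, neg = col[positive], col[~positive]
    decision = marker_delta(pos, neg, beta=beta, channel=int(channel))

    lo, hi = float(col.min()), float(col.max())
    if lo == hi:  # constant channel: one degenerate bin
        edges = np.array([lo, lo + 1e-12])
    else:
        edges = np.linspace(lo, hi, bins + 1)
    dens_pos, _ = np.histogram(pos, bins=edges, density=True)
    dens_neg, _ = np.histogram(neg, bins=edges, density=True)
    p_cdf, q_cdf = EmpiricalCDF(pos), EmpiricalCDF(neg)
    table = pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "density_pos": dens_pos,
            "density_neg": dens_neg,
            "cdf_pos": p_cdf(edges[1:]),
            "cdf_neg": q_cdf(edges[1:]),
        }
    )
    return DistributionReport(channel=int(channel), decision=decision, table=table)
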