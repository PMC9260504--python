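"""Accuracy and agreement metrics for predicted vs observed mean utilities.

Conventions match the published analyses: differences are taken as
observed - predicted; RMSE averages over the 30 valued states by default
(the full-health row is an exact anchor and contributes zero if included);
Bland-Altman summaries use all 31 rows, the sample SD (denominator n-1)
and plain 1.96 limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .states import FULL_HEALTH


@dataclass(frozen=True)
class BlandAltmanSummary:
    """Agreement between two sets of per-state mean utilities."""

    mean_bias: float  # mean of observed - predicted
    sd_diff: float  # sample SD of the differences
    loa_low: float  # bias - 1.96 sd
    loa_high: float  # bias + 1.96 sd
    width: float  # 2 * 1.96 * sd
    n: int

    def as_dict(self) -> dict:
        return {
            "mean_bias": self.mean_bias,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "width": self.width,
            "n": self.n,
        }


def _aligned(predicted, observed, states, include_full_health):
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have equal length")
    if states is not None:
        states = [str(s) for s in states]
        if len(states) != len(predicted):
            raise ValueError("state list length mismatch")
        if not include_full_health:
            keep = np.array([c != FULL_HEALTH for c in states])
            predicted, observed = predicted[keep], observed[keep]
    return predicted, observed


def rmse(predicted, observed, states=None, include_full_health: bool = False) -> float:
    """Root mean squared error of predicted against observed mean utilities.

    If ``states`` is supplied the full-health row is excluded by default
    (it is an exact anchor in both columns); whether the published figure
    averaged over 30 or 31 rows is ambiguous at the printed precision, so
    the flag is exposed.
    """
    predicted, observed = _aligned(predicted, observed, states, include_full_health)
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def bland_altman(predicted, observed) -> BlandAltmanSummary:
    """Bland-Altman agreement summary over all supplied rows.

    Differences are observed - predicted; limits of agreement are
    mean_bias +/- 1.96 x sample SD.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have equal length")
    if predicted.size < 2:
        raise ValueError("need at least two rows for an agreement summary")
    d = observed - predicted
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanSummary(
        mean_bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        width=2 * 1.96 * sd,
        n=int(predicted.size),
    )


def difference_table(predicted, observed, states) -> pd.DataFrame:
    """Plot-ready Bland-Altman table: state, average, difference."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    return pd.DataFrame(
        {
            "state": [str(s) for s in states],
            "average": (observed + predicted) / 2.0,
            "difference": observed - predicted,
        }
    )


def qaly_cost_impact(
    delta_u: float, base_utility: float, years: float, cost: float
) -> tuple[float, float]:
    """QALY gain arithmetic for a utility-estimate shift.

    A treatment extending life by ``years`` at utility ``base_utility +
    delta_u`` yields (base + delta) * years QALYs; dividing the treatment
    cost by that gives the cost per QALY.  E.g. a 0.03 average utility
    difference moves 0.5 QALY/year to 0.53, and a 10,000 treatment from
    20,000 to ~18,868 per QALY.
    """
    qalys = (base_utility + delta_u) * years
    if qalys <= 0:
        raise ValueError("QALYs must be positive")
    return float(qalys), float(cost / qalys)
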