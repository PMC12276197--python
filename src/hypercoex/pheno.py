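"""Closed-form phenotype summaries: qPCR fold change, Fulton's K, respirometry.

These are the small arithmetic endpoints of the study design: relative gene
expression by the delta-delta-Ct method (fold = 2^-ddCt after housekeeping
normalization), Fulton's condition factor K = 100 M / L^3 for fish body
condition, and respirometry summaries where basal metabolic rate is the mean
of the lowest 10% of oxygen-uptake trials and aerobic scope is the maximum
uptake minus basal rate.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "QpcrMeasurement",
    "RespirometryTrial",
    "delta_delta_ct",
    "delta_ct_ttest",
    "fulton_condition_factor",
    "respirometry_summary",
]


@dataclasses.dataclass
class QpcrMeasurement:
    """Mean Ct of the target and housekeeping gene for one group."""

    ct_target: float
    ct_housekeeping: float
    group: str = ""

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_housekeeping):
            if not math.isfinite(v) or v <= 0:
                raise ValueError("Ct values must be positive and finite")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_housekeeping


@dataclasses.dataclass
class RespirometryTrial:
    """Oxygen-uptake rates (mgO2 kg^-1 h^-1) from one respirometry session."""

    rates: Sequence[float]

    def __post_init__(self) -> None:
        self.rates = [float(r) for r in self.rates]
        if any(r < 0 for r in self.rates):
            raise ValueError("uptake rates must be non-negative")


def delta_delta_ct(treated: QpcrMeasurement, control: QpcrMeasurement) -> float:
    """Relative fold change 2^-(dCt_treated - dCt_control)."""
    ddct = treated.delta_ct - control.delta_ct
    return float(2.0 ** (-ddct))


def delta_ct_ttest(
    treated_dct: Sequence[float], control_dct: Sequence[float]
) -> tuple[float, float]:
    """Unpaired two-sided t-test on per-replicate delta-Ct values."""
    res = stats.ttest_ind(np.asarray(treated_dct), np.asarray(control_dct))
    return float(res.statistic), float(res.pvalue)


def fulton_condition_factor(mass: float, length: float) -> float:
    """Fulton's K = 100 M / L^3 (mass in grams, length in centimetres)."""
    if mass <= 0 or length <= 0:
        raise ValueError("mass and length must be positive")
    return 100.0 * mass / length**3


def respirometry_summary(trial: RespirometryTrial) -> tuple[float, float, float]:
    """(basal rate, maximum rate, aerobic scope) in mgO2 kg^-1 h^-1.

    Basal metabolic rate is the mean of the lowest 10% of trials, with the
    lowest-10% count taken as max(1, floor(0.1 n)) so the set is never
    empty; aerobic scope is the maximum uptake minus the basal rate.
    """
    rates = np.asarray(trial.rates, dtype=float)
    if rates.size == 0:
        raise ValueError("no trials recorded")
    k = max(1, int(np.floor(0.1 * rates.size)))
    bmr = float(np.sort(rates)[:k].mean())
    mmr = float(rates.max())
    return bmr, mmr, mmr - bmr
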