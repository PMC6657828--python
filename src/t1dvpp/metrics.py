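"""Glycemic outcome metrics and population comparison statistics.

Time-in-range bands use the standard clinical thresholds: hypoglycemia
below 70 mg/dl, target 70-180 mg/dl (boundaries inclusive), and
hyperglycemia above 180 mg/dl.  The low/high blood glucose risk indices
(LBGI/HBGI) use the Kovatchev symmetrizing transform in its mg/dl
parameterization, f(G) = 1.509 ((ln G)^1.084 - 5.381), whose zero sits
at ~112.5 mg/dl; risk is 10 f(G)^2 split by the sign of f.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "OutcomeMetrics",
    "time_in_ranges",
    "lbgi_hbgi",
    "outcome_metrics",
    "mae_outcomes",
    "compare_populations",
]

HYPO_MGDL = 70.0
HYPER_MGDL = 180.0


@dataclass
class OutcomeMetrics:
    """Glycemic outcomes of one glucose trace."""

    pct_hypo: float     # % of samples < 70 mg/dl
    pct_target: float   # % in [70, 180] mg/dl
    pct_hyper: float    # % > 180 mg/dl
    lbgi: float
    hbgi: float

    def as_dict(self) -> dict[str, float]:
        return {
            "pct_hypo": self.pct_hypo,
            "pct_target": self.pct_target,
            "pct_hyper": self.pct_hyper,
            "lbgi": self.lbgi,
            "hbgi": self.hbgi,
        }


def time_in_ranges(glucose: np.ndarray) -> tuple[float, float, float]:
    """Percent of samples below/within/above the 70-180 mg/dl band."""
    g = np.asarray(glucose, dtype=float)
    if g.size == 0:
        raise ValueError("glucose series must be non-empty")
    n = g.size
    hypo = 100.0 * np.count_nonzero(g < HYPO_MGDL) / n
    hyper = 100.0 * np.count_nonzero(g > HYPER_MGDL) / n
    return hypo, 100.0 - hypo - hyper, hyper


def lbgi_hbgi(glucose: np.ndarray) -> tuple[float, float]:
    """Low and high blood glucose risk indices of a series."""
    g = np.asarray(glucose, dtype=float)
    if g.size == 0:
        raise ValueError("glucose series must be non-empty")
    if np.any(g <= 0):
        raise ValueError("glucose values must be strictly positive")
    f = 1.509 * (np.log(g) ** 1.084 - 5.381)
    risk = 10.0 * f * f
    lbgi = float(np.mean(np.where(f < 0, risk, 0.0)))
    hbgi = float(np.mean(np.where(f > 0, risk, 0.0)))
    return lbgi, hbgi


def outcome_metrics(glucose: np.ndarray) -> OutcomeMetrics:
    """All primary and secondary outcomes of one trace."""
    hypo, target, hyper = time_in_ranges(glucose)
    lbgi, hbgi = lbgi_hbgi(glucose)
    return OutcomeMetrics(hypo, target, hyper, lbgi, hbgi)


def mae_outcomes(
    clinical: list[OutcomeMetrics] | list[dict],
    simulated: list[OutcomeMetrics] | list[dict],
) -> dict[str, float]:
    """Mean absolute error of each outcome metric over paired scenarios."""
    if len(clinical) != len(simulated):
        raise ValueError("clinical and simulated lists must be paired (equal length)")
    if not clinical:
        raise ValueError("need at least one paired scenario")

    def _d(m):
        return m.as_dict() if isinstance(m, OutcomeMetrics) else dict(m)

    keys = _d(clinical[0]).keys()
    return {
        k: float(np.mean([abs(_d(c)[k] - _d(s)[k]) for c, s in zip(clinical, simulated)]))
        for k in keys
    }


def compare_populations(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True, paired: bool = False
) -> dict[str, float]:
    """Two-tailed t-test comparison of one metric between two groups.

    Classical equal-variance two-sample test by default (Welch via
    ``equal_var=False``, paired test via ``paired``).  Degenerate input
    with zero variance in both groups and equal means reports p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per group")
    out = {
        "mean_a": float(a.mean()),
        "sd_a": float(a.std(ddof=1)),
        "mean_b": float(b.mean()),
        "sd_b": float(b.std(ddof=1)),
    }
    if a.std() == 0 and b.std() == 0:
        out["p_value"] = 1.0 if a.mean() == b.mean() else 0.0
        return out
    if paired:
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=equal_var)
    out["p_value"] = float(res.pvalue)
    return out
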