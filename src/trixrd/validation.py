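"""Hold-out validation of composition estimates against known mixtures.

The protocol mirrors the in-sample check used to validate the system:
calibrate on a subset of replicates, predict the held-out replicates, and
compare estimated to actual weight fractions.  Metrics per mineral: mean
absolute error excluding pure samples (whose error is zero by construction),
slope and R^2 of an actual-vs-predicted regression, and the fraction of
errors falling within 1 and 2 combined standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MINERAL_COLUMNS
from .model import CompositionVector
from .uncertainty import CompositionEstimate

__all__ = ["ValidationReport", "validate_estimates"]


@dataclass(frozen=True)
class ValidationReport:
    mae: dict                   # per-mineral MAE, wt% (pure samples excluded)
    mae_overall: float          # pooled over minerals, wt%
    slope: dict                 # actual-vs-predicted regression slope
    r2: dict                    # actual-vs-predicted R^2
    frac_within_1se: float
    frac_within_2se: float
    n_estimates: int

    def summary(self) -> str:
        lines = [
            "Hold-out validation against known compositions",
            "=" * 52,
            f"{'mineral':<12}{'MAE (wt%)':>10}{'slope':>8}{'R^2':>8}",
        ]
        for m in MINERAL_COLUMNS:
            lines.append(
                f"{m:<12}{self.mae[m]:>10.2f}{self.slope[m]:>8.3f}{self.r2[m]:>8.4f}"
            )
        lines.append("-" * 52)
        lines.append(
            f"overall MAE {self.mae_overall:.2f} wt% "
            f"(pure samples excluded, n = {self.n_estimates})"
        )
        lines.append(
            f"errors within 1 SE: {100 * self.frac_within_1se:.0f}%   "
            f"within 2 SE: {100 * self.frac_within_2se:.0f}%"
        )
        return "\n".join(lines)


def validate_estimates(
    truths: list[CompositionVector], estimates: list[CompositionEstimate]
) -> ValidationReport:
    """Compare estimates to their known compositions.

    ``truths`` and ``estimates`` are parallel lists (one truth per
    estimate).  Regression of predicted on actual uses all samples; MAE and
    SE-coverage exclude pure samples, where the estimator returns the exact
    unit vector with zero SE.
    """
    if len(truths) != len(estimates):
        raise ValueError("truths and estimates must have equal length")
    if not estimates:
        raise ValueError("no overlap between design and estimates")
    actual = np.array([t.fractions for t in truths])
    pred = np.array([e.composition.fractions for e in estimates])
    se = np.array([e.se_combined for e in estimates])
    pure = np.array([t.is_pure for t in truths])

    mae, slope, r2 = {}, {}, {}
    for i, m in enumerate(MINERAL_COLUMNS):
        err = np.abs(pred[~pure, i] - actual[~pure, i])
        mae[m] = float(100.0 * err.mean()) if err.size else float("nan")
        a, p = actual[:, i], pred[:, i]
        if np.ptp(a) > 0:
            b, b0 = np.polyfit(a, p, 1)
            resid = p - (b0 + b * a)
            r2[m] = float(1 - resid.var() / p.var()) if p.var() > 0 else float("nan")
            slope[m] = float(b)
        else:
            slope[m], r2[m] = float("nan"), float("nan")

    err_all = np.abs(pred[~pure] - actual[~pure])
    se_all = se[~pure]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se_all > 0, err_all / se_all, np.where(err_all == 0, 0.0, np.inf))
    nonzero = actual[~pure] > 0  # minerals absent from a mixture carry zero SE
    return ValidationReport(
        mae=mae,
        mae_overall=float(100.0 * err_all.mean()) if err_all.size else float("nan"),
        slope=slope,
        r2=r2,
        frac_within_1se=float(np.mean(z[nonzero] <= 1)),
        frac_within_2se=float(np.mean(z[nonzero] <= 2)),
        n_estimates=len(estimates),
    )
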