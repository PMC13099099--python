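"""Legacy inverse-calibration regression on peak height ratios (PHR).

Historical practice for *bimineral* calcite/aragonite samples: regress the
known calcite weight percent on the observed peak height ratio (a linear or
quadratic polynomial), then read unknown compositions off the fitted curve.
This is an inverse calibration - statistically backwards, with no physical
law behind it and no uncertainty statement - kept here as a comparison
baseline.  Its characteristic pathologies are reproduced deliberately:
predictions can fall outside [0, 100] wt% (they are clamped and flagged),
and applying it to trimineral samples by merging the two calcite peaks
biases the estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CalibrationSample, PeakHeightVector

__all__ = ["PHRModel", "fit_phr_regression", "predict_phr", "peak_height_ratio"]


def peak_height_ratio(i_calcite: float, i_aragonite: float, convention: str = "bounded"):
    """PHR conventions: 'bounded' = C/(C+A) in [0,1]; 'ratio' = C/A."""
    if convention == "bounded":
        return i_calcite / (i_calcite + i_aragonite)
    if convention == "ratio":
        return i_calcite / i_aragonite
    raise ValueError(f"unknown PHR convention {convention!r}")


@dataclass(frozen=True)
class PHRModel:
    """Fitted inverse-calibration polynomial: wt% calcite = poly(PHR)."""

    degree: int
    coefficients: np.ndarray  # ascending powers
    convention: str
    phr_range: tuple[float, float]

    def __post_init__(self):
        if self.degree not in (1, 2):
            raise ValueError("PHR regression degree must be 1 or 2")
        object.__setattr__(
            self, "coefficients", np.asarray(self.coefficients, dtype=float)
        )


def _bimineral_parts(pk: PeakHeightVector) -> tuple[float, float]:
    """(calcite, aragonite) heights; the two calcite peaks are merged.

    Genuinely bimineral samples have one calcite peak absent, so the merge
    is a no-op for them; for trimineral samples it reproduces the legacy
    treatment that cannot tell LMC from HMC.
    """
    return float(pk.heights[1] + pk.heights[2]), float(pk.heights[0])


def fit_phr_regression(
    samples: list[CalibrationSample],
    degree: int = 2,
    convention: str = "bounded",
    allow_trimineral: bool = False,
) -> PHRModel:
    """Least-squares fit of known wt% calcite on the observed PHR.

    Requires bimineral calibration data (at most one calcite present per
    mixture) unless ``allow_trimineral`` is set to emulate forcing the
    legacy method onto trimineral samples.
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    phr, wt = [], []
    for s in samples:
        calcite_fracs = s.composition.fractions[1:]
        if not allow_trimineral and np.all(calcite_fracs > 0):
            raise ValueError(
                f"sample {s.sample_id} is trimineral; the PHR baseline is "
                "bimineral-only - use the external-standard system instead"
            )
        for _, pk in s.replicates:
            c, a = _bimineral_parts(pk)
            phr.append(peak_height_ratio(c, a, convention))
            wt.append(100.0 * calcite_fracs.sum())
    phr, wt = np.asarray(phr), np.asarray(wt)
    if len(phr) < degree + 2:
        raise ValueError(f"need >= {degree + 2} samples for a degree-{degree} fit")
    if np.ptp(phr) == 0:
        raise ValueError("degenerate calibration: all peak height ratios identical")
    coeffs = np.polynomial.polynomial.polyfit(phr, wt, degree)
    return PHRModel(degree, coeffs, convention, (float(phr.min()), float(phr.max())))


def predict_phr(model: PHRModel, pk: PeakHeightVector) -> tuple[float, dict]:
    """Predicted wt% calcite with pathology flags.

    Returns ``(wtpct, flags)`` where flags record clamping (raw prediction
    outside [0, 100]) and extrapolation beyond the fitted PHR range.  No
    uncertainty is reported: the legacy approach does not provide one.
    """
    c, a = _bimineral_parts(pk)
    x = peak_height_ratio(c, a, model.convention)
    raw = float(np.polynomial.polynomial.polyval(x, model.coefficients))
    flags = {
        "raw_prediction": raw,
        "clamped": not (0.0 <= raw <= 100.0),
        "out_of_range": not (model.phr_range[0] <= x <= model.phr_range[1]),
    }
    return float(np.clip(raw, 0.0, 100.0)), flags
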