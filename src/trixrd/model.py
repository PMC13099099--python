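"""Core types and the external-standard model for trimineral XRD quantification.

The quantification problem: a powdered carbonate sample is a mixture of up to
three minerals (aragonite, low-Mg calcite, high-Mg calcite).  Each mineral
produces a characteristic diffraction peak whose height ``I_l`` is, to first
order, proportional to the mineral's weight fraction ``pi_l`` through a
reference intensity ratio (RIR) ``k_l``.  The external-standard equation
inverts that proportionality on the 3-simplex:

    pi_hat_l = (I_l / k_l) / sum_i (I_i / k_i)

Aragonite is the reference mineral, so ``k_1 = 1`` and ``k_2, k_3`` are
intensities per unit weight relative to aragonite.  This module holds the
domain types, the estimator, and the forward (generative-mean) model; noise
and calibration live in :mod:`trixrd.calibration` and
:mod:`trixrd.uncertainty`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MineralBasis",
    "CARBONATE_BASIS",
    "CompositionVector",
    "PeakHeightVector",
    "RIRSet",
    "GenerativeParams",
    "CalibrationSample",
    "SIMPLEX_TOL",
    "estimate_weight_fractions",
    "expected_relative_intensities",
    "forward_expected_intensities",
]

#: tolerance for simplex-closure checks (closed-form arithmetic only)
SIMPLEX_TOL = 1e-12


@dataclass(frozen=True)
class MineralBasis:
    """Ordered mineral system with nominal primary-peak positions.

    The first label is the reference mineral (its RIR is fixed at 1).
    Positions are in degrees 2-theta within the 26-32 scan window.
    """

    labels: tuple[str, ...] = ("aragonite", "lmc", "hmc")
    peak_positions: tuple[float, ...] = (26.2, 29.4, 29.7)
    aux_peaks: dict = field(
        default_factory=lambda: {"aragonite2": 27.2, "halite": 31.7}
    )
    reference_index: int = 0
    notes: str = "standards: LMC 0.3 wt% MgCO3, HMC 11.3 wt% MgCO3"

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("mineral labels must be unique")
        if len(self.peak_positions) != len(self.labels):
            raise ValueError("one peak position per mineral required")
        pos = np.asarray(self.peak_positions, dtype=float)
        if not np.all(np.diff(pos) > 0):
            raise ValueError("peak positions must be strictly increasing")
        if not (0 <= self.reference_index < len(self.labels)):
            raise ValueError("reference_index out of range")

    @property
    def n_minerals(self) -> int:
        return len(self.labels)


#: default aragonite / low-Mg calcite / high-Mg calcite basis
CARBONATE_BASIS = MineralBasis()


def _as_array(x, n=3, name="vector"):
    a = np.asarray(x, dtype=float)
    if a.shape != (n,):
        raise ValueError(f"{name} must have shape ({n},), got {a.shape}")
    return a


@dataclass(frozen=True)
class CompositionVector:
    """Weight fractions on the 3-simplex (dimensionless)."""

    fractions: np.ndarray

    def __post_init__(self):
        f = _as_array(self.fractions, name="fractions")
        object.__setattr__(self, "fractions", f)
        if np.any(f < -SIMPLEX_TOL) or np.any(f > 1 + SIMPLEX_TOL):
            raise ValueError(f"weight fractions must lie in [0, 1]: {f}")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"weight fractions must sum to 1, got {f.sum()!r}")

    @classmethod
    def from_percent(cls, percents) -> "CompositionVector":
        p = _as_array(percents, name="percents")
        if abs(p.sum() - 100.0) > 0.5:
            raise ValueError(f"percent composition must sum to 100, got {p.sum()}")
        return cls(p / p.sum())

    def as_percent(self) -> np.ndarray:
        return 100.0 * self.fractions

    @property
    def is_pure(self) -> bool:
        return bool(np.any(self.fractions >= 1.0 - SIMPLEX_TOL))

    def __getitem__(self, i):
        return float(self.fractions[i])

    def __iter__(self):
        return iter(self.fractions.tolist())


@dataclass(frozen=True)
class PeakHeightVector:
    """Observed primary-peak heights in counts, with absent-peak flags.

    A mineral whose peak does not qualitatively appear in the diffractogram is
    *absent*: its height is stored as 0 with ``absent=True``.  The estimator
    treats absent and exactly-zero peaks identically (the external-standard
    equation is continuous at ``I = 0``); the flag survives for reporting.
    """

    heights: np.ndarray
    absent: np.ndarray = None
    halite_height: float | None = None
    positions: np.ndarray | None = None

    def __post_init__(self):
        h = np.asarray(self.heights, dtype=float)
        if h.shape != (3,):
            raise ValueError(f"expected 3 peak heights, got shape {h.shape}")
        absent = self.absent
        if absent is None:
            absent = np.isnan(h)
        absent = np.asarray(absent, dtype=bool)
        h = np.where(absent, 0.0, h)
        if np.any(~np.isfinite(h)):
            raise ValueError("present peak heights must be finite")
        if np.any(h < 0):
            raise ValueError(f"peak heights must be non-negative: {h}")
        if absent.all():
            raise ValueError("at least one mineral peak must be present")
        object.__setattr__(self, "heights", h)
        object.__setattr__(self, "absent", absent)
        if self.positions is not None:
            object.__setattr__(
                self, "positions", np.asarray(self.positions, dtype=float)
            )

    @classmethod
    def from_values(cls, i1, i2, i3, **kw) -> "PeakHeightVector":
        """Build from three heights; ``None`` or ``nan`` marks an absent peak."""
        vals = [np.nan if v is None else float(v) for v in (i1, i2, i3)]
        return cls(np.array(vals), **kw)

    def __getitem__(self, i):
        return float(self.heights[i])


@dataclass(frozen=True)
class RIRSet:
    """Reference intensity ratios (k1, k2, k3); k1 is pinned at 1."""

    k: np.ndarray

    #: support of the calibration prior for k2, k3
    PRIOR_LO = 0.01
    PRIOR_HI = 100.0

    def __post_init__(self):
        k = _as_array(self.k, name="k")
        object.__setattr__(self, "k", k)
        if k[0] != 1.0:
            raise ValueError("k1 (reference mineral) must equal 1")
        if np.any(k[1:] <= self.PRIOR_LO) or np.any(k[1:] >= self.PRIOR_HI):
            raise ValueError(
                f"k2, k3 must lie in ({self.PRIOR_LO}, {self.PRIOR_HI}): {k[1:]}"
            )

    @classmethod
    def from_values(cls, k2: float, k3: float) -> "RIRSet":
        return cls(np.array([1.0, k2, k3]))

    def __getitem__(self, i):
        return float(self.k[i])


@dataclass(frozen=True)
class GenerativeParams:
    """Parameters of the generative intensity model.

    ``kappa`` scales the heteroskedastic measurement noise,
    Var(I_l) = kappa * lambda_l; ``total_intensity`` is the expected summed
    peak intensity Lambda for one analysed subsample (counts).
    """

    rirs: RIRSet
    kappa: float
    total_intensity: float

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.total_intensity <= 0:
            raise ValueError("total intensity Lambda must be > 0")


@dataclass(frozen=True)
class CalibrationSample:
    """A standard mixture of known composition with replicate measurements."""

    sample_id: str
    composition: CompositionVector
    replicates: tuple = ()

    def __post_init__(self):
        ids = [rid for rid, _ in self.replicates]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate replicate ids in sample {self.sample_id}")
        for _, pk in self.replicates:
            if not isinstance(pk, PeakHeightVector):
                raise TypeError("replicates must be (id, PeakHeightVector) pairs")


def _heights(I) -> np.ndarray:
    if isinstance(I, PeakHeightVector):
        return I.heights
    return _as_array(I, name="heights")


def _ks(k) -> np.ndarray:
    if isinstance(k, RIRSet):
        return k.k
    return _as_array(k, name="k")


def estimate_weight_fractions(I, k) -> CompositionVector:
    """Invert the external-standard equation: heights -> weight fractions.

    pi_hat_l = (I_l / k_l) / sum_i (I_i / k_i).  Absent peaks contribute
    I = 0 and receive pi_hat = 0 exactly.  The estimate is invariant to
    rescaling all heights by a common positive factor.

    Parameters
    ----------
    I : PeakHeightVector or array-like of 3 heights (counts)
    k : RIRSet or array-like of 3 reference intensity ratios

    Raises
    ------
    ValueError
        If all peaks are absent/zero ("no signal") or any height is negative.
    """
    h = _heights(I)
    kv = _ks(k)
    if np.any(h < 0):
        raise ValueError(f"peak heights must be non-negative: {h}")
    scaled = h / kv
    total = scaled.sum()
    if total <= 0:
        raise ValueError("no signal: all peaks absent or zero")
    return CompositionVector(scaled / total)


def expected_relative_intensities(pi, k) -> np.ndarray:
    """Forward map on the simplex: E(r_l) = k_l pi_l / sum_i k_i pi_i.

    The exact inverse of :func:`estimate_weight_fractions` on noise-free
    input; returns relative intensities summing to 1.
    """
    p = pi.fractions if isinstance(pi, CompositionVector) else _as_array(pi, name="pi")
    kv = _ks(k)
    w = kv * p
    return w / w.sum()


def forward_expected_intensities(pi, params: GenerativeParams) -> np.ndarray:
    """Expected peak heights lambda_l = Lambda * r_l for one subsample."""
    r = expected_relative_intensities(pi, params.rirs)
    return params.total_intensity * r
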