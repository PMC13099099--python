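"""File formats: peak tables, design tables, calibration JSON, scan traces.

All flat files are comma-separated UTF-8 with a mandatory header and "."
decimals.  Heights are in counts, compositions in percent (fractions are
internal only).  Scan files are two-column ASCII xy (2-theta, counts) with
"#" comment lines.  An empty cell or "NA" in a height column marks an
absent peak.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationFit
from .model import (
    CalibrationSample,
    CompositionVector,
    PeakHeightVector,
)
from .uncertainty import CompositionEstimate

__all__ = [
    "MINERAL_COLUMNS",
    "read_peak_table",
    "write_peak_table",
    "read_design",
    "write_design",
    "read_calibration_params",
    "write_calibration_params",
    "build_calibration_samples",
    "write_estimates",
    "ScanTrace",
    "PeakWindow",
    "PeakWindowSet",
    "read_scan",
    "extract_peak_heights",
]

MINERAL_COLUMNS = ("aragonite", "lmc", "hmc")
_HEIGHT_COLS = tuple(f"height_{m}" for m in MINERAL_COLUMNS)
_POS_COLS = tuple(f"pos_{m}" for m in MINERAL_COLUMNS)


# -- peak tables ----------------------------------------------------------


def read_peak_table(
    path, on_all_absent: str = "raise"
) -> list[tuple[str, str, PeakHeightVector]]:
    """Read a peak-height table: one row per (sample, replicate).

    Required columns: ``sample_id``, ``replicate``, ``height_aragonite``,
    ``height_lmc``, ``height_hmc``.  Optional: per-mineral ``pos_*``
    (measured degrees 2-theta) and ``height_halite``.  Rows with every peak
    absent carry no signal; they are rejected (default) or skipped with a
    warning when ``on_all_absent='skip'``.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "replicate": str})
    required = ["sample_id", "replicate", *_HEIGHT_COLS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"peak table {path} is missing required columns: {missing}")
    dupes = df.duplicated(subset=["sample_id", "replicate"])
    if dupes.any():
        bad = df.loc[dupes, ["sample_id", "replicate"]].to_records(index=False)
        raise ValueError(f"duplicate (sample, replicate) keys: {list(bad)}")
    records = []
    for _, row in df.iterrows():
        heights = np.array([row[c] for c in _HEIGHT_COLS], dtype=float)
        if np.any(heights[~np.isnan(heights)] < 0):
            raise ValueError(
                f"negative peak height in sample {row['sample_id']} "
                f"replicate {row['replicate']}"
            )
        if np.all(np.isnan(heights)):
            msg = (
                f"all peaks absent for sample {row['sample_id']} "
                f"replicate {row['replicate']}"
            )
            if on_all_absent == "skip":
                import warnings

                warnings.warn(msg + "; row skipped", stacklevel=2)
                continue
            raise ValueError(msg)
        positions = None
        if all(c in df.columns for c in _POS_COLS):
            positions = np.array([row[c] for c in _POS_COLS], dtype=float)
        halite = None
        if "height_halite" in df.columns and not pd.isna(row["height_halite"]):
            halite = float(row["height_halite"])
        pk = PeakHeightVector(heights, halite_height=halite, positions=positions)
        records.append((str(row["sample_id"]), str(row["replicate"]), pk))
    return records


def write_peak_table(records, path) -> None:
    """Write (sample_id, replicate, PeakHeightVector) records; NA = absent."""
    rows = []
    for sid, rid, pk in records:
        row = {"sample_id": sid, "replicate": rid}
        for i, c in enumerate(_HEIGHT_COLS):
            row[c] = np.nan if pk.absent[i] else pk.heights[i]
        if pk.positions is not None:
            for i, c in enumerate(_POS_COLS):
                row[c] = pk.positions[i]
        if pk.halite_height is not None:
            row["height_halite"] = pk.halite_height
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, na_rep="NA")


# -- design tables --------------------------------------------------------


def read_design(path) -> dict[str, CompositionVector]:
    """Read known compositions (percent by weight) keyed by sample id."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    required = ["sample_id", *MINERAL_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"design table {path} is missing columns: {missing}")
    out = {}
    for _, row in df.iterrows():
        pct = np.array([row[m] for m in MINERAL_COLUMNS], dtype=float)
        if abs(pct.sum() - 100.0) > 0.5:
            raise ValueError(
                f"design row {row['sample_id']} sums to {pct.sum()}, expected 100"
            )
        out[str(row["sample_id"])] = CompositionVector(pct / pct.sum())
    return out


def write_design(design: dict[str, CompositionVector], path) -> None:
    rows = [
        {"sample_id": sid, **dict(zip(MINERAL_COLUMNS, comp.as_percent()))}
        for sid, comp in design.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def build_calibration_samples(
    design: dict[str, CompositionVector], peak_records
) -> list[CalibrationSample]:
    """Join a design table with measured peaks into calibration samples."""
    by_sample: dict[str, list] = {}
    unmatched = []
    for sid, rid, pk in peak_records:
        if sid not in design:
            unmatched.append(sid)
            continue
        by_sample.setdefault(sid, []).append((rid, pk))
    if unmatched:
        raise ValueError(
            f"peak-table samples missing from the design: {sorted(set(unmatched))}"
        )
    missing = sorted(set(design) - set(by_sample))
    if missing:
        raise ValueError(f"design samples with no measured peaks: {missing}")
    return [
        CalibrationSample(sid, design[sid], tuple(reps))
        for sid, reps in by_sample.items()
    ]


# -- calibration parameter files ------------------------------------------

_CAL_KEYS = ("k2", "k3", "kappa", "var_k2", "var_k3", "cov_k2k3")


def write_calibration_params(fit: CalibrationFit, path) -> None:
    with open(path, "w") as fh:
        json.dump(fit.to_dict(), fh, indent=2)
        fh.write("\n")


def read_calibration_params(path) -> CalibrationFit:
    with open(path) as fh:
        d = json.load(fh)
    missing = [k for k in _CAL_KEYS if k not in d]
    if missing:
        raise ValueError(f"calibration file {path} is missing keys: {missing}")
    bad = [k for k in _CAL_KEYS if not isinstance(d[k], (int, float))]
    if bad:
        raise ValueError(f"calibration file {path}: non-numeric values for {bad}")
    return CalibrationFit.from_dict(d)


# -- estimates table ------------------------------------------------------


def write_estimates(estimates: list[CompositionEstimate], path) -> None:
    """Write composition estimates (percent scale) with the SE decomposition."""
    rows = []
    for e in estimates:
        row = {"sample_id": e.sample_id, "replicate": e.replicate}
        for i, m in enumerate(MINERAL_COLUMNS):
            row[f"wtpct_{m}"] = 100.0 * e.composition.fractions[i]
        for i, m in enumerate(MINERAL_COLUMNS):
            row[f"se_intrinsic_{m}"] = 100.0 * e.se_intrinsic[i]
        for i, m in enumerate(MINERAL_COLUMNS):
            row[f"se_calibration_{m}"] = 100.0 * e.se_calibration[i]
        for i, m in enumerate(MINERAL_COLUMNS):
            row[f"se_combined_{m}"] = 100.0 * e.se_combined[i]
        row["flags"] = json.dumps(e.flags)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# -- raw scans and peak extraction ----------------------------------------


@dataclass(frozen=True)
class ScanTrace:
    """A raw diffractogram segment: counts versus degrees 2-theta."""

    two_theta: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        tt = np.asarray(self.two_theta, dtype=float)
        ct = np.asarray(self.counts, dtype=float)
        if tt.ndim != 1 or tt.shape != ct.shape:
            raise ValueError("two_theta and counts must be matching 1-D arrays")
        if not np.all(np.diff(tt) > 0):
            raise ValueError("2-theta values must be strictly increasing")
        if np.any(ct < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "two_theta", tt)
        object.__setattr__(self, "counts", ct)

    @property
    def step(self) -> float:
        return float(np.median(np.diff(self.two_theta)))


def read_scan(path) -> ScanTrace:
    """Read a two-column ASCII xy scan; '#' lines are comments."""
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"scan file {path} must have two columns (2theta, counts)")
    return ScanTrace(data[:, 0], data[:, 1])


@dataclass(frozen=True)
class PeakWindow:
    """Search range [lo, hi] for one peak, with optional wider background
    range [bg_lo, bg_hi] whose edges must sit on quiet baseline.  The
    calcite doublet needs this: the two search windows abut at 29.55 deg,
    where both peak tails are still live, so their background is taken from
    the quiet flanks of the whole doublet instead."""

    name: str
    center: float
    lo: float
    hi: float
    bg_lo: float | None = None
    bg_hi: float | None = None

    def __post_init__(self):
        if not (self.lo < self.center < self.hi):
            raise ValueError(f"window {self.name}: need lo < center < hi")

    @property
    def background_span(self) -> tuple[float, float]:
        return (
            self.bg_lo if self.bg_lo is not None else self.lo,
            self.bg_hi if self.bg_hi is not None else self.hi,
        )


@dataclass(frozen=True)
class PeakWindowSet:
    """Extraction windows for the quantified and auxiliary peaks.

    The low- and high-Mg calcite primary peaks sit only ~0.3 deg apart, so
    their windows split at the midpoint rather than using the generic
    half-width; quantified windows must never overlap.  ``prominence_factor``
    is the multiple of the robust edge-noise estimate below which a peak is
    called absent.
    """

    windows: tuple[PeakWindow, ...] = (
        PeakWindow("aragonite", 26.2, 25.9, 26.5),
        PeakWindow("lmc", 29.4, 29.1, 29.55, bg_lo=29.0, bg_hi=30.1),
        PeakWindow("hmc", 29.7, 29.55, 30.0, bg_lo=29.0, bg_hi=30.1),
    )
    halite: PeakWindow | None = PeakWindow("halite", 31.7, 31.4, 32.0)
    prominence_factor: float = 3.0
    n_edge: int = 3

    def __post_init__(self):
        spans = sorted((w.lo, w.hi) for w in self.windows)
        for (_, hi_a), (lo_b, _) in zip(spans, spans[1:]):
            if lo_b < hi_a:
                raise ValueError("quantified peak windows must not overlap")


def _window_height(scan: ScanTrace, lo: float, hi: float,
                   bg_lo: float, bg_hi: float, n_edge: int, prom: float):
    """Background-subtracted peak height and position inside [lo, hi].

    Background is the line through the medians of the first/last ``n_edge``
    points of the [bg_lo, bg_hi] range; a peak is absent when its height is
    below ``prom`` times a robust noise estimate from those edges.
    """
    bg_sel = (scan.two_theta >= bg_lo) & (scan.two_theta <= bg_hi)
    sel = (scan.two_theta >= lo) & (scan.two_theta <= hi)
    if bg_sel.sum() < 2 * n_edge + 1 or sel.sum() < 1:
        raise ValueError(
            f"scan does not cover window [{bg_lo:.2f}, {bg_hi:.2f}] deg 2-theta"
        )
    btt, bct = scan.two_theta[bg_sel], scan.counts[bg_sel]
    xl, yl = np.median(btt[:n_edge]), np.median(bct[:n_edge])
    xr, yr = np.median(btt[-n_edge:]), np.median(bct[-n_edge:])
    slope = (yr - yl) / (xr - xl)
    tt, ct = scan.two_theta[sel], scan.counts[sel]
    net = ct - (yl + slope * (tt - xl))
    edge_net = np.concatenate(
        [bct[:n_edge] - (yl + slope * (btt[:n_edge] - xl)),
         bct[-n_edge:] - (yl + slope * (btt[-n_edge:] - xl))]
    )
    noise = 1.4826 * np.median(np.abs(edge_net - np.median(edge_net)))
    i = int(np.argmax(net))
    height = float(net[i])
    # a maximum on the window boundary is a neighbouring peak's tail, not a
    # resolved apex inside this window
    if i in (0, len(net) - 1) or height <= prom * max(noise, 1e-9):
        return None, None
    return height, float(tt[i])


def extract_peak_heights(
    scan: ScanTrace, windows: PeakWindowSet | None = None
) -> PeakHeightVector:
    """Extract the three quantified peak heights from a raw scan.

    If a halite internal-standard window is configured and its peak is found,
    the measured offset from the nominal 31.7 deg is first applied to all
    windows (angular alignment); halite never enters quantification.
    """
    if windows is None:
        windows = PeakWindowSet()
    shift = 0.0
    halite_height = None
    if windows.halite is not None:
        w = windows.halite
        blo, bhi = w.background_span
        h, pos = _window_height(
            scan, w.lo, w.hi, blo, bhi,
            windows.n_edge, windows.prominence_factor,
        )
        if h is not None:
            shift = pos - w.center
            halite_height = h
    heights = np.full(3, np.nan)
    positions = np.full(3, np.nan)
    for i, w in enumerate(windows.windows):
        blo, bhi = w.background_span
        h, pos = _window_height(
            scan,
            w.lo + shift,
            w.hi + shift,
            blo + shift,
            bhi + shift,
            windows.n_edge,
            windows.prominence_factor,
        )
        if h is not None:
            heights[i] = h
            positions[i] = pos
    if np.all(np.isnan(heights)):
        raise ValueError("no peaks detected in scan (flat or empty trace)")
    return PeakHeightVector(heights, halite_height=halite_height, positions=positions)
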