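"""Melt-curve analysis: midpoint melting temperature (Tm) from DSF traces.

A differential scanning fluorimetry (DSF) experiment ramps temperature while
a dye (here CPM-style, signal rising on unfolding) reports the unfolded
fraction of a protein.  The midpoint melting temperature is read
operationally from the derivative of the fluorescence trace: Tm is the
location of the global extremum of the smoothed first derivative,
equivalently the descending zero crossing of the second derivative, refined
to sub-grid precision by quadratic interpolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

MIN_POINTS = 20

QC_OK = "ok"
QC_LOW_AMPLITUDE = "low_amplitude"
QC_EDGE_PEAK = "edge_peak"
QC_MULTI_PEAK = "multi_peak"
QC_NO_TRANSITION = "no_transition"


@dataclass(frozen=True)
class MeltCurve:
    """One well's fluorescence-vs-temperature trace.

    temperatures must form a strictly increasing grid of at least 20 points;
    fluorescence has the same length and no missing values.
    """

    well_id: str
    temperatures: np.ndarray
    fluorescence: np.ndarray
    compound_id: str | None = None
    concentration_m: float | None = None
    role: str = "sample"  # "sample" or "dmso_control"

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.ndim != 1 or t.size < MIN_POINTS:
            raise ValueError(
                f"melt curve needs >= {MIN_POINTS} points, got {t.size}"
            )
        if f.shape != t.shape:
            raise ValueError("temperature and fluorescence lengths differ")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(f)):
            raise ValueError("melt curve contains missing/non-finite values")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "fluorescence", f)

    @property
    def step(self) -> float:
        return float(np.median(np.diff(self.temperatures)))


@dataclass(frozen=True)
class TmEstimate:
    """Tm call for one well, with QC flags.

    qc is a tuple of flags; an empty tuple plus ``ok=True`` means the call is
    usable for control statistics.  peak_height is the first-derivative
    extremum (AU/degC), amplitude the fluorescence span across the transition.
    """

    well_id: str
    tm: float
    peak_height: float
    amplitude: float
    qc: tuple[str, ...]
    method: str = "smoothed-derivative"

    @property
    def ok(self) -> bool:
        return self.qc == (QC_OK,)


@dataclass(frozen=True)
class TmConfig:
    """Settings for Tm determination.

    window_degC: Savitzky-Golay smoothing window in temperature units.
    poly_order: local polynomial order (>= 2).
    min_peak_height: AU/degC below which a well is flagged no_transition.
    min_amplitude: AU below which a well is flagged low_amplitude.
    edge_margin_degC: peaks within this margin of either end are edge_peak.
    multi_peak_frac: a secondary derivative peak at least this fraction of
        the main peak sets the multi_peak flag.
    direction: "up" for dyes whose signal rises on unfolding (CPM),
        "down" for the opposite convention.
    """

    window_degC: float = 2.0
    poly_order: int = 2
    min_peak_height: float = 0.005
    min_amplitude: float = 0.05
    edge_margin_degC: float = 2.0
    multi_peak_frac: float = 0.5
    direction: str = "up"


def smooth_curve(curve: MeltCurve, window_degC: float = 2.0,
                 poly_order: int = 2) -> MeltCurve:
    """Local polynomial (Savitzky-Golay) least-squares smoothing.

    The window is expressed in temperature units and converted to an odd
    number of grid points.  Polynomial inputs of degree <= poly_order are
    reproduced to numerical precision (projection identity); endpoints are
    handled by polynomial extension over the terminal window.
    """
    if poly_order < 2:
        raise ValueError("poly_order must be >= 2")
    step = curve.step
    if window_degC < step:
        raise ValueError("smoothing window smaller than grid resolution")
    npts = int(round(window_degC / step)) | 1  # force odd
    npts = max(npts, poly_order + 2)
    npts = npts if npts % 2 == 1 else npts + 1
    npts = min(npts, curve.temperatures.size - (curve.temperatures.size + 1) % 2)
    smoothed = savgol_filter(curve.fluorescence, npts, poly_order,
                             mode="interp")
    return replace(curve, fluorescence=smoothed)


def derivative(curve: MeltCurve, order: int = 1) -> np.ndarray:
    """Finite-difference derivative of fluorescence w.r.t. temperature.

    Central differences on the interior, one-sided at the ends
    (numpy.gradient).  order=2 is the derivative of the derivative.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    d = np.gradient(curve.fluorescence, curve.temperatures)
    if order == 2:
        d = np.gradient(d, curve.temperatures)
    return d


def _quadratic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through the three points bracketing index i."""
    if i == 0 or i == x.size - 1:
        return float(x[i]), float(y[i])
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2 * x2 * (y0 - y1) + x1 * x1 * (y2 - y0) + x0 * x0 * (y1 - y2)) / denom
    if a >= 0:  # not a maximum; fall back to the grid point
        return float(x1), float(y1)
    xv = -b / (2 * a)
    if not (x0 <= xv <= x2):
        return float(x1), float(y1)
    c = y1 - a * x1 * x1 - b * x1
    return float(xv), float(a * xv * xv + b * xv + c)


def smoothed_derivative(curve: MeltCurve, window_degC: float = 2.0,
                        poly_order: int = 2) -> np.ndarray:
    """First derivative of the local-polynomial (Savitzky-Golay) fit.

    Estimating the derivative directly from the local fit is markedly more
    noise-robust than differencing a smoothed trace.
    """
    if poly_order < 2:
        raise ValueError("poly_order must be >= 2")
    step = curve.step
    if window_degC < step:
        raise ValueError("smoothing window smaller than grid resolution")
    npts = max(int(round(window_degC / step)) | 1, poly_order + 2)
    npts = npts if npts % 2 == 1 else npts + 1
    return savgol_filter(curve.fluorescence, npts, poly_order, deriv=1,
                         delta=step, mode="interp")


def determine_tm(curve: MeltCurve, config: TmConfig = TmConfig()) -> TmEstimate:
    """Tm from the extremum of the smoothed first derivative.

    The global maximum of dF/dT (minimum for ``direction="down"``) is located
    on the grid — excluding the edge margin, where local-fit derivatives are
    unreliable — and refined by quadratic interpolation through the three
    bracketing points.  QC flags are set for weak transitions, low amplitude,
    edge-proximal peaks and secondary peaks; no_transition is reported as a
    flag, never an exception.
    """
    sm = smooth_curve(curve, config.window_degC, config.poly_order)
    d1 = smoothed_derivative(curve, config.window_degC, config.poly_order)
    signal = d1 if config.direction == "up" else -d1

    t = curve.temperatures
    margin = max(int(round(config.edge_margin_degC / curve.step)), 1)
    margin = min(margin, (t.size - 3) // 2)
    interior = slice(margin, t.size - margin)
    i = margin + int(np.argmax(signal[interior]))
    tm, peak_height = _quadratic_refine(t, signal, i)
    amplitude = float(np.ptp(sm.fluorescence))

    flags: list[str] = []
    if peak_height < config.min_peak_height:
        return TmEstimate(curve.well_id, float("nan"), peak_height, amplitude,
                          (QC_NO_TRANSITION,))
    if amplitude < config.min_amplitude:
        flags.append(QC_LOW_AMPLITUDE)
    t_lo = t[0] + config.edge_margin_degC
    t_hi = t[-1] - config.edge_margin_degC
    if not (t_lo < tm < t_hi) or i in (margin, t.size - margin - 1):
        flags.append(QC_EDGE_PEAK)
    # secondary peaks: local maxima of the derivative away from the main one
    peaks, _ = find_peaks(signal)
    secondary = [p for p in peaks
                 if abs(curve.temperatures[p] - tm) > config.window_degC]
    if secondary and max(signal[p] for p in secondary) >= \
            config.multi_peak_frac * peak_height:
        flags.append(QC_MULTI_PEAK)
    qc = tuple(flags) if flags else (QC_OK,)
    return TmEstimate(curve.well_id, tm, peak_height, amplitude, qc)


def batch_tm(curves: dict[str, MeltCurve] | list[MeltCurve],
             config: TmConfig = TmConfig()) -> dict[str, TmEstimate]:
    """Per-well Tm estimates for a plate; failures flagged, never dropped."""
    if isinstance(curves, dict):
        curves = list(curves.values())
    estimates = {c.well_id: determine_tm(c, config) for c in curves}
    counts: dict[str, int] = {}
    for est in estimates.values():
        for fl in est.qc:
            counts[fl] = counts.get(fl, 0) + 1
    logger.info("batch_tm: %d wells, qc counts %s", len(estimates), counts)
    return estimates


# ---------------------------------------------------------------------------
# I/O: wide melt CSV (temperature_C + one column per well) and plate map.

def read_melt_plate(melt_csv: str | Path,
                    plate_map_csv: str | Path) -> list[MeltCurve]:
    """Read a wide melt CSV plus plate-map CSV into MeltCurve objects.

    The wide CSV has column 1 "temperature_C" and one fluorescence column per
    well id; the plate map has columns well, compound_id, concentration_M,
    role (sample | dmso_control).
    """
    wide = pd.read_csv(melt_csv)
    if wide.columns[0] != "temperature_C":
        raise ValueError("first column of melt CSV must be temperature_C")
    pmap = pd.read_csv(plate_map_csv).set_index("well")
    temps = wide["temperature_C"].to_numpy(float)
    curves = []
    for well in wide.columns[1:]:
        meta = pmap.loc[well] if well in pmap.index else None
        cid = None if meta is None or pd.isna(meta["compound_id"]) \
            else str(meta["compound_id"])
        conc = None if meta is None or pd.isna(meta["concentration_M"]) \
            else float(meta["concentration_M"])
        role = "sample" if meta is None else str(meta["role"])
        curves.append(MeltCurve(well, temps, wide[well].to_numpy(float),
                                compound_id=cid, concentration_m=conc,
                                role=role))
    return curves


def write_tm_table(estimates: dict[str, TmEstimate],
                   curves: list[MeltCurve], path: str | Path) -> pd.DataFrame:
    """Write the per-well Tm CSV (well, compound_id, tm_C, peak_height,
    amplitude, qc)."""
    meta = {c.well_id: c for c in curves}
    rows = []
    for well, est in estimates.items():
        c = meta.get(well)
        rows.append({
            "well": well,
            "compound_id": c.compound_id if c else None,
            "concentration_M": c.concentration_m if c else None,
            "role": c.role if c else "sample",
            "tm_C": est.tm,
            "peak_height": est.peak_height,
            "amplitude": est.amplitude,
            "qc": "|".join(est.qc),
        })
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
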