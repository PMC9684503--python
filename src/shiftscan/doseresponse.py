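"""Dose-response analysis: background subtraction, four-parameter logistic
(4PL) fits for IC50/EC50, cross-experiment aggregation, single-point percent
of control, many-to-one significance testing and mutant-binding
normalization.

The 4PL model is fitted in log10-concentration space:

    y = bottom + (top - bottom) / (1 + 10^(hill * (log10 x - log10 m)))

where m is the midpoint (IC50 for uptake inhibition, EC50 for radioligand
competition).  Fits are least squares with quartile-based initialization and
multistart; the best-RSS solution wins.  A compound whose fitted span covers
half the signal or less within the tested range is reported as
"not_determined" rather than given an extrapolated midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

STATUS_OK = "ok"
STATUS_NOT_DETERMINED = "not_determined"
STATUS_UPPER_BOUND = "upper_bound"


@dataclass(frozen=True)
class FourPLFit:
    compound_id: str
    bottom: float
    top: float
    log_midpoint: float  # log10 M
    hill: float
    se: tuple[float, float, float, float]  # per parameter, same order
    rss: float
    converged: bool
    status: str
    n_points: int
    tested_range: tuple[float, float]

    @property
    def midpoint(self) -> float:
        """IC50/EC50 in M."""
        return float(10.0 ** self.log_midpoint)

    @property
    def extrapolated(self) -> bool:
        lo, hi = self.tested_range
        return not (lo <= self.midpoint <= hi)


def subtract_background(series: pd.DataFrame,
                        clip_negative: bool = True) -> pd.DataFrame:
    """Specific signal: transfected wells minus the mean of control wells.

    Expects columns compound_id, concentration_M, replicate, signal,
    well_type (transfected | control).  Negatives are clipped to zero and
    flagged in a ``clipped`` column.
    """
    controls = series[series["well_type"] == "control"]
    if controls.empty:
        raise ValueError("no control wells to estimate background from")
    background = controls["signal"].mean()
    out = series[series["well_type"] == "transfected"].copy()
    out["signal"] = out["signal"] - background
    out["clipped"] = out["signal"] < 0
    if clip_negative:
        out["signal"] = out["signal"].clip(lower=0.0)
    return out.drop(columns=["well_type"])


def _model(logx, bottom, top, logm, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logx - logm)))


def fit_4pl(series: pd.DataFrame, compound_id: str | None = None,
            n_starts: int = 5, bottom_min: float = 0.0,
            span_fraction: float = 0.5,
            se_fraction_upper_bound: float = 1.0,
            seed: int = 0) -> FourPLFit:
    """Least-squares 4PL fit of signal vs concentration.

    series needs columns concentration_M and signal (background-subtracted),
    with >= 4 distinct concentrations.  Initialization from data quartiles;
    ``n_starts`` multistart perturbations with the best-RSS winner;
    covariance-based standard errors.  status is "not_determined" when the
    fitted span within the tested range inhibits <= ``span_fraction`` of the
    top signal, "upper_bound" when the midpoint SE exceeds
    ``se_fraction_upper_bound`` of the estimate.
    """
    if compound_id is None:
        compound_id = str(series["compound_id"].iloc[0]) \
            if "compound_id" in series else "?"
    x = series["concentration_M"].to_numpy(float)
    y = series["signal"].to_numpy(float)
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    if np.unique(x).size < 4:
        raise ValueError("need >= 4 distinct concentrations to fit")
    logx = np.log10(x)
    rng = np.random.default_rng(seed)

    top0 = float(np.quantile(y, 0.95))
    bottom0 = max(float(np.quantile(y, 0.05)), bottom_min)
    logm0 = float(np.median(logx))
    p0 = np.array([bottom0, top0, logm0, 1.0])
    lb = np.array([bottom_min, bottom_min, logx.min() - 3.0, 0.05])
    ub = np.array([np.inf, np.inf, logx.max() + 3.0, 10.0])

    def residuals(p):
        return _model(logx, *p) - y

    best = None
    for start in range(n_starts):
        p_init = p0.copy()
        if start > 0:
            p_init[2] += rng.uniform(-1.5, 1.5)
            p_init[3] = float(np.exp(rng.uniform(-0.7, 0.7)))
        p_init = np.clip(p_init, lb, ub)
        try:
            res = optimize.least_squares(residuals, p_init,
                                         bounds=(lb, ub), method="trf")
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res

    tested = (float(x.min()), float(x.max()))
    if best is None:
        return FourPLFit(compound_id, np.nan, np.nan, np.nan, np.nan,
                         (np.nan,) * 4, np.nan, False,
                         STATUS_NOT_DETERMINED, x.size, tested)

    p = best.x
    rss = float(2 * best.cost)
    dof = max(x.size - 4, 1)
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * rss / dof
        se = tuple(float(s) for s in np.sqrt(np.maximum(np.diag(cov), 0.0)))
    except np.linalg.LinAlgError:
        se = (np.nan,) * 4

    bottom, top, logm, hill = (float(v) for v in p)
    # span achieved within the tested range, relative to the top signal
    y_lo = _model(np.log10(tested[0]), *p)
    y_hi = _model(np.log10(tested[1]), *p)
    span = abs(y_lo - y_hi)
    status = STATUS_OK
    if top <= 0 or span / max(top, 1e-12) <= span_fraction:
        status = STATUS_NOT_DETERMINED
    elif np.isfinite(se[2]) and \
            se[2] * np.log(10) * 10 ** logm > \
            se_fraction_upper_bound * 10 ** logm:
        status = STATUS_UPPER_BOUND
    return FourPLFit(compound_id, bottom, top, logm, hill, se, rss, True,
                     status, x.size, tested)


def aggregate_fits(fits: list[FourPLFit],
                   min_n: int = 2) -> dict:
    """Mean +/- sample SD of best-fit midpoints across independent
    experiments, on the linear scale (the conventional reporting)."""
    mids = [f.midpoint for f in fits if f.converged and f.status == STATUS_OK]
    if len(mids) == 0:
        return {"status": STATUS_NOT_DETERMINED, "n": 0,
                "mean": np.nan, "sd": np.nan}
    if len(mids) < min_n:
        return {"status": "insufficient_fits", "n": len(mids),
                "mean": float(np.mean(mids)), "sd": np.nan}
    arr = np.asarray(mids)
    return {"status": STATUS_OK, "n": arr.size,
            "mean": float(arr.mean()), "sd": float(arr.std(ddof=1))}


def percent_of_control(compound_counts: np.ndarray,
                       control_counts: np.ndarray) -> tuple[float, float]:
    """Single-point binding as percent of control: 100 x mean(compound) /
    mean(control), SD from the replicate-to-control-mean ratios."""
    compound_counts = np.asarray(compound_counts, dtype=float)
    control_counts = np.asarray(control_counts, dtype=float)
    ctrl_mean = control_counts.mean()
    if ctrl_mean <= 0:
        raise ValueError("control mean must be positive")
    ratios = 100.0 * compound_counts / ctrl_mean
    sd = float(ratios.std(ddof=1)) if ratios.size >= 2 else float("nan")
    return float(ratios.mean()), sd


def compare_to_control(groups: dict[str, np.ndarray],
                       control: str = "DMSO") -> pd.DataFrame:
    """One-way ANOVA followed by Dunnett many-to-one comparisons against the
    control group; returns per-group adjusted p-values."""
    if control not in groups:
        raise ValueError(f"control group {control!r} missing")
    names = [g for g in groups if g != control]
    samples = [np.asarray(groups[g], dtype=float) for g in names]
    ctrl = np.asarray(groups[control], dtype=float)
    for name, s in list(zip(names, samples)) + [(control, ctrl)]:
        if s.size < 2:
            raise ValueError(f"group {name!r} needs >= 2 replicates")
    pooled = np.concatenate(samples + [ctrl])
    degenerate = np.allclose(pooled.std(), 0.0)
    if degenerate:
        return pd.DataFrame({"group": names,
                             "p_anova": np.nan, "p_adjusted": np.nan,
                             "flag": "degenerate_variance"})
    _, p_anova = stats.f_oneway(ctrl, *samples)
    # Dunnett p-values are evaluated by Monte Carlo integration of the
    # multivariate t; a fixed seed keeps results reproducible
    dunnett = stats.dunnett(*samples, control=ctrl,
                            random_state=np.random.default_rng(0))
    return pd.DataFrame({"group": names, "p_anova": float(p_anova),
                         "p_adjusted": dunnett.pvalue,
                         "flag": ""})


def normalize_mutant_binding(measurements: pd.DataFrame,
                             wt: str = "WT") -> pd.DataFrame:
    """Expression-corrected binding as percent of wild type.

    measurements: construct, experiment, replicate, counts, band_intensity.
    Per experiment, each construct's mean counts/band_intensity ratio is
    divided by the wild-type ratio (x100); experiments are then averaged, so
    batch-to-batch expression differences cancel before aggregation.
    """
    required = {"construct", "experiment", "counts", "band_intensity"}
    if not required <= set(measurements.columns):
        raise ValueError(f"missing columns: {required - set(measurements.columns)}")
    if (measurements["band_intensity"] <= 0).any():
        raise ValueError("band intensities must be positive")
    rows = []
    for exp, batch in measurements.groupby("experiment"):
        ratios = batch.assign(ratio=batch["counts"] / batch["band_intensity"])
        per_construct = ratios.groupby("construct")["ratio"].mean()
        if wt not in per_construct.index:
            raise ValueError(f"experiment {exp}: wild type {wt!r} missing")
        pct = 100.0 * per_construct / per_construct[wt]
        for construct, val in pct.items():
            rows.append({"experiment": exp, "construct": construct,
                         "pct_of_wt": float(val)})
    per_exp = pd.DataFrame(rows)
    out = per_exp.groupby("construct")["pct_of_wt"] \
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count") \
        .reset_index()
    return out
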