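"""Thermal-shift hit calling: per-plate control statistics, delta-Tm, the
5 x SD rule and the staged screen -> primary -> validated cascade.

The screen classifies a compound as an initial hit when its thermal shift
delta-Tm = Tm(compound) - mean Tm(DMSO controls) exceeds, in magnitude, five
times the sample standard deviation of the DMSO-control Tm values on the
same plate.  Initial hits are confirmed in triplicate at a single high
concentration (primary hits, same rule on the triplicate mean) and then in
an eight-point concentration series (validated hits, Welch tests against the
plate controls with Holm step-down adjustment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .meltcurve import TmEstimate

logger = logging.getLogger(__name__)

STAGES = ("initial", "primary", "validated", "selected")


@dataclass(frozen=True)
class ControlStats:
    """DMSO-control Tm statistics for one plate (QC-ok wells only)."""

    plate_id: str
    mean_tm: float
    sd_tm: float
    n: int
    excluded: tuple[tuple[str, str], ...] = ()  # (well, reason)

    def threshold(self, k: float = 5.0, floor: float = 0.5) -> float:
        """Hit threshold k x SD, with a configurable absolute floor for the
        degenerate zero-SD case (logged)."""
        if self.sd_tm > 0:
            return k * self.sd_tm
        logger.warning("plate %s: control SD is 0; applying threshold floor "
                       "%.2f degC", self.plate_id, floor)
        return floor


@dataclass(frozen=True)
class HitRecord:
    compound_id: str
    delta_tm: float
    threshold: float
    direction: str  # stabilizer | destabilizer | none
    stage: str
    plate_id: str
    replicate_delta_tms: tuple[float, ...] = ()


@dataclass(frozen=True)
class DoseValidationResult:
    """Concentration-dependent validation of one primary hit."""

    compound_id: str
    table: pd.DataFrame  # concentration_M, mean_delta_tm, sd, n, p_raw,
    #                      p_adjusted, significant
    validated: bool
    rule_id: str


class PlateUnanalyzable(ValueError):
    """Raised when a plate has fewer than two usable DMSO controls."""


def summarize_controls(estimates: dict[str, TmEstimate],
                       roles: dict[str, str],
                       plate_id: str = "plate") -> ControlStats:
    """Mean and sample SD (n-1 denominator) of QC-ok DMSO-control wells.

    Control wells failing curve QC are excluded (and recorded) before the SD
    is computed, so a dead well cannot inflate every threshold on the plate.
    """
    tms, excluded = [], []
    for well, role in roles.items():
        if role != "dmso_control":
            continue
        est = estimates.get(well)
        if est is None:
            excluded.append((well, "missing estimate"))
        elif not est.ok:
            excluded.append((well, "qc:" + "|".join(est.qc)))
        else:
            tms.append(est.tm)
    if len(tms) < 2:
        raise PlateUnanalyzable(
            f"plate {plate_id}: only {len(tms)} usable DMSO controls")
    arr = np.asarray(tms)
    return ControlStats(plate_id, float(arr.mean()),
                        float(arr.std(ddof=1)), arr.size, tuple(excluded))


def compute_delta_tm(compound_tm: float, controls: ControlStats) -> float:
    """delta-Tm = Tm(compound) - Tm(DMSO control mean)."""
    return compound_tm - controls.mean_tm


def call_hits(delta_tms: dict[str, float], controls: ControlStats,
              k: float = 5.0, stage: str = "initial",
              threshold_floor: float = 0.5,
              replicate_delta_tms: dict[str, tuple[float, ...]] | None = None,
              ) -> list[HitRecord]:
    """Apply the k x SD rule to per-compound delta-Tm values.

    direction is stabilizer for delta > k*SD, destabilizer for delta < -k*SD,
    none otherwise.  For the primary stage the caller passes the triplicate
    mean delta-Tm (replicates recorded when given).
    """
    thr = controls.threshold(k, threshold_floor)
    records = []
    for cid, delta in delta_tms.items():
        if delta > thr:
            direction = "stabilizer"
        elif delta < -thr:
            direction = "destabilizer"
        else:
            direction = "none"
        reps = tuple((replicate_delta_tms or {}).get(cid, ()))
        records.append(HitRecord(cid, float(delta), thr, direction, stage,
                                 controls.plate_id, reps))
    return records


def validate_dose_response(compound_id: str,
                           tm_by_concentration: dict[float, np.ndarray],
                           controls: ControlStats,
                           control_tms: np.ndarray,
                           alpha: float = 0.05,
                           min_significant: int = 2,
                           min_effect_degc: float = 0.5,
                           ) -> DoseValidationResult:
    """Eight-point concentration-dependent confirmation.

    Per concentration, a Welch two-sample test of the compound's replicate Tm
    values against the plate's DMSO-control Tm values; Holm step-down
    adjustment across concentrations.  A concentration counts as significant
    when its adjusted p-value is below ``alpha`` AND its mean shift exceeds
    ``min_effect_degc`` in magnitude — triplicate Welch tests are
    anti-conservative when the sample variance happens to be small, so a
    p-value alone would validate spurious sub-reproducibility shifts.
    Validated when at least ``min_significant`` concentrations are
    significant with a consistent sign of the mean shift.
    """
    control_tms = np.asarray(control_tms, dtype=float)
    rows = []
    for conc in sorted(tm_by_concentration):
        tms = np.asarray(tm_by_concentration[conc], dtype=float)
        if tms.size < 2:
            rows.append((conc, float(tms.mean() - controls.mean_tm),
                         float("nan"), tms.size, float("nan")))
            continue
        t, p = stats.ttest_ind(tms, control_tms, equal_var=False)
        rows.append((conc, float(tms.mean() - controls.mean_tm),
                     float(tms.std(ddof=1)), tms.size, float(p)))
    df = pd.DataFrame(rows, columns=["concentration_M", "mean_delta_tm",
                                     "sd", "n", "p_raw"])
    testable = df["p_raw"].notna()
    adjusted = np.full(len(df), np.nan)
    if testable.any():
        adjusted[testable.to_numpy()] = multipletests(
            df.loc[testable, "p_raw"], method="holm")[1]
    df["p_adjusted"] = adjusted
    df["significant"] = (df["p_adjusted"] < alpha) & \
        (df["mean_delta_tm"].abs() > min_effect_degc)
    sig = df[df["significant"]]
    consistent = sig.empty or (sig["mean_delta_tm"] > 0).all() \
        or (sig["mean_delta_tm"] < 0).all()
    validated = bool(len(sig) >= min_significant and consistent)
    rule_id = (f"welch-holm:adj_p<{alpha}:|dTm|>{min_effect_degc}"
               f":>={min_significant}conc:same_sign")
    return DoseValidationResult(compound_id, df, validated, rule_id)


@dataclass
class CascadeResult:
    initial: list[HitRecord]
    primary: list[HitRecord]
    validated: list[DoseValidationResult]
    audit: list[dict] = field(default_factory=list)

    def stage_sets(self) -> dict[str, set[str]]:
        return {
            "initial": {h.compound_id for h in self.initial
                        if h.direction != "none"},
            "primary": {h.compound_id for h in self.primary
                        if h.direction != "none"},
            "validated": {v.compound_id for v in self.validated
                          if v.validated},
        }


def run_cascade(screen_deltas: dict[str, dict[str, float]],
                screen_controls: dict[str, ControlStats],
                primary_replicates: dict[str, dict[str, tuple[float, ...]]],
                primary_controls: dict[str, ControlStats],
                validation_data: dict[str, dict[float, np.ndarray]],
                validation_controls: ControlStats | None = None,
                validation_control_tms: np.ndarray | None = None,
                k: float = 5.0) -> CascadeResult:
    """Staged hit cascade over already-summarized Tm data.

    screen_deltas / screen_controls: per plate, single-point delta-Tm per
    compound.  primary_replicates / primary_controls: per plate, triplicate
    delta-Tm tuples for the initial hits.  validation_data: per compound,
    replicate Tm arrays by concentration.  Each stage is a subset of the
    previous; a compound absent from a later assay is carried as untested
    (recorded in the audit log), never failed.
    """
    audit: list[dict] = []
    initial: list[HitRecord] = []
    for plate_id, deltas in screen_deltas.items():
        recs = call_hits(deltas, screen_controls[plate_id], k=k,
                         stage="initial")
        initial.extend(recs)
        for r in recs:
            if r.direction == "none":
                audit.append({"stage": "initial", "compound": r.compound_id,
                              "event": "below_threshold",
                              "delta_tm": r.delta_tm,
                              "threshold": r.threshold})
    initial_set = {h.compound_id for h in initial if h.direction != "none"}

    primary: list[HitRecord] = []
    tested_primary: set[str] = set()
    for plate_id, reps in primary_replicates.items():
        reps = {cid: v for cid, v in reps.items() if cid in initial_set}
        tested_primary |= set(reps)
        means = {cid: float(np.mean(v)) for cid, v in reps.items()}
        recs = call_hits(means, primary_controls[plate_id], k=k,
                         stage="primary", replicate_delta_tms=reps)
        primary.extend(recs)
    for cid in sorted(initial_set - tested_primary):
        audit.append({"stage": "primary", "compound": cid,
                      "event": "untested"})
    primary_set = {h.compound_id for h in primary if h.direction != "none"}

    validated: list[DoseValidationResult] = []
    for cid, by_conc in validation_data.items():
        if cid not in primary_set:
            audit.append({"stage": "validated", "compound": cid,
                          "event": "not_a_primary_hit_skipped"})
            continue
        validated.append(validate_dose_response(
            cid, by_conc, validation_controls, validation_control_tms))
    for cid in sorted(primary_set - set(validation_data)):
        audit.append({"stage": "validated", "compound": cid,
                      "event": "untested"})
    return CascadeResult(initial, primary, validated, audit)


def hits_table(records: list[HitRecord]) -> pd.DataFrame:
    """Staged hit table (TSV-ready): compound_id, stage, delta_tm, sd,
    threshold, direction."""
    rows = []
    for r in records:
        sd = float(np.std(r.replicate_delta_tms, ddof=1)) \
            if len(r.replicate_delta_tms) >= 2 else np.nan
        rows.append({"compound_id": r.compound_id, "stage": r.stage,
                     "delta_tm": r.delta_tm, "sd": sd,
                     "threshold": r.threshold, "direction": r.direction,
                     "plate_id": r.plate_id})
    return pd.DataFrame(rows)
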