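"""End-to-end orchestration: simulate -> Tm -> hit cascade -> cluster ->
dose-response -> MD report, from a single seeded configuration.

Every stochastic stage derives its seed deterministically from the global
seed plus the stage name, so an identical configuration yields byte-identical
summaries.  The synthetic demo emulates a 1280-compound single-point screen
(384-well plates, 32 DMSO controls each), triplicate confirmation at 200 uM,
an 8-point concentration validation, fingerprint clustering of the primary
hits, and IC50 determination for the selected candidates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemcluster, doseresponse, mdpost, screening, synthetic
from .meltcurve import TmConfig, batch_tm, determine_tm
from .synthetic import (PlateSpec, SyntheticDoseParams, SyntheticMeltParams,
                        generate_melt_curve, generate_plate, half_log_dilution,
                        make_plate_layout)

logger = logging.getLogger(__name__)

STAGE_NAMES = ("library", "screen", "primary", "validate", "cluster",
               "doseresponse", "mdpost")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2^31)."""
    return (int(global_seed) * 2654435761 + zlib.crc32(stage.encode())) \
        % (2 ** 31)


@dataclass
class RunConfig:
    """Flat run configuration; unknown keys are rejected on load."""

    seed: int = 0
    n_compounds: int = 1280
    frac_active: float = 0.05
    effect_range: tuple[float, float] = (2.0, 12.0)
    compounds_per_plate: int = 352
    n_controls: int = 32
    control_tm_mean: float = synthetic.CONTROL_TM_MEAN
    control_tm_sd: float = synthetic.CONTROL_TM_SD
    k_multiplier: float = 5.0
    threshold_floor: float = 0.5
    screen_concentration_m: float = 167e-6
    primary_concentration_m: float = 200e-6
    validation_points: int = 8
    validation_range: tuple[float, float] = (120e-9, 270e-6)
    validation_replicates: int = 3
    k_clusters: int = 30
    fingerprint_bits: int = 1024
    linkage_method: str = "average"
    dr_top_concentration_m: float = 100e-6
    dr_points: int = 10
    dr_replicates: int = 3
    dr_experiments: int = 3
    dr_cv_noise: float = 0.05
    max_dr_compounds: int = 16
    stages: dict = field(default_factory=lambda: {s: True
                                                  for s in STAGE_NAMES})
    outdir: str | None = None

    def __post_init__(self):
        if self.n_compounds < 1 or self.compounds_per_plate < 1:
            raise ValueError("compound counts must be positive")
        if not (0 <= self.frac_active <= 1):
            raise ValueError("frac_active must be in [0, 1]")
        unknown = set(self.stages) - set(STAGE_NAMES)
        if unknown:
            raise ValueError(f"unknown stages in config: {sorted(unknown)}")
        for s in STAGE_NAMES:
            self.stages.setdefault(s, True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "effect_range" in d:
            d["effect_range"] = tuple(d["effect_range"])
        if "validation_range" in d:
            d["validation_range"] = tuple(d["validation_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _plate_tm_stats(curves, tm_config: TmConfig, plate_id: str):
    """Estimate per-well Tm and control statistics for one simulated plate."""
    estimates = batch_tm(curves, tm_config)
    roles = {c.well_id: c.role for c in curves}
    stats = screening.summarize_controls(estimates, roles, plate_id)
    return estimates, stats


def _dsf_effect(effect: float, conc: float, midpoint: float) -> float:
    """Concentration-dependent thermal shift: saturating occupancy model."""
    return effect * conc / (conc + midpoint)


def run(config: RunConfig,
        melt_params: SyntheticMeltParams = SyntheticMeltParams(),
        tm_config: TmConfig = TmConfig()) -> dict:
    """Execute the enabled stages in dependency order; returns the
    machine-readable summary (also written to outdir when configured)."""
    summary: dict = {"config": {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in dataclasses.asdict(config).items()}}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # --- library -----------------------------------------------------------
    if not config.stages["library"]:
        raise ValueError("the synthetic demo requires the library stage")
    library, lib_truth = synthetic.generate_library(
        config.n_compounds, config.frac_active, config.effect_range,
        seed=stage_seed(config.seed, "library"))
    effects = lib_truth.records["effects"]
    rng_lib = np.random.default_rng(stage_seed(config.seed, "library-dsf"))
    # per-compound DSF midpoint for the concentration-dependent shift
    # (log-uniform 0.1-10 uM: medium-high affinity binders saturate their
    # thermal shift within the screened concentration range)
    dsf_midpoint = {cid: float(10 ** rng_lib.uniform(-7.0, -5.0))
                    for cid, eff in effects.items() if eff != 0.0}
    truth_active = sorted(cid for cid, e in effects.items() if e != 0.0)
    summary["library"] = {"n_compounds": len(library),
                          "n_active_truth": len(truth_active)}

    # --- single-point screen ----------------------------------------------
    if not config.stages["screen"]:
        summary["stages_run"] = ["library"]
        return _finalize(summary, outdir)
    ids = library["compound_id"].tolist()
    plate_chunks = [ids[i:i + config.compounds_per_plate]
                    for i in range(0, len(ids), config.compounds_per_plate)]
    screen_deltas: dict[str, dict[str, float]] = {}
    screen_controls: dict[str, screening.ControlStats] = {}
    truth_initial: set[str] = set()
    initial_records: list[screening.HitRecord] = []
    for p_idx, chunk in enumerate(plate_chunks):
        plate_id = f"SP{p_idx + 1:02d}"
        spec = PlateSpec(
            plate_id=plate_id,
            layout=make_plate_layout(chunk, config.screen_concentration_m,
                                     config.n_controls),
            control_tm_mean=config.control_tm_mean,
            control_tm_sd=config.control_tm_sd,
            effect_map={cid: _dsf_effect(effects[cid],
                                         config.screen_concentration_m,
                                         dsf_midpoint.get(cid, 1.0))
                        for cid in chunk if effects[cid] != 0.0},
            k_multiplier=config.k_multiplier,
            threshold_floor=config.threshold_floor,
            seed=stage_seed(config.seed, f"screen:{plate_id}"))
        curves, truth = generate_plate(spec, melt_params)
        truth_initial |= set(truth.records["hit_set"])
        estimates, stats = _plate_tm_stats(curves, tm_config, plate_id)
        well_meta = {c.well_id: c for c in curves}
        deltas = {}
        for well, est in estimates.items():
            c = well_meta[well]
            if c.role != "sample" or not est.ok:
                continue
            deltas[c.compound_id] = screening.compute_delta_tm(est.tm, stats)
        screen_deltas[plate_id] = deltas
        screen_controls[plate_id] = stats
        initial_records.extend(screening.call_hits(
            deltas, stats, k=config.k_multiplier, stage="initial",
            threshold_floor=config.threshold_floor))
    initial_hits = sorted({r.compound_id for r in initial_records
                           if r.direction != "none"})
    summary["screen"] = {
        "n_plates": len(plate_chunks),
        "initial_hits": initial_hits,
        "n_initial": len(initial_hits),
        "truth_initial": sorted(truth_initial),
        "thresholds": {pid: screen_controls[pid].threshold(
            config.k_multiplier, config.threshold_floor)
            for pid in sorted(screen_controls)},
    }

    # --- primary confirmation (triplicates at one high concentration) ------
    if not config.stages["primary"]:
        return _finalize(summary, outdir)
    rng_primary = np.random.default_rng(stage_seed(config.seed, "primary"))
    prim_layout_ids = [f"{cid}#r{r}" for cid in initial_hits
                       for r in (1, 2, 3)]
    per_plate = (384 - config.n_controls) // 3 * 3
    primary_deltas_truth: dict[str, float] = {}
    primary_records: list[screening.HitRecord] = []
    truth_primary: set[str] = set()
    chunk_idx = 0
    for i in range(0, len(prim_layout_ids), per_plate):
        chunk_idx += 1
        plate_id = f"PP{chunk_idx:02d}"
        chunk = prim_layout_ids[i:i + per_plate]
        spec = PlateSpec(
            plate_id=plate_id,
            layout=make_plate_layout(chunk, config.primary_concentration_m,
                                     config.n_controls),
            control_tm_mean=config.control_tm_mean,
            control_tm_sd=config.control_tm_sd,
            effect_map={wid: _dsf_effect(effects[wid.split("#")[0]],
                                         config.primary_concentration_m,
                                         dsf_midpoint.get(wid.split("#")[0],
                                                          1.0))
                        for wid in chunk
                        if effects[wid.split("#")[0]] != 0.0},
            k_multiplier=config.k_multiplier,
            threshold_floor=config.threshold_floor,
            seed=int(rng_primary.integers(2 ** 31)))
        curves, t = generate_plate(spec, melt_params)
        estimates, stats = _plate_tm_stats(curves, tm_config, plate_id)
        well_meta = {c.well_id: c for c in curves}
        reps_est: dict[str, list[float]] = {}
        for well, est in estimates.items():
            c = well_meta[well]
            if c.role != "sample" or not est.ok:
                continue
            cid = c.compound_id.split("#")[0]
            reps_est.setdefault(cid, []).append(
                screening.compute_delta_tm(est.tm, stats))
        means = {cid: float(np.mean(v)) for cid, v in reps_est.items()}
        primary_records.extend(screening.call_hits(
            means, stats, k=config.k_multiplier, stage="primary",
            threshold_floor=config.threshold_floor,
            replicate_delta_tms={c: tuple(v) for c, v in reps_est.items()}))
        # exact-rule truth on the drawn Tm values of the same plate
        by_cid: dict[str, list[float]] = {}
        for w in t.records["wells"].values():
            if w["role"] != "sample":
                continue
            by_cid.setdefault(w["compound_id"].split("#")[0], []) \
                .append(w["delta_true"])
        thr = t.records["threshold"]
        for cid, deltas in by_cid.items():
            m = float(np.mean(deltas))
            primary_deltas_truth[cid] = m
            if abs(m) > thr:
                truth_primary.add(cid)
    primary_hits = sorted({r.compound_id for r in primary_records
                           if r.direction != "none"})
    n_stab = sum(1 for r in primary_records if r.direction == "stabilizer")
    n_destab = sum(1 for r in primary_records
                   if r.direction == "destabilizer")
    summary["primary"] = {"primary_hits": primary_hits,
                          "n_primary": len(primary_hits),
                          "n_stabilizers": n_stab,
                          "n_destabilizers": n_destab,
                          "truth_primary": sorted(truth_primary)}

    # --- 8-point concentration-dependent validation -------------------------
    if not config.stages["validate"]:
        return _finalize(summary, outdir)
    lo, hi = config.validation_range
    concs = np.geomspace(lo, hi, config.validation_points)
    rng_val = np.random.default_rng(stage_seed(config.seed, "validate"))
    # one shared control set for the validation batch
    ctrl_tms_drawn = rng_val.normal(config.control_tm_mean,
                                    config.control_tm_sd, config.n_controls)
    ctrl_est, ctrl_drawn_list = [], []
    for i, tm_true in enumerate(ctrl_tms_drawn):
        p = dataclasses.replace(melt_params, tm_true=float(tm_true),
                                seed=None)
        curve, _ = generate_melt_curve(p, well_id=f"VC{i}",
                                       role="dmso_control", rng=rng_val)
        ctrl_est.append(determine_tm(curve, tm_config).tm)
        ctrl_drawn_list.append(float(tm_true))
    ctrl_est = np.asarray(ctrl_est)
    ctrl_drawn = np.asarray(ctrl_drawn_list)
    stats_est = screening.ControlStats("VAL", float(ctrl_est.mean()),
                                       float(ctrl_est.std(ddof=1)),
                                       ctrl_est.size)
    stats_drawn = screening.ControlStats("VAL", float(ctrl_drawn.mean()),
                                         float(ctrl_drawn.std(ddof=1)),
                                         ctrl_drawn.size)
    validated_results = []
    truth_validated: set[str] = set()
    for cid in primary_hits:
        by_conc_est: dict[float, np.ndarray] = {}
        by_conc_drawn: dict[float, np.ndarray] = {}
        for conc in concs:
            eff = _dsf_effect(effects[cid], conc, dsf_midpoint.get(cid, 1.0)) \
                if effects[cid] != 0.0 else 0.0
            drawn = rng_val.normal(config.control_tm_mean,
                                   config.control_tm_sd,
                                   config.validation_replicates) + eff
            est = []
            for tm_true in drawn:
                p = dataclasses.replace(melt_params, tm_true=float(tm_true),
                                        seed=None)
                curve, _ = generate_melt_curve(p, well_id="V",
                                               compound_id=cid, rng=rng_val)
                est.append(determine_tm(curve, tm_config).tm)
            by_conc_est[float(conc)] = np.asarray(est)
            by_conc_drawn[float(conc)] = drawn
        res = screening.validate_dose_response(cid, by_conc_est, stats_est,
                                               ctrl_est)
        validated_results.append(res)
        res_truth = screening.validate_dose_response(
            cid, by_conc_drawn, stats_drawn, ctrl_drawn)
        if res_truth.validated:
            truth_validated.add(cid)
    validated_hits = sorted(r.compound_id for r in validated_results
                            if r.validated)
    summary["validate"] = {"validated_hits": validated_hits,
                           "n_validated": len(validated_hits),
                           "truth_validated": sorted(truth_validated),
                           "rule_id": validated_results[0].rule_id
                           if validated_results else None}

    # --- clustering and candidate selection --------------------------------
    if not config.stages["cluster"]:
        return _finalize(summary, outdir)
    hit_lib = library[library["compound_id"].isin(primary_hits)]
    records = chemcluster.load_library(hit_lib, config.fingerprint_bits)
    usable = [r for r in records if not r.quarantined]
    selected: list[str] = []
    if len(usable) >= 2:
        fps = [r.fingerprint for r in usable]
        dist = chemcluster.distance_matrix(fps)
        tree = chemcluster.hierarchical_cluster(dist, config.linkage_method)
        k = min(config.k_clusters, len(usable))
        assignment = chemcluster.cut_clusters(
            tree, k, [r.compound_id for r in usable])
        # mean primary delta-Tm per compound drives representative choice
        hit_deltas = {}
        for r in primary_records:
            if r.compound_id in validated_hits:
                hit_deltas[r.compound_id] = r.delta_tm
        selected, controls_list, audit = chemcluster.select_candidates(
            hit_deltas, assignment, usable)
        summary["cluster"] = {"k": k, "n_clustered": len(usable),
                              "selected": sorted(selected),
                              "n_selected": len(selected),
                              "control_compounds": sorted(controls_list)}
        if outdir:
            pd.DataFrame(sorted(assignment.items()),
                         columns=["compound_id", "cluster"]) \
                .to_csv(outdir / "cluster_assignment.csv", index=False)
            (outdir / "linkage.nwk").write_text(chemcluster.to_newick(
                tree, [r.compound_id for r in usable]))
    else:
        summary["cluster"] = {"k": 0, "n_clustered": len(usable),
                              "selected": [], "n_selected": 0,
                              "control_compounds": []}

    # --- dose-response (uptake IC50) ----------------------------------------
    if not config.stages["doseresponse"]:
        return _finalize(summary, outdir)
    rng_dr = np.random.default_rng(stage_seed(config.seed, "doseresponse"))
    dr_compounds = sorted(selected)[:config.max_dr_compounds]
    concs_dr = half_log_dilution(config.dr_top_concentration_m,
                                 config.dr_points)
    ic50_rows = []
    for cid in dr_compounds:
        true_ic50 = float(10 ** rng_dr.uniform(-7.5, -5.3))
        fits = []
        for exp in range(config.dr_experiments):
            params = SyntheticDoseParams(
                true_midpoint=true_ic50, hill=1.0, top=1000.0, bottom=0.0,
                concentrations=concs_dr,
                replicates=config.dr_replicates,
                cv_noise=config.dr_cv_noise, background_level=100.0,
                compound_id=cid, seed=None)
            series, _ = generate_dose_response_seeded(params, rng_dr)
            specific = doseresponse.subtract_background(series)
            fits.append(doseresponse.fit_4pl(specific, compound_id=cid,
                                             seed=0))
        agg = doseresponse.aggregate_fits(fits, min_n=2)
        ic50_rows.append({"compound_id": cid,
                          "ic50_true_uM": true_ic50 * 1e6,
                          "ic50_mean_uM": agg["mean"] * 1e6
                          if np.isfinite(agg["mean"]) else None,
                          "ic50_sd_uM": agg["sd"] * 1e6
                          if np.isfinite(agg["sd"]) else None,
                          "n_experiments": agg["n"],
                          "status": agg["status"]})
    summary["doseresponse"] = {"table": ic50_rows}

    # --- MD post-processing report ------------------------------------------
    if config.stages["mdpost"]:
        lists, state_of = mdpost.load_reference_contributors()
        summary["mdpost"] = mdpost.hotspot_report(lists, state_of)

    summary["truth_vs_recovered"] = {
        "initial_equal": sorted(truth_initial) == initial_hits,
        "primary_equal": sorted(truth_primary) == primary_hits,
        "validated_equal": sorted(truth_validated) == validated_hits,
    }
    return _finalize(summary, outdir)


def generate_dose_response_seeded(params: SyntheticDoseParams,
                                  rng: np.random.Generator):
    """Dose-response generation with an externally supplied generator (for
    stage-level seeding)."""
    return synthetic.generate_dose_response(params, rng=rng)


def _finalize(summary: dict, outdir: Path | None) -> dict:
    summary["stages_run"] = [k for k in summary if k in STAGE_NAMES]
    if outdir:
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True, default=str))
    return summary


def summary_bytes(summary: dict) -> bytes:
    """Canonical serialization used for byte-stability checks."""
    return json.dumps(summary, indent=1, sort_keys=True,
                      default=str).encode()
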