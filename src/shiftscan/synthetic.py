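"""Seeded synthetic-data generators with carried ground truth.

Every generator returns its outputs together with a :class:`SyntheticTruth`
record holding the true parameters used, so downstream recovery tests can be
exact rather than probabilistic.

The melt-curve model is a two-state van 't Hoff unfolding with linear native
and unfolded baselines and an optional post-transition exponential decay of
the dye signal:

    K(T)   = exp((dH_vH / R) * (1/Tm - 1/T))          (T, Tm in kelvin)
    f_u(T) = K / (1 + K)                              (unfolded fraction)
    F(T)   = [F_N(T) + F_U(T) * K(T)] / (1 + K(T)) * D(T) + eps
    D(T)   = exp(-decay_rate * max(0, T - Tm))

so the unfolded fraction is exactly 0.5 at Tm.  The default regime emulates
a detergent-solubilized transporter with a DMSO-control Tm of 62.6 C and a
well-to-well control SD of 0.32 C on a 384-well plate screened from 25 to
95 C.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy.constants import R as _R_J

from .meltcurve import MeltCurve

R_KCAL = _R_J / 4184.0  # gas constant, kcal/(mol K)
CELSIUS_OFFSET = 273.15

#: Default DMSO-control regime (plate-level, degC).
CONTROL_TM_MEAN = 62.6
CONTROL_TM_SD = 0.32

#: Fluorescence noise (AU) at which the smoothed-derivative Tm estimator
#: scatters by ~0.3 degC on the default grid/curve shape -- the calibrated
#: single-curve noise regime.  Plate traces use the much smaller default in
#: SyntheticMeltParams (instrument melt traces are smooth; well-to-well Tm
#: variation dominates the observed control SD).
CALIBRATED_NOISE_SD = 0.03


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


@dataclass
class SyntheticTruth:
    """Ground-truth record carried alongside every generated dataset."""

    kind: str
    params: dict[str, Any]
    records: dict[str, Any]

    def to_json(self, path: str | Path) -> None:
        def default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))
        Path(path).write_text(
            json.dumps(asdict(self), indent=1, sort_keys=True,
                       default=default))


# ---------------------------------------------------------------------------
# Melt curves

@dataclass(frozen=True)
class SyntheticMeltParams:
    """Parameters of one synthetic two-state melt curve.

    dh_vanthoff is the van 't Hoff unfolding enthalpy (kcal/mol) setting the
    transition sharpness; baselines are (intercept AU, slope AU/degC);
    decay_rate (1/degC, >= 0) models post-transition signal decline.
    """

    tm_true: float = CONTROL_TM_MEAN
    dh_vanthoff: float = 150.0
    native_baseline: tuple[float, float] = (1.0, 0.001)
    unfolded_baseline: tuple[float, float] = (3.0, -0.005)
    decay_rate: float = 0.02
    noise_sd: float = 0.002
    temp_range: tuple[float, float] = (25.0, 95.0)
    temp_step: float = 0.1
    seed: int | None = 0

    def __post_init__(self):
        lo, hi = self.temp_range
        if self.temp_step <= 0:
            raise ValueError("temp_step must be > 0")
        if not (lo < self.tm_true < hi):
            raise ValueError("tm_true must lie strictly inside temp_range")
        if self.dh_vanthoff <= 0:
            raise ValueError("dh_vanthoff must be > 0")
        if self.noise_sd < 0 or self.decay_rate < 0:
            raise ValueError("noise_sd and decay_rate must be >= 0")

    @property
    def temperatures(self) -> np.ndarray:
        lo, hi = self.temp_range
        n = int(round((hi - lo) / self.temp_step)) + 1
        return lo + self.temp_step * np.arange(n)


def unfolded_fraction(params: SyntheticMeltParams,
                      temps_c: np.ndarray) -> np.ndarray:
    """Two-state unfolded fraction K/(1+K) on the Kelvin scale."""
    t_k = np.asarray(temps_c, dtype=float) + CELSIUS_OFFSET
    tm_k = params.tm_true + CELSIUS_OFFSET
    log_k = (params.dh_vanthoff / R_KCAL) * (1.0 / tm_k - 1.0 / t_k)
    # equivalent to K/(1+K), stable for large |log_k|
    return 1.0 / (1.0 + np.exp(-log_k))


def melt_fluorescence(params: SyntheticMeltParams,
                      temps_c: np.ndarray) -> np.ndarray:
    """Noise-free model fluorescence F(T) at the given temperatures (degC)."""
    t = np.asarray(temps_c, dtype=float)
    fu = unfolded_fraction(params, t)
    b_n = params.native_baseline[0] + params.native_baseline[1] * t
    b_u = params.unfolded_baseline[0] + params.unfolded_baseline[1] * t
    decay = np.exp(-params.decay_rate * np.maximum(0.0, t - params.tm_true))
    return (b_n * (1 - fu) + b_u * fu) * decay


def generate_melt_curve(params: SyntheticMeltParams,
                        well_id: str = "A1",
                        compound_id: str | None = None,
                        concentration_m: float | None = None,
                        role: str = "sample",
                        rng: np.random.Generator | None = None,
                        ) -> tuple[MeltCurve, SyntheticTruth]:
    """One seeded melt curve plus its truth record."""
    if rng is None:
        rng = _rng(params.seed)
    t = params.temperatures
    f = melt_fluorescence(params, t)
    if params.noise_sd > 0:
        f = f + rng.normal(0.0, params.noise_sd, size=t.size)
    curve = MeltCurve(well_id, t, f, compound_id=compound_id,
                      concentration_m=concentration_m, role=role)
    truth = SyntheticTruth(
        kind="melt_curve",
        params={k: v for k, v in asdict(params).items()},
        records={well_id: {"tm_true": params.tm_true}},
    )
    return curve, truth


# ---------------------------------------------------------------------------
# Screening plates

@dataclass(frozen=True)
class PlateSpec:
    """One screening plate: well layout plus true thermal-shift effects.

    layout maps well id -> (compound_id or None for a DMSO control,
    concentration in M).  effect_map gives each compound's true delta-Tm in
    degC (compounds absent from the map are inactive).  The truth hit set is
    defined against the realized control draw: a well is a true hit when its
    drawn Tm deviates from the drawn-control mean by more than
    k_multiplier x the drawn-control sample SD.
    """

    plate_id: str
    layout: dict[str, tuple[str | None, float]]
    control_tm_mean: float = CONTROL_TM_MEAN
    control_tm_sd: float = CONTROL_TM_SD
    effect_map: dict[str, float] = field(default_factory=dict)
    replicate_noise: float = 0.0
    k_multiplier: float = 5.0
    threshold_floor: float = 0.5
    seed: int | None = 0

    def __post_init__(self):
        if not self.layout:
            raise ValueError("plate layout is empty")
        controls = [w for w, (cid, _) in self.layout.items() if cid is None]
        if len(controls) < 2:
            raise ValueError("plate needs >= 2 DMSO-control wells")
        if self.control_tm_sd < 0 or self.replicate_noise < 0:
            raise ValueError("spread parameters must be >= 0")


def wells_384() -> list[str]:
    """Well ids of a 384-well plate, row-major A1..P24."""
    rows = string.ascii_uppercase[:16]
    return [f"{r}{c}" for r in rows for c in range(1, 25)]


def make_plate_layout(compound_ids: list[str],
                      concentration_m: float = 167e-6,
                      n_controls: int = 32) -> dict[str, tuple[str | None, float]]:
    """384-well layout: DMSO controls in the outer columns (1 and 24 by
    default), compounds row-major in the remainder."""
    wells = wells_384()
    control_wells = [w for w in wells
                     if w.endswith("1") and not w[-2].isdigit()] + \
                    [w for w in wells if w[1:] == "24"]
    control_wells = control_wells[:n_controls]
    sample_wells = [w for w in wells if w not in control_wells]
    if len(compound_ids) > len(sample_wells):
        raise ValueError("too many compounds for one 384-well plate")
    layout: dict[str, tuple[str | None, float]] = {
        w: (None, 0.0) for w in control_wells}
    for w, cid in zip(sample_wells, compound_ids):
        layout[w] = (cid, concentration_m)
    return layout


def draw_plate_tms(spec: PlateSpec,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw true per-well Tm values for a plate.

    Control wells: Tm ~ N(control_tm_mean, control_tm_sd).  Compound wells:
    an independent control-distribution draw plus the compound's true
    delta-Tm plus replicate noise.
    """
    if rng is None:
        rng = _rng(spec.seed)
    rows = []
    for well, (cid, conc) in spec.layout.items():
        base = rng.normal(spec.control_tm_mean, spec.control_tm_sd)
        if cid is None:
            rows.append((well, None, 0.0, "dmso_control", base, 0.0))
        else:
            eff = spec.effect_map.get(cid, 0.0)
            noise = rng.normal(0.0, spec.replicate_noise) \
                if spec.replicate_noise > 0 else 0.0
            rows.append((well, cid, conc, "sample", base + eff + noise, eff))
    return pd.DataFrame(
        rows, columns=["well", "compound_id", "concentration_M", "role",
                       "tm_true", "effect_true"])


def plate_truth(spec: PlateSpec, tms: pd.DataFrame) -> SyntheticTruth:
    """Exact-rule truth for a drawn plate: the k x SD rule applied to the
    realized control sample."""
    ctrl = tms.loc[tms["role"] == "dmso_control", "tm_true"]
    mean_c = float(ctrl.mean())
    sd_c = float(ctrl.std(ddof=1))
    thr = spec.k_multiplier * sd_c if sd_c > 0 else spec.threshold_floor
    wells: dict[str, Any] = {}
    hits: list[str] = []
    for rec in tms.itertuples():
        delta = rec.tm_true - mean_c
        direction = "none"
        if rec.role == "sample":
            if delta > thr:
                direction = "stabilizer"
            elif delta < -thr:
                direction = "destabilizer"
            if direction != "none":
                hits.append(rec.compound_id)
        wells[rec.well] = {"compound_id": rec.compound_id,
                           "tm_true": rec.tm_true,
                           "effect_true": rec.effect_true,
                           "delta_true": delta,
                           "direction": direction,
                           "role": rec.role}
    return SyntheticTruth(
        kind="plate",
        params={"plate_id": spec.plate_id,
                "control_tm_mean": spec.control_tm_mean,
                "control_tm_sd": spec.control_tm_sd,
                "k_multiplier": spec.k_multiplier,
                "seed": spec.seed},
        records={"wells": wells,
                 "control_mean_drawn": mean_c,
                 "control_sd_drawn": sd_c,
                 "threshold": thr,
                 "hit_set": sorted(hits)})


def generate_plate(spec: PlateSpec,
                   melt_params: SyntheticMeltParams = SyntheticMeltParams(),
                   ) -> tuple[list[MeltCurve], SyntheticTruth]:
    """Full plate of melt curves: per-well Tm draws rendered through the
    two-state curve model, plus exact-rule truth."""
    rng = _rng(spec.seed)
    tms = draw_plate_tms(spec, rng)
    truth = plate_truth(spec, tms)
    curves = []
    for rec in tms.itertuples():
        p = SyntheticMeltParams(
            tm_true=rec.tm_true,
            dh_vanthoff=melt_params.dh_vanthoff,
            native_baseline=melt_params.native_baseline,
            unfolded_baseline=melt_params.unfolded_baseline,
            decay_rate=melt_params.decay_rate,
            noise_sd=melt_params.noise_sd,
            temp_range=melt_params.temp_range,
            temp_step=melt_params.temp_step,
            seed=None)
        curve, _ = generate_melt_curve(
            p, well_id=rec.well, compound_id=rec.compound_id,
            concentration_m=rec.concentration_M, role=rec.role, rng=rng)
        curves.append(curve)
    return curves, truth


# ---------------------------------------------------------------------------
# Dose-response series

@dataclass(frozen=True)
class SyntheticDoseParams:
    """One synthetic dose-response series on the four-parameter logistic
    y = bottom + (top - bottom) / (1 + (x / midpoint)^hill), with
    multiplicative Gaussian noise of the stated CV and a paired control-cell
    background series at background_level."""

    true_midpoint: float  # M
    hill: float = 1.0
    top: float = 1000.0
    bottom: float = 0.0
    concentrations: tuple[float, ...] = ()
    replicates: int = 3
    cv_noise: float = 0.05
    background_level: float = 100.0
    compound_id: str = "CPD"
    seed: int | None = 0

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size < 1 or np.any(conc <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be sorted ascending")
        if not (0 <= self.cv_noise < 1):
            raise ValueError("cv_noise must be in [0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.true_midpoint <= 0:
            raise ValueError("true_midpoint must be > 0")


def half_log_dilution(top_m: float, n_points: int) -> tuple[float, ...]:
    """n half-log (sqrt(10)) dilution steps descending from top_m, returned
    ascending."""
    points = top_m / (10 ** (0.5 * np.arange(n_points)))
    return tuple(sorted(points))


def four_pl(x, bottom, top, midpoint, hill):
    """Four-parameter logistic, decreasing in x for hill > 0."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / midpoint) ** hill)


def generate_dose_response(params: SyntheticDoseParams,
                           rng: np.random.Generator | None = None,
                           ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Seeded dose-response measurements (transfected + control wells)."""
    if rng is None:
        rng = _rng(params.seed)
    rows = []
    for conc in params.concentrations:
        y_true = four_pl(conc, params.bottom + params.background_level,
                         params.top + params.background_level,
                         params.true_midpoint, params.hill)
        for rep in range(1, params.replicates + 1):
            y = y_true * (1.0 + rng.normal(0.0, params.cv_noise)) \
                if params.cv_noise > 0 else y_true
            rows.append((params.compound_id, conc, rep, y, "transfected"))
            bg = params.background_level * \
                (1.0 + rng.normal(0.0, params.cv_noise)) \
                if params.cv_noise > 0 else params.background_level
            rows.append((params.compound_id, conc, rep, bg, "control"))
    df = pd.DataFrame(rows, columns=["compound_id", "concentration_M",
                                     "replicate", "signal", "well_type"])
    truth = SyntheticTruth(
        kind="dose_response",
        params=asdict(params),
        records={params.compound_id: {
            "true_midpoint": params.true_midpoint,
            "hill": params.hill, "top": params.top,
            "bottom": params.bottom,
            "background_level": params.background_level}})
    return df, truth


# ---------------------------------------------------------------------------
# MD-analysis tables

@dataclass(frozen=True)
class SyntheticMDParams:
    """Synthetic per-residue decomposition / H-bond / enthalpy / RMSD tables.

    planted_hotspots maps residue -> (mean energy kcal/mol, tuple of system
    ids in which it is planted); means must be below -1.0 kcal/mol.
    occupancy_truth maps (system, donor, acceptor) -> occupancy percent.
    rmsd_profile: (protein level A, ligand level A, jitter A, total ns,
    optional list of (time_ns, jump_A) step events applied to the ligand).
    """

    systems: tuple[str, ...]
    residue_pool: tuple[str, ...]
    planted_hotspots: dict[str, tuple[float, tuple[str, ...]]] = \
        field(default_factory=dict)
    energy_noise_sd: float = 0.2
    background_energy_sd: float = 0.3
    occupancy_truth: dict[tuple[str, str, str], float] = \
        field(default_factory=dict)
    enthalpy_mean: dict[str, float] = field(default_factory=dict)
    enthalpy_sd: float = 5.0
    n_frames: int = 1000
    rmsd_profile: tuple = (1.5, 2.0, 0.2, 500.0, ())
    seed: int | None = 0

    def __post_init__(self):
        if len(set(self.systems)) != len(self.systems):
            raise ValueError("duplicate system ids")
        for res, (mean, _) in self.planted_hotspots.items():
            if mean >= -1.0:
                raise ValueError(
                    f"planted hot-spot mean for {res} must be < -1.0 kcal/mol")
        for occ in self.occupancy_truth.values():
            if not (0 <= occ <= 100):
                raise ValueError("occupancies must be in [0, 100]")


def generate_md_tables(params: SyntheticMDParams,
                       ) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Decomposition, H-bond, enthalpy-trace and RMSD-trace tables.

    Planted hot spots are guaranteed below the -1.0 kcal/mol cutoff in their
    designated systems (draws above the cutoff are redrawn); background
    residues scatter around zero.
    """
    rng = _rng(params.seed)
    decomp_rows, hb_rows, enth_rows, rmsd_rows = [], [], [], []
    for sys_id in params.systems:
        for res in params.residue_pool:
            planted = params.planted_hotspots.get(res)
            if planted is not None and sys_id in planted[1]:
                e = rng.normal(planted[0], params.energy_noise_sd)
                while e >= -1.0:
                    e = rng.normal(planted[0], params.energy_noise_sd)
            else:
                e = rng.normal(0.0, params.background_energy_sd)
            decomp_rows.append((sys_id, res, e))
        mean_h = params.enthalpy_mean.get(sys_id, -50.0)
        frames = rng.normal(mean_h, params.enthalpy_sd, size=params.n_frames)
        for i, v in enumerate(frames):
            enth_rows.append((sys_id, i, v))
        prot, lig, jitter, total_ns, events = params.rmsd_profile
        t = np.linspace(0.0, total_ns, 501)
        rp = prot + rng.normal(0, jitter, t.size)
        rl = lig + rng.normal(0, jitter, t.size)
        for when, jump in events:
            rl = np.where(t >= when, rl + jump, rl)
        rp, rl = np.abs(rp), np.abs(rl)
        for ti, a, b in zip(t, rp, rl):
            rmsd_rows.append((sys_id, ti, a, b))
    for (sys_id, donor, acceptor), occ in params.occupancy_truth.items():
        hb_rows.append((sys_id, donor, acceptor, occ))
    tables = {
        "decomp": pd.DataFrame(
            decomp_rows, columns=["system_id", "residue", "energy_kcal_mol"]),
        "hbonds": pd.DataFrame(
            hb_rows, columns=["system_id", "donor", "acceptor",
                              "occupancy_pct"]),
        "enthalpy": pd.DataFrame(
            enth_rows, columns=["system_id", "frame", "enthalpy_kcal_mol"]),
        "rmsd": pd.DataFrame(
            rmsd_rows, columns=["system_id", "time_ns", "rmsd_protein_A",
                                "rmsd_ligand_A"]),
    }
    truth = SyntheticTruth(
        kind="md_tables",
        params={"systems": list(params.systems), "seed": params.seed},
        records={
            "planted_hotspots": {
                res: {"mean": mean, "systems": list(systems)}
                for res, (mean, systems) in params.planted_hotspots.items()},
            "occupancy": {f"{s}|{d}|{a}": occ for (s, d, a), occ
                          in params.occupancy_truth.items()},
            "enthalpy_mean": dict(params.enthalpy_mean)})
    return tables, truth


# ---------------------------------------------------------------------------
# Compound library (SMILES + annotation flags)

_SCAFFOLDS = ["c1ccccc1", "c1ccncc1", "c1ccc2ccccc2c1", "C1CCNCC1",
              "C1CCOCC1", "c1ccsc1", "c1cnc2ccccc2c1", "C1CCCCC1"]
_LINKERS = ["C", "CC", "CCC", "CO", "CN", "C(C)", "CCO", "CCN", "C(=O)N",
            "C(=O)O", "CS", "C(O)"]
_TERMINALS = ["C", "O", "N", "Cl", "F", "C(C)C", "C#N", "C(F)(F)F"]


def generate_library(n_compounds: int = 1280, frac_active: float = 0.05,
                     effect_range: tuple[float, float] = (2.0, 12.0),
                     frac_withdrawn: float = 0.05,
                     frac_known_ligand: float = 0.01,
                     seed: int | None = 0,
                     ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Synthetic screening library: unique valid SMILES assembled from
    drug-like fragments, annotation flags, and planted true delta-Tm effects
    (random sign, |effect| uniform in effect_range) for a frac_active subset.
    """
    from rdkit import Chem
    from rdkit import RDLogger
    RDLogger.DisableLog("rdApp.*")

    rng = _rng(seed)
    seen: set[str] = set()
    smiles_list: list[str] = []
    while len(smiles_list) < n_compounds:
        parts = [str(rng.choice(_SCAFFOLDS))]
        for _ in range(int(rng.integers(1, 4))):
            parts.append(str(rng.choice(_LINKERS)))
        parts.append(str(rng.choice(_TERMINALS)))
        smi = "".join(parts)
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        seen.add(canonical)
        smiles_list.append(canonical)

    n_active = int(round(frac_active * n_compounds))
    active_idx = rng.choice(n_compounds, size=n_active, replace=False)
    effects = np.zeros(n_compounds)
    lo, hi = effect_range
    magnitudes = rng.uniform(lo, hi, size=n_active)
    signs = rng.choice([-1.0, 1.0], size=n_active)
    effects[active_idx] = magnitudes * signs

    withdrawn = rng.random(n_compounds) < frac_withdrawn
    known = rng.random(n_compounds) < frac_known_ligand
    classes = rng.choice(["CNS", "CV", "Resp", "Met", "GE", "Aller", "End"],
                         size=n_compounds)
    ids = [f"CPD{i:04d}" for i in range(n_compounds)]
    df = pd.DataFrame({
        "compound_id": ids,
        "smiles": smiles_list,
        "withdrawn": withdrawn,
        "known_vmat_ligand": known,
        "class": classes,
    })
    truth = SyntheticTruth(
        kind="library",
        params={"n_compounds": n_compounds, "frac_active": frac_active,
                "effect_range": list(effect_range), "seed": seed},
        records={"effects": dict(zip(ids, effects.tolist()))})
    return df, truth


# ---------------------------------------------------------------------------
# Mutant binding batches (radioligand counts + western band intensities)

def generate_binding_batches(truth_pct: dict[str, float],
                             wt_counts: float = 10000.0,
                             n_experiments: int = 3,
                             replicates: int = 4,
                             cv_noise: float = 0.05,
                             seed: int | None = 0) -> tuple[pd.DataFrame,
                                                            SyntheticTruth]:
    """Per-experiment radioligand binding counts and band intensities with
    planted binding deficits (percent of wild type) per construct."""
    rng = _rng(seed)
    rows = []
    for exp in range(1, n_experiments + 1):
        for construct, pct in truth_pct.items():
            band = rng.uniform(0.5, 2.0)  # expression varies per experiment
            mean_counts = wt_counts * (pct / 100.0) * band
            for rep in range(1, replicates + 1):
                c = max(0.0, mean_counts * (1 + rng.normal(0, cv_noise)))
                rows.append((construct, exp, rep, c, band))
    df = pd.DataFrame(rows, columns=["construct", "experiment", "replicate",
                                     "counts", "band_intensity"])
    truth = SyntheticTruth(kind="binding", params={"seed": seed},
                           records={"pct_of_wt": dict(truth_pct)})
    return df, truth


# ---------------------------------------------------------------------------
# Writers (wide melt CSV + plate map; dose CSV; MD CSVs; truth JSON)

def write_melt_plate(curves: list[MeltCurve], melt_csv: str | Path,
                     plate_map_csv: str | Path) -> None:
    temps = curves[0].temperatures
    data = {"temperature_C": temps}
    rows = []
    for c in curves:
        if not np.array_equal(c.temperatures, temps):
            raise ValueError("all wells must share one temperature grid")
        data[c.well_id] = c.fluorescence
        rows.append({"well": c.well_id, "compound_id": c.compound_id,
                     "concentration_M": c.concentration_m, "role": c.role})
    pd.DataFrame(data).to_csv(melt_csv, index=False)
    pd.DataFrame(rows).to_csv(plate_map_csv, index=False)


def write_md_tables(tables: dict[str, pd.DataFrame],
                    outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths
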