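"""Post-processing of MD-derived tables.

Operates purely on tabular outputs of an MD/end-point-energy workflow:
per-frame RMSD traces (stability detection), per-frame binding-enthalpy
traces (mean +/- SD summaries), per-residue decomposed energies (extraction
of main contributors below a cutoff), cross-system hot-spot recurrence, and
hydrogen-bond occupancy filtering.  No trajectory parsing or energy
evaluation happens here.

A reference contributor table for 20 ligand:VMAT2 simulation systems
(reserpine, tetrabenazine, salmeterol and ziprasidone in all protonation /
stereoisomer states, docked to cytoplasm-facing and lumen-facing VMAT2
models) ships with the package; see :func:`load_reference_contributors`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

DEFAULT_ENERGY_CUTOFF = -1.0  # kcal/mol
DEFAULT_OCCUPANCY_THRESHOLD = 50.0  # percent of frames


@dataclass(frozen=True)
class ContributorList:
    """Residues of one system with decomposed energy below the cutoff,
    sorted ascending (most favorable first)."""

    system_id: str
    residues: tuple[str, ...]
    energies: tuple[float, ...]
    cutoff: float


def residue_number(label: str) -> int:
    """Numeric part of a one-letter + number residue label (tie-breaking);
    labels without a number sort last."""
    m = re.search(r"(\d+)", label)
    return int(m.group(1)) if m else 10 ** 9


def detect_stable_window(trace: pd.DataFrame, window_ns: float = 200.0,
                         protein_tol: float = 1.5,
                         ligand_tol: float = 2.0) -> tuple[float, float] | None:
    """The terminal analysis window, if stable; otherwise None.

    A binding mode qualifies for end-point analysis when both RMSD series
    have been stable through the final ``window_ns`` of the trajectory
    (max - min within the window <= the per-series tolerance) — the same
    terminal stretch that downstream frame extraction uses.  Stability
    earlier in the run does not qualify a trajectory whose ending is
    unstable.

    trace: time_ns (strictly increasing), rmsd_protein_A, rmsd_ligand_A.
    """
    t = trace["time_ns"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time_ns must be strictly increasing")
    if t[-1] - t[0] < window_ns:
        raise ValueError("window longer than the trace")
    prot = trace["rmsd_protein_A"].to_numpy(float)
    lig = trace["rmsd_ligand_A"].to_numpy(float)
    i = int(np.searchsorted(t, t[-1] - window_ns, side="left"))
    pw, lw = prot[i:], lig[i:]
    if pw.max() - pw.min() <= protein_tol and \
            lw.max() - lw.min() <= ligand_tol:
        return float(t[i]), float(t[-1])
    return None


def summarize_enthalpy(trace: pd.DataFrame | np.ndarray) -> dict:
    """Mean +/- sample SD of the per-frame binding enthalpy."""
    values = trace["enthalpy_kcal_mol"].to_numpy(float) \
        if isinstance(trace, pd.DataFrame) else np.asarray(trace, dtype=float)
    if values.size < 2:
        raise ValueError("need >= 2 frames")
    return {"mean": float(values.mean()), "sd": float(values.std(ddof=1)),
            "n_frames": int(values.size)}


def extract_contributors(table: pd.DataFrame,
                         cutoff: float = DEFAULT_ENERGY_CUTOFF,
                         system_id: str | None = None) -> ContributorList:
    """Main contributors: residues with decomposed energy strictly below the
    cutoff, sorted ascending (top contributor first), ties by residue number.

    table: residue, energy_kcal_mol (optionally system_id).
    """
    if table.empty:
        raise ValueError("empty decomposition table")
    if system_id is None:
        system_id = str(table["system_id"].iloc[0]) \
            if "system_id" in table else "?"
    if table["residue"].duplicated().any():
        raise ValueError("duplicate residue labels in one system")
    sub = table[table["energy_kcal_mol"] < cutoff]
    ordered = sorted(sub.itertuples(),
                     key=lambda r: (r.energy_kcal_mol,
                                    residue_number(r.residue)))
    return ContributorList(system_id,
                           tuple(r.residue for r in ordered),
                           tuple(float(r.energy_kcal_mol) for r in ordered),
                           cutoff)


def extract_all_contributors(decomp: pd.DataFrame,
                             cutoff: float = DEFAULT_ENERGY_CUTOFF
                             ) -> list[ContributorList]:
    """Per-system contributor lists from a stacked decomposition table."""
    return [extract_contributors(g, cutoff, system_id=str(sys_id))
            for sys_id, g in decomp.groupby("system_id", sort=True)]


def hotspot_frequency(lists: list[ContributorList],
                      state_of: dict[str, str] | None = None) -> pd.DataFrame:
    """Recurrence of residues among main contributors across systems.

    Returns residue, count, systems (tuple) and, when ``state_of`` maps
    system id -> conformational state (e.g. CYT / LUM), per-state counts.
    Ordered by descending count, ties by residue number.
    """
    if not lists:
        raise ValueError("need >= 1 contributor list")
    occurrences: dict[str, list[str]] = {}
    for cl in lists:
        for res in cl.residues:
            occurrences.setdefault(res, []).append(cl.system_id)
    rows = []
    for res, systems in occurrences.items():
        row = {"residue": res, "count": len(systems),
               "systems": tuple(systems)}
        if state_of:
            states = [state_of.get(s, "?") for s in systems]
            for st in sorted(set(state_of.values())):
                row[f"count_{st}"] = states.count(st)
        rows.append(row)
    df = pd.DataFrame(rows)
    df["_resnum"] = df["residue"].map(residue_number)
    df = df.sort_values(["count", "_resnum"], ascending=[False, True]) \
        .drop(columns="_resnum").reset_index(drop=True)
    return df


def filter_hbonds(records: pd.DataFrame,
                  threshold: float = DEFAULT_OCCUPANCY_THRESHOLD
                  ) -> pd.DataFrame:
    """Hydrogen bonds present for more than the threshold fraction of frames
    (strictly greater), grouped by system."""
    occ = records["occupancy_pct"]
    if ((occ < 0) | (occ > 100)).any():
        raise ValueError("occupancies must be in [0, 100]")
    return records[occ > threshold] \
        .sort_values(["system_id", "occupancy_pct"],
                     ascending=[True, False]).reset_index(drop=True)


def compare_states(summaries: pd.DataFrame,
                   annotation: dict[str, dict[str, str]]) -> pd.DataFrame:
    """Rank protonation/stereoisomer states per ligand by mean enthalpy.

    summaries: system_id, mean (kcal/mol); annotation maps system_id ->
    {"ligand": ..., "state": ...}.  The most favorable (lowest-mean) state is
    flagged per ligand; exact ties are reported, not silently broken.
    """
    missing = set(summaries["system_id"]) - set(annotation)
    if missing:
        raise ValueError(f"systems without annotation: {sorted(missing)}")
    df = summaries.copy()
    df["ligand"] = df["system_id"].map(lambda s: annotation[s]["ligand"])
    df["state"] = df["system_id"].map(lambda s: annotation[s]["state"])
    out = []
    for ligand, grp in df.groupby("ligand", sort=True):
        if len(grp) < 2:
            raise ValueError(f"ligand {ligand!r}: need >= 2 states to compare")
        grp = grp.sort_values(["mean", "system_id"])
        best = grp["mean"].min()
        ties = (grp["mean"] == best).sum()
        grp = grp.assign(rank=np.arange(1, len(grp) + 1),
                         preferred=grp["mean"] == best,
                         tie=ties > 1)
        out.append(grp)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Reference contributor lists (20 ligand:VMAT2 systems)

def load_reference_contributors() -> tuple[list[ContributorList],
                                           dict[str, str]]:
    """Contributor lists for the 20 reference ligand:VMAT2 systems, plus a
    system -> state (CYT/LUM) map.

    Only the ordering of residues is known for these systems (energies were
    published as ordered lists, not values), so the returned lists carry
    NaN energies and support recurrence/ordering analyses only.
    """
    with resources.files("shiftscan") \
            .joinpath("data/vmat2_contributors.csv").open() as fh:
        df = pd.read_csv(fh)
    lists = []
    state_of = {}
    for sys_id, grp in df.groupby("system_id", sort=False):
        grp = grp.sort_values("rank")
        lists.append(ContributorList(str(sys_id),
                                     tuple(grp["residue"]),
                                     tuple([float("nan")] * len(grp)),
                                     DEFAULT_ENERGY_CUTOFF))
        state_of[str(sys_id)] = str(grp["vmat2_state"].iloc[0])
    return lists, state_of


def hotspot_report(lists: list[ContributorList],
                   state_of: dict[str, str] | None = None,
                   top_n: int = 4) -> dict:
    """JSON-ready hot-spot report: recurrence table plus the top residues."""
    freq = hotspot_frequency(lists, state_of)
    report = {
        "n_systems": len(lists),
        "total_contributor_entries": int(sum(len(l.residues) for l in lists)),
        "top_residues": freq["residue"].head(top_n).tolist(),
        "counts": {r.residue: int(r.count) for r in freq.itertuples()},
    }
    if state_of:
        states = sorted(set(state_of.values()))
        report["per_state_counts"] = {
            row["residue"]: {st: int(row[f"count_{st}"]) for st in states}
            for _, row in freq.iterrows()}
    return report
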