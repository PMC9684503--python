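"""MD table post-processing: stability windows, contributor extraction,
hot-spot recurrence, H-bond filtering, state comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from shiftscan.mdpost import (compare_states, detect_stable_window,
                              extract_all_contributors, extract_contributors,
                              filter_hbonds, hotspot_frequency,
                              hotspot_report, load_reference_contributors,
                              summarize_enthalpy)


def rmsd_trace(t, prot, lig):
    return pd.DataFrame({"time_ns": t, "rmsd_protein_A": prot,
                         "rmsd_ligand_A": lig})


class TestStableWindow:
    def test_constant_traces_return_final_window(self):
        t = np.linspace(0, 500, 501)
        win = detect_stable_window(rmsd_trace(t, np.full(501, 1.5),
                                              np.full(501, 2.0)))
        assert win == (300.0, 500.0)

    def test_late_step_jump_disqualifies(self):
        t = np.linspace(0, 500, 501)
        lig = np.where(t >= 400, 7.0, 2.0)
        win = detect_stable_window(rmsd_trace(t, np.full(501, 1.5), lig))
        assert win is None

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_terminal_window_check(self, seed):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 600, 301)
        prot = 1.5 + rng.normal(0, 0.5, t.size)
        lig = 2.0 + rng.normal(0, 0.7, t.size)
        trace = rmsd_trace(t, np.abs(prot), np.abs(lig))
        got = detect_stable_window(trace, window_ns=200.0)
        i = int(np.searchsorted(t, 400.0))
        pw = trace["rmsd_protein_A"].to_numpy()[i:]
        lw = trace["rmsd_ligand_A"].to_numpy()[i:]
        stable = (pw.max() - pw.min() <= 1.5) and \
            (lw.max() - lw.min() <= 2.0)
        assert got == ((400.0, 600.0) if stable else None)

    def test_window_longer_than_trace_rejected(self):
        t = np.linspace(0, 100, 51)
        with pytest.raises(ValueError):
            detect_stable_window(rmsd_trace(t, t * 0 + 1, t * 0 + 1),
                                 window_ns=200.0)


class TestEnthalpy:
    def test_mean_sd_arithmetic(self):
        out = summarize_enthalpy(np.array([-40.0, -50.0, -60.0]))
        assert out["mean"] == pytest.approx(-50.0)
        assert out["sd"] == pytest.approx(10.0)
        const = summarize_enthalpy(np.full(1000, -50.0))
        assert (const["mean"], const["sd"]) == (-50.0, 0.0)
        with pytest.raises(ValueError):
            summarize_enthalpy(np.array([-50.0]))


class TestContributorExtraction:
    def table(self, mapping, system_id="S"):
        return pd.DataFrame({"system_id": system_id,
                             "residue": list(mapping),
                             "energy_kcal_mol": list(mapping.values())})

    def test_threshold_and_ascending_order(self):
        t = self.table({"E313": -3.0, "Y342": -2.5, "F335": -1.2,
                        "A230": -1.05, "G100": -0.5})
        out = extract_contributors(t)
        assert out.residues == ("E313", "Y342", "F335", "A230")
        assert list(out.energies) == sorted(out.energies)

    def test_boundary_value_excluded_strictly(self):
        out = extract_contributors(self.table({"X1": -1.0, "X2": -1.0001}))
        assert out.residues == ("X2",)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_equals_bruteforce_filter_and_sort(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 30))
        residues = [f"R{i}" for i in rng.choice(500, n, replace=False)]
        energies = rng.uniform(-4, 1, n).round(3)
        t = self.table(dict(zip(residues, energies)))
        out = extract_contributors(t)
        expected = sorted(
            ((e, r) for r, e in zip(residues, energies) if e < -1.0),
            key=lambda p: (p[0], int(p[1][1:])))
        assert out.residues == tuple(r for _, r in expected)

    def test_permutation_invariance_and_monotone_cutoff(self, rng):
        mapping = {f"R{i}": float(e)
                   for i, e in enumerate(rng.uniform(-4, 0, 20))}
        base = extract_contributors(self.table(mapping))
        items = list(mapping.items())
        rng.shuffle(items)
        shuffled = extract_contributors(self.table(dict(items)))
        assert base.residues == shuffled.residues
        deeper = extract_contributors(self.table(mapping), cutoff=-2.0)
        assert set(deeper.residues) <= set(base.residues)

    def test_duplicate_residues_rejected(self):
        t = pd.DataFrame({"system_id": "S", "residue": ["A1", "A1"],
                          "energy_kcal_mol": [-2.0, -3.0]})
        with pytest.raises(ValueError):
            extract_contributors(t)


class TestHotspotFrequency:
    def test_reference_systems_recover_quoted_recurrence(self):
        lists, state_of = load_reference_contributors()
        assert len(lists) == 20
        freq = hotspot_frequency(lists, state_of).set_index("residue")
        top4 = set(freq.head(4).index)
        assert {"Y342", "F335", "V233"} <= top4
        assert freq.loc["Y342", "count"] == 10
        assert freq.loc["F335", "count"] == 10
        assert freq.loc["V233", "count"] == 9
        # I309 recurs, but only in lumen-facing systems
        assert freq.loc["I309", "count"] == 7
        assert freq.loc["I309", "count_CYT"] == 0
        assert freq.loc["I309", "count_LUM"] == 7

    def test_totals_equal_sum_of_list_lengths(self):
        lists, _ = load_reference_contributors()
        freq = hotspot_frequency(lists)
        assert freq["count"].sum() == sum(len(l.residues) for l in lists)

    def test_single_list_counts_all_one(self):
        lists, _ = load_reference_contributors()
        freq = hotspot_frequency(lists[:1])
        assert (freq["count"] == 1).all()

    def test_report_structure(self):
        lists, state_of = load_reference_contributors()
        rep = hotspot_report(lists, state_of)
        assert rep["n_systems"] == 20
        assert set(rep["top_residues"]) == {"Y342", "F335", "V233", "I309"}


class TestHBondFilter:
    def frame(self, occs):
        return pd.DataFrame({"system_id": "S", "donor": "LIG",
                             "acceptor": [f"R{i}" for i in range(len(occs))],
                             "occupancy_pct": occs})

    def test_strict_boundary(self):
        out = filter_hbonds(self.frame([49.9, 50.0, 50.1]))
        assert list(out["occupancy_pct"]) == [50.1]

    def test_all_zero_empty_and_invalid_rejected(self):
        assert filter_hbonds(self.frame([0.0, 0.0])).empty
        with pytest.raises(ValueError):
            filter_hbonds(self.frame([120.0]))

    @given(st.integers(0, 2 ** 31 - 1))
    def test_equals_bruteforce_filter(self, seed):
        rng = np.random.default_rng(seed)
        occs = rng.uniform(0, 100, int(rng.integers(1, 40))).round(1)
        out = filter_hbonds(self.frame(list(occs)), threshold=50.0)
        assert set(out["occupancy_pct"]) == {o for o in occs if o > 50.0}


class TestStateComparison:
    def summaries(self, means):
        return pd.DataFrame({"system_id": list(means),
                             "mean": list(means.values())})

    def annotation(self, means, ligand="ZPS"):
        return {s: {"ligand": ligand, "state": s.split(":")[0]}
                for s in means}

    def test_most_favorable_state_flagged(self):
        means = {"prot:LUM": -60.0, "deprot:LUM": -40.0}
        out = compare_states(self.summaries(means), self.annotation(means))
        best = out[out["preferred"]]
        assert list(best["system_id"]) == ["prot:LUM"]
        assert not best["tie"].iloc[0]

    def test_tie_reported_not_broken(self):
        means = {"a:X": -50.0, "b:X": -50.0}
        out = compare_states(self.summaries(means), self.annotation(means))
        assert out["preferred"].sum() == 2
        assert out["tie"].all()

    def test_planted_preference_structure_recovered(self, rng):
        from shiftscan.synthetic import SyntheticMDParams, generate_md_tables
        params = SyntheticMDParams(
            systems=("ZPS+:LUM", "ZPS_deprot:LUM"),
            residue_pool=("V233", "Y342"),
            enthalpy_mean={"ZPS+:LUM": -60.0, "ZPS_deprot:LUM": -40.0},
            enthalpy_sd=3.0, seed=2)
        tables, truth = generate_md_tables(params)
        summaries = pd.DataFrame(
            [{"system_id": s,
              "mean": summarize_enthalpy(
                  tables["enthalpy"].query("system_id == @s"))["mean"]}
             for s in params.systems])
        ann = {s: {"ligand": "ZPS", "state": s.split(":")[0]}
               for s in params.systems}
        out = compare_states(summaries, ann)
        assert out.loc[out["preferred"], "system_id"].iloc[0] == "ZPS+:LUM"

    def test_missing_annotation_rejected(self):
        means = {"a:X": -50.0, "b:X": -40.0}
        with pytest.raises(ValueError):
            compare_states(self.summaries(means), {})
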