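"""Fingerprints, Tanimoto distance, hierarchical clustering, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from shiftscan.chemcluster import (CompoundRecord, cut_clusters,
                                   distance_matrix, fingerprint,
                                   hierarchical_cluster, load_library,
                                   select_candidates, tanimoto_distance,
                                   to_newick)

DRUGS = {
    "tetrabenazine": "CC(C)CC1CN2CCc3cc(OC)c(OC)cc3C2CC1=O",
    "salmeterol": "OCc1cc(C(O)CNCCCCCCOCCCCc2ccccc2)ccc1O",
    "fluoxetine": "CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1",
    "propranolol": "CC(C)NCC(O)COc1cccc2ccccc12",
    "ziprasidone": "O=C1Cc2cc(CCN3CCN(c4nsc5ccccc45)CC3)c(Cl)cc2N1",
}


class TestFingerprint:
    def test_deterministic_and_canonicalization_invariant(self):
        from rdkit import Chem
        for smi in DRUGS.values():
            a = fingerprint(smi)
            assert np.array_equal(a, fingerprint(smi))
            # a randomized-atom-order SMILES of the same molecule
            mol = Chem.MolFromSmiles(smi)
            alt = Chem.MolToSmiles(mol, doRandom=True, canonical=False)
            assert np.array_equal(a, fingerprint(alt))

    def test_unparseable_smiles_raises_and_is_quarantined_on_load(self):
        with pytest.raises(ValueError):
            fingerprint("")
        with pytest.raises(ValueError):
            fingerprint("not_a_molecule((")
        df = pd.DataFrame({"compound_id": ["ok", "bad"],
                           "smiles": [DRUGS["propranolol"], "(((("],
                           "withdrawn": [False, False],
                           "known_vmat_ligand": [False, False]})
        records = load_library(df)
        assert not records[0].quarantined
        assert records[1].quarantined
        assert "unparseable" in records[1].quarantine_reason


class TestTanimoto:
    def bits(self, on, n=16):
        a = np.zeros(n, dtype=bool)
        a[list(on)] = True
        return a

    def test_forced_values(self):
        assert tanimoto_distance(self.bits({1, 2}), self.bits({1, 2})) == 0.0
        assert tanimoto_distance(self.bits({1, 2}), self.bits({3, 4})) == 1.0
        assert tanimoto_distance(self.bits({1, 2, 3}),
                                 self.bits({2, 3, 4})) == pytest.approx(0.5)
        assert tanimoto_distance(self.bits(set()), self.bits(set())) == 0.0
        with pytest.raises(ValueError):
            tanimoto_distance(self.bits({1}), self.bits({1}, n=32))

    @given(st.lists(st.integers(0, 31), max_size=12),
           st.lists(st.integers(0, 31), max_size=12),
           st.lists(st.integers(0, 31), max_size=12))
    def test_metric_properties(self, xs, ys, zs):
        a, b, c = (self.bits(set(v), 32) for v in (xs, ys, zs))
        dab = tanimoto_distance(a, b)
        assert 0.0 <= dab <= 1.0
        assert dab == tanimoto_distance(b, a)
        if np.array_equal(a, b):
            assert dab == 0.0
        # triangle inequality (Tanimoto/Jaccard distance is a metric)
        assert dab <= tanimoto_distance(a, c) + tanimoto_distance(c, b) + 1e-12

    def test_distance_matrix_matches_pairwise_calls(self, rng):
        fps = [rng.random(64) < 0.3 for _ in range(10)]
        d = distance_matrix(fps)
        for i in range(10):
            for j in range(10):
                assert d[i, j] == pytest.approx(
                    tanimoto_distance(fps[i], fps[j]), abs=1e-12)


def bruteforce_average_linkage(dist):
    """Naive UPGMA agglomeration: merge the closest pair of clusters,
    average distance over all cross pairs, ties by lowest pair index."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai, a in enumerate(keys):
            for b in keys[ai + 1:]:
                d = np.mean([dist[i, j] for i in clusters[a]
                             for j in clusters[b]])
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        new = n + len(merges)
        clusters[new] = clusters.pop(a) + clusters.pop(b)
        merges.append((d, frozenset(clusters[new])))
    return merges


def partition_at_k(merges, n, k):
    """Flat partition after n-k merges, as a set of frozensets."""
    clusters = [frozenset([i]) for i in range(n)]
    for d, merged in merges[:n - k]:
        absorbed = [c for c in clusters if c <= merged]
        clusters = [c for c in clusters if not c <= merged]
        clusters.append(frozenset().union(*absorbed))
    return set(clusters)


class TestHierarchicalClustering:
    def test_two_points_merge_at_their_distance(self):
        d = np.array([[0.0, 0.4], [0.4, 0.0]])
        tree = hierarchical_cluster(d)
        assert tree.shape == (1, 4)
        assert tree[0, 2] == pytest.approx(0.4)

    def test_duplicate_points_merge_first_at_zero_height(self):
        d = np.array([[0.0, 0.0, 0.9],
                      [0.0, 0.0, 0.8],
                      [0.9, 0.8, 0.0]])
        tree = hierarchical_cluster(d)
        assert tree[0, 2] == pytest.approx(0.0)
        assert {int(tree[0, 0]), int(tree[0, 1])} == {0, 1}

    @pytest.mark.parametrize("n,seed", [(5, 0), (6, 1), (7, 2), (8, 3)])
    def test_matches_exhaustive_agglomeration_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        d = rng.random((n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = hierarchical_cluster(d, "average")
        merges = bruteforce_average_linkage(d)
        np.testing.assert_allclose(tree[:, 2], [m[0] for m in merges],
                                   atol=1e-12)
        for k in range(1, n + 1):
            got = cut_clusters(tree, k)
            got_partition = {}
            for cid, lab in got.items():
                got_partition.setdefault(lab, set()).add(int(cid))
            got_sets = {frozenset(v) for v in got_partition.values()}
            assert got_sets == partition_at_k(merges, n, k)

    def test_cut_extremes_and_permutation_stability(self, rng):
        n = 12
        d = rng.random((n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = hierarchical_cluster(d)
        singles = cut_clusters(tree, n)
        assert len(set(singles.values())) == n
        one = cut_clusters(tree, 1)
        assert set(one.values()) == {1}
        # permuting inputs permutes the partition identically
        perm = rng.permutation(n)
        dp = d[np.ix_(perm, perm)]
        tp = hierarchical_cluster(dp)
        for k in (3, 5):
            base = cut_clusters(tree, k)
            permuted = cut_clusters(tp, k)
            base_sets = {}
            for i, lab in base.items():
                base_sets.setdefault(lab, set()).add(int(i))
            perm_sets = {}
            for i, lab in permuted.items():
                perm_sets.setdefault(lab, set()).add(int(perm[int(i)]))
            assert {frozenset(s) for s in base_sets.values()} == \
                {frozenset(s) for s in perm_sets.values()}

    def test_rejects_nonfinite_or_asymmetric(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(np.array([[0.0, np.inf], [np.inf, 0.0]]))
        with pytest.raises(ValueError):
            hierarchical_cluster(np.array([[0.0, 0.2], [0.4, 0.0]]))
        with pytest.raises(ValueError):
            cut_clusters(hierarchical_cluster(np.zeros((2, 2))), 0)


class TestSelection:
    def records(self, flags):
        return [CompoundRecord(cid, "C", np.ones(8, dtype=bool),
                               withdrawn=w, known_vmat_ligand=k)
                for cid, (w, k) in flags.items()]

    def test_distinct_clusters_all_kept(self):
        hits = {"a": 3.0, "b": -4.0}
        selected, controls, _ = select_candidates(
            hits, {"a": 1, "b": 2}, self.records({"a": (False, False),
                                                  "b": (False, False)}))
        assert sorted(selected) == ["a", "b"]
        assert controls == []

    def test_largest_shift_wins_within_cluster(self):
        # salmeterol-vs-formoterol-scale shifts sharing one cluster
        hits = {"SMT": 9.71, "formoterol": 1.87}
        selected, _, audit = select_candidates(
            hits, {"SMT": 1, "formoterol": 1},
            self.records({"SMT": (False, False),
                          "formoterol": (False, False)}))
        assert selected == ["SMT"]
        assert any(e["event"] == "redundant_with" for e in audit)

    def test_withdrawn_and_known_ligand_routing(self):
        hits = {"w": 9.0, "k": 8.0, "ok": 2.1}
        selected, controls, audit = select_candidates(
            hits, {"w": 1, "k": 2, "ok": 3},
            self.records({"w": (True, False), "k": (False, True),
                          "ok": (False, False)}))
        assert selected == ["ok"]
        assert controls == ["k"]
        assert {e["event"] for e in audit} >= {"withdrawn_filtered",
                                               "known_ligand_control"}

    def test_hit_missing_from_assignment_is_an_error(self):
        with pytest.raises(KeyError):
            select_candidates({"a": 1.0}, {},
                              self.records({"a": (False, False)}))


class TestNewickExport:
    def test_tree_parses_and_preserves_leaves(self, rng):
        from io import StringIO
        from Bio import Phylo
        n = 9
        d = rng.random((n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = hierarchical_cluster(d)
        labels = [f"CPD{i}" for i in range(n)]
        nwk = to_newick(tree, labels)
        parsed = Phylo.read(StringIO(nwk), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == \
            sorted(labels)
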