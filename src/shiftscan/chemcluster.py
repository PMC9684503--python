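"""Fingerprint clustering and non-redundant candidate selection.

Compounds are encoded as path-based binary fingerprints (1024 bits,
FP2-like), compared by Tanimoto distance, clustered agglomeratively
(average linkage by default) and cut into K flat clusters.  Among validated
hits, withdrawn drugs are filtered out, known ligands of the target are
routed to a controls list, and each cluster contributes at most one
representative (the largest |delta-Tm|, ties by compound id).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    smiles: str
    fingerprint: np.ndarray | None  # bool array; None when quarantined
    withdrawn: bool = False
    known_vmat_ligand: bool = False
    therapeutic_class: str = ""
    quarantine_reason: str | None = None

    @property
    def quarantined(self) -> bool:
        return self.fingerprint is None


def fingerprint(smiles: str, n_bits: int = 1024) -> np.ndarray:
    """Path-based binary fingerprint of a molecule (deterministic).

    Raises ValueError on unparseable SMILES; callers that ingest libraries
    should quarantine such records rather than abort (see ``load_library``).
    """
    from rdkit import Chem
    from rdkit import RDLogger
    RDLogger.DisableLog("rdApp.*")
    mol = Chem.MolFromSmiles(smiles) if smiles else None
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    fp = Chem.RDKFingerprint(mol, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=bool)
    arr[list(fp.GetOnBits())] = True
    return arr


def load_library(df: pd.DataFrame, n_bits: int = 1024) -> list[CompoundRecord]:
    """Build CompoundRecords from a compound table (compound_id, smiles,
    withdrawn, known_vmat_ligand, class); unparseable SMILES quarantined."""
    records = []
    for row in df.to_dict("records"):
        try:
            fp = fingerprint(str(row["smiles"]), n_bits)
            reason = None
        except ValueError as exc:
            fp, reason = None, str(exc)
        records.append(CompoundRecord(
            compound_id=str(row["compound_id"]), smiles=str(row["smiles"]),
            fingerprint=fp,
            withdrawn=bool(row.get("withdrawn", False)),
            known_vmat_ligand=bool(row.get("known_vmat_ligand", False)),
            therapeutic_class=str(row.get("class", "")),
            quarantine_reason=reason))
    return records


def tanimoto_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - |a AND b| / |a OR b| on equal-length bit sets; 0 when both empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("fingerprint length mismatch")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    inter = np.logical_and(a, b).sum()
    return 1.0 - inter / union


def distance_matrix(fps: list[np.ndarray]) -> np.ndarray:
    """Pairwise Tanimoto distance matrix (vectorized)."""
    x = np.asarray(fps, dtype=bool)
    inter = (x[:, None, :] & x[None, :, :]).sum(axis=2) \
        if x.shape[0] <= 64 else x.astype(np.int32) @ x.astype(np.int32).T
    counts = x.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def hierarchical_cluster(dist: np.ndarray, method: str = "average"
                         ) -> np.ndarray:
    """Agglomerative linkage tree (scipy format) from a symmetric,
    zero-diagonal distance matrix."""
    dist = np.asarray(dist, dtype=float)
    if not np.all(np.isfinite(dist)):
        raise ValueError("non-finite distances")
    if dist.shape[0] != dist.shape[1] or not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(dist), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    condensed = squareform(dist, checks=False)
    return hierarchy.linkage(condensed, method=method)


def cut_clusters(tree: np.ndarray, k: int,
                 compound_ids: list[str] | None = None) -> dict:
    """Cut the linkage tree into exactly K flat clusters (labels 1..K).

    Cutting at the (n-K)-th merge; cluster labels are arbitrary but stable
    for a given input.
    """
    n = tree.shape[0] + 1
    if k < 1:
        raise ValueError("K must be >= 1")
    if k > n:
        raise ValueError("K exceeds the number of compounds")
    labels = hierarchy.cut_tree(tree, n_clusters=k).ravel() + 1
    ids = compound_ids if compound_ids is not None \
        else [str(i) for i in range(n)]
    return {cid: int(lab) for cid, lab in zip(ids, labels)}


def select_candidates(hit_delta_tms: dict[str, float],
                      assignment: dict[str, int],
                      records: list[CompoundRecord],
                      ) -> tuple[list[str], list[str], list[dict]]:
    """Non-redundant follow-up selection among validated hits.

    Drops withdrawn-flagged hits; routes known target ligands to a controls
    list; keeps one representative per cluster (largest |delta-Tm|, ties by
    compound id).  Returns (selected, controls, audit log).
    """
    meta = {r.compound_id: r for r in records}
    audit: list[dict] = []
    controls: list[str] = []
    by_cluster: dict[int, list[str]] = {}
    for cid in sorted(hit_delta_tms):
        if cid not in assignment:
            raise KeyError(f"hit {cid} missing from cluster assignment")
        rec = meta.get(cid)
        if rec is not None and rec.withdrawn:
            audit.append({"compound": cid, "event": "withdrawn_filtered"})
            continue
        if rec is not None and rec.known_vmat_ligand:
            controls.append(cid)
            audit.append({"compound": cid, "event": "known_ligand_control"})
            continue
        by_cluster.setdefault(assignment[cid], []).append(cid)
    selected: list[str] = []
    for cluster in sorted(by_cluster):
        members = by_cluster[cluster]
        best = min(members,
                   key=lambda c: (-abs(hit_delta_tms[c]), c))
        selected.append(best)
        for other in members:
            if other != best:
                audit.append({"compound": other, "cluster": cluster,
                              "event": "redundant_with", "kept": best})
    return selected, controls, audit


def to_newick(tree: np.ndarray, labels: list[str]) -> str:
    """Newick serialization of a scipy linkage tree (branch lengths from
    merge heights)."""
    root = hierarchy.to_tree(tree)

    def walk(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(root, root.dist) + ";"
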