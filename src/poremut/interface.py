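"""Dimer-interface residue mapping.

Two operationalizations of "forms the interface": buried surface area on
complexation (delta-SASA > threshold, default 1 Å²) and cross-chain heavy-atom
proximity (any atom within threshold, default 4.5 Å). Membership is computed
on the full structure and excluded ranges are filtered only from the reported
sets, so counts are reproducible under different exclusion configs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from poremut.structure import AnalysisConfig, ResidueKey, Structure
from poremut.surface import delta_sasa_on_complexation

DEFAULT_DELTA_SASA_THRESHOLD = 1.0  # Å²
DEFAULT_DISTANCE_THRESHOLD = 4.5  # Å


@dataclass
class InterfaceSet:
    residues: dict[str, set[ResidueKey]]  # per chain
    method: str  # "delta_sasa" or "distance"
    threshold: float

    def __contains__(self, key: ResidueKey) -> bool:
        return any(key in s for s in self.residues.values())

    def all_keys(self) -> set[ResidueKey]:
        out: set[ResidueKey] = set()
        for s in self.residues.values():
            out |= s
        return out


def _two_chains(dimer: Structure) -> tuple[str, str]:
    ids = dimer.chain_ids
    if len(ids) < 2:
        raise ValueError("interface detection requires 2 chains")
    if len(ids) > 2:
        warnings.warn(f"structure has {len(ids)} chains; using {ids[0]} and {ids[1]}")
    return ids[0], ids[1]


def _chain_heavy(dimer: Structure, chain_id: str):
    atoms = [a for res in dimer.chain(chain_id) for a in res.atoms if a.is_heavy]
    return atoms, np.array([a.coord for a in atoms])


def find_interface_residues(dimer: Structure, config: AnalysisConfig | None = None,
                            method: str = "delta_sasa",
                            threshold: float | None = None) -> InterfaceSet:
    """Residues of each chain in contact with the other chain."""
    config = config or AnalysisConfig()
    ca, cb = _two_chains(dimer)
    residues: dict[str, set[ResidueKey]] = {ca: set(), cb: set()}
    if method == "delta_sasa":
        thr = DEFAULT_DELTA_SASA_THRESHOLD if threshold is None else threshold
        for cid in (ca, cb):
            deltas = delta_sasa_on_complexation(dimer, cid, config)
            residues[cid] = {k for k, v in deltas.items() if v > thr}
    elif method == "distance":
        thr = DEFAULT_DISTANCE_THRESHOLD if threshold is None else threshold
        atoms_a, xyz_a = _chain_heavy(dimer, ca)
        atoms_b, xyz_b = _chain_heavy(dimer, cb)
        tree_b = cKDTree(xyz_b)
        hits = tree_b.query_ball_point(xyz_a, thr)
        for atom, hit in zip(atoms_a, hits):
            if hit:
                residues[ca].add(atom.residue_key)
                for j in hit:
                    residues[cb].add(atoms_b[j].residue_key)
    else:
        raise ValueError(f"unknown interface method {method!r}")
    for cid in (ca, cb):
        residues[cid] = {k for k in residues[cid] if not config.is_excluded(k)}
    return InterfaceSet(residues, method, thr)


def min_cross_chain_distance(key: ResidueKey, dimer: Structure,
                             target_keys: set[ResidueKey]) -> float:
    """Min heavy-atom distance from ``key`` to any residue in ``target_keys``."""
    res = dimer.get_residue(*key)
    src = res.heavy_coords()
    best = np.inf
    for tkey in target_keys:
        tgt = dimer.get_residue(*tkey).heavy_coords()
        d = np.sqrt(((src[:, None, :] - tgt[None, :, :]) ** 2).sum(-1)).min()
        best = min(best, float(d))
    return best


def near_interface(key: ResidueKey, dimer: Structure, cutoff: float = 6.0,
                   interface: InterfaceSet | None = None,
                   config: AnalysisConfig | None = None) -> bool:
    """True if the residue is in, or within ``cutoff`` Å of, the interface.

    An interface residue is trivially near (zero distance). Otherwise the
    minimum heavy-atom distance to the other chain's interface residues is
    compared against ``cutoff``.
    """
    if not dimer.has_residue(*key):
        raise KeyError(f"no residue {key} in structure")
    if interface is None:
        interface = find_interface_residues(dimer, config)
    if key in interface:
        return True
    ca, cb = _two_chains(dimer)
    other = cb if key[0] == ca else ca
    targets = interface.residues.get(other, set())
    if not targets:
        return False
    return min_cross_chain_distance(key, dimer, targets) <= cutoff


def interface_table(dimer: Structure, config: AnalysisConfig | None = None):
    """Per-residue interface report: delta-SASA, min cross-chain distance, membership."""
    import pandas as pd

    config = config or AnalysisConfig()
    ca, cb = _two_chains(dimer)
    iset = find_interface_residues(dimer, config)
    rows = []
    for cid, other in ((ca, cb), (cb, ca)):
        deltas = delta_sasa_on_complexation(dimer, cid, config)
        _, xyz_other = _chain_heavy(dimer, other)
        tree = cKDTree(xyz_other)
        for res in dimer.chain(cid):
            if config.is_excluded(res.key):
                continue
            d, _ = tree.query(res.heavy_coords())
            rows.append(
                {
                    "chain": cid,
                    "res_seq": res.res_seq,
                    "res_name": res.res_name,
                    "delta_sasa_A2": deltas.get(res.key, 0.0),
                    "min_cross_chain_dist_A": float(np.min(d)),
                    "in_interface": res.key in iset,
                }
            )
    return pd.DataFrame(rows)
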