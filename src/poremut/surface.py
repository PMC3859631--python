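"""Solvent-accessible surface area, relative accessibility and buriedness.

SASA uses the classic test-point construction: a deterministic golden-spiral
lattice is placed on each atom's solvent-expanded sphere (radius + probe)
and a point counts as accessible when it lies outside every other atom's
expanded sphere. Relative accessibility (RSA) is SASA over a Gly-X-Gly
maximum-exposure reference; residues with RSA < 15% are flagged buried.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from poremut._tables import max_asa
from poremut.structure import AnalysisConfig, ResidueKey, Structure

BURIED_RSA_PERCENT = 15.0  # strict: buried iff RSA < 15%

AtomKey = tuple[str, int, str, str]  # residue key + atom name


@dataclass
class SasaResult:
    per_atom: dict[AtomKey, float]
    per_residue: dict[ResidueKey, float]
    probe_radius: float
    sphere_points: int


@dataclass
class RsaRecord:
    key: ResidueKey
    res_name: str
    sasa: float
    max_asa_ref: float | None
    rsa: float | None  # percent; None for non-standard residues
    buried: bool | None


@lru_cache(maxsize=8)
def _golden_spiral(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points (deterministic)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = np.pi * (3.0 - np.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley(structure: Structure, config: AnalysisConfig | None = None) -> SasaResult:
    """Per-atom and per-residue SASA over heavy atoms."""
    config = config or AnalysisConfig()
    if config.sphere_points < 100:
        raise ValueError("sphere_points must be >= 100")
    atoms = structure.heavy_atoms()
    if not atoms:
        raise ValueError("empty structure")
    centers = np.array([a.coord for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms]) + config.probe_radius
    unit = _golden_spiral(config.sphere_points)
    tree = cKDTree(centers)
    rmax = radii.max()
    per_atom: dict[AtomKey, float] = {}
    per_residue: dict[ResidueKey, float] = {}
    for i, atom in enumerate(atoms):
        pts = centers[i] + radii[i] * unit
        neigh = tree.query_ball_point(centers[i], radii[i] + rmax)
        accessible = np.ones(len(pts), dtype=bool)
        for j in neigh:
            if j == i:
                continue
            d = np.linalg.norm(centers[j] - centers[i])
            if d >= radii[i] + radii[j]:
                continue
            accessible &= np.sum((pts - centers[j]) ** 2, axis=1) > radii[j] ** 2
            if not accessible.any():
                break
        area = accessible.mean() * 4.0 * np.pi * radii[i] ** 2
        per_atom[(*atom.residue_key, atom.name)] = float(area)
        per_residue[atom.residue_key] = per_residue.get(atom.residue_key, 0.0) + float(area)
    return SasaResult(per_atom, per_residue, config.probe_radius, config.sphere_points)


def relative_sasa(sasa: SasaResult, structure: Structure,
                  reference: str = "tien_theoretical") -> list[RsaRecord]:
    """RSA per residue against the configured max-ASA table.

    Non-standard residues get ``rsa=None`` / ``buried=None`` rather than an
    error; the buried flag is the strict RSA < 15% rule.
    """
    ref = max_asa(reference)
    records = []
    for res in structure.residues():
        area = sasa.per_residue.get(res.key, 0.0)
        if res.res_name not in ref:
            records.append(RsaRecord(res.key, res.res_name, area, None, None, None))
            continue
        m = ref[res.res_name]
        rsa = float(100.0 * area / m)
        records.append(
            RsaRecord(res.key, res.res_name, float(area), m, rsa,
                      bool(rsa < BURIED_RSA_PERCENT))
        )
    return records


def delta_sasa_on_complexation(dimer: Structure, chain_id: str,
                               config: AnalysisConfig | None = None) -> dict[ResidueKey, float]:
    """Per-residue SASA lost by ``chain_id`` when the other chains are present.

    Because the test-point lattice is anchored on each atom, adding atoms can
    only remove accessible points, so every value is >= 0 exactly.
    """
    config = config or AnalysisConfig()
    if len(dimer.chain_ids) < 2:
        raise ValueError("delta SASA on complexation needs at least 2 chains")
    if chain_id not in dimer.chain_ids:
        raise KeyError(f"no chain {chain_id!r} in structure")
    isolated = shrake_rupley(dimer.chain_view(chain_id), config)
    complexed = shrake_rupley(dimer, config)
    return {
        key: isolated.per_residue[key] - complexed.per_residue[key]
        for key in isolated.per_residue
    }


def rsa_table(records: list[RsaRecord]):
    """RSA records as a tidy DataFrame (chain, res_seq, res_name, sasa, rsa, buried)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "chain": [r.key[0] for r in records],
            "res_seq": [r.key[1] for r in records],
            "res_name": [r.res_name for r in records],
            "sasa_A2": [r.sasa for r in records],
            "rsa_pct": [r.rsa for r in records],
            "buried": [r.buried for r in records],
        }
    )
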