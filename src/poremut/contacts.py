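"""Geometric side-chain contact detection: hydrogen bonds and aromatic pairs.

Hydrogen bonds use a heavy-atom criterion (models typically lack hydrogens):
a side-chain N/O of the focus residue within 3.5 Å of any N/O of another
residue, with the angle at the focus atom (antecedent-atom-partner) >= 90°
when the antecedent is defined. Aromatic contacts pair ring centroids within
7 Å whose plane normals are stacked or tilted-T (<= 60° or >= 120°).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from poremut.structure import ResidueKey, Residue, Structure

HBOND_DISTANCE_CUTOFF = 3.5  # Å, heavy donor-acceptor
HBOND_MIN_ANGLE = 90.0  # degrees at the focus atom
AROMATIC_CENTROID_CUTOFF = 7.0  # Å
AROMATIC_ANGLE_LOW = 60.0
AROMATIC_ANGLE_HIGH = 120.0

# Side-chain heavy atoms per residue type (beyond CA); used both for polar-atom
# lookup and for the mutant atom-template rule in contacts_lost.
SIDECHAIN_ATOMS: dict[str, set[str]] = {
    "GLY": set(),
    "ALA": {"CB"},
    "SER": {"CB", "OG"},
    "CYS": {"CB", "SG"},
    "THR": {"CB", "OG1", "CG2"},
    "VAL": {"CB", "CG1", "CG2"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "ILE": {"CB", "CG1", "CG2", "CD1"},
    "MET": {"CB", "CG", "SD", "CE"},
    "PRO": {"CB", "CG", "CD"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"},
    "TRP": {"CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "ASP": {"CB", "CG", "OD1", "OD2"},
    "GLU": {"CB", "CG", "CD", "OE1", "OE2"},
    "ASN": {"CB", "CG", "OD1", "ND2"},
    "GLN": {"CB", "CG", "CD", "OE1", "NE2"},
    "HIS": {"CB", "CG", "ND1", "CD2", "CE1", "NE2"},
    "LYS": {"CB", "CG", "CD", "CE", "NZ"},
    "ARG": {"CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"},
}

# Antecedent (covalently bonded) heavy atom for each polar side-chain atom,
# used for the angular criterion.
_ANTECEDENT: dict[str, str] = {
    "OG": "CB", "OG1": "CB", "SG": "CB",
    "OD1": "CG", "OD2": "CG", "ND2": "CG", "ND1": "CG",
    "OE1": "CD", "OE2": "CD", "NE2": "CD",
    "OH": "CZ", "NZ": "CE", "NE": "CD", "NH1": "CZ", "NH2": "CZ",
    "NE1": "CD1",
    "N": "CA", "O": "C",
}

AROMATIC_RESIDUES = {"PHE", "TYR", "TRP", "HIS"}  # His counted as aromatic

_RING_ATOMS: dict[str, list[str]] = {
    "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TRP": ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"],  # six-membered ring
    "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
}

# Chemically similar substitutions where an equivalent contact may survive
# (e.g. Glu -> Asp keeps a carboxylate one bond shorter).
_SIMILAR_PAIRS = {
    ("GLU", "ASP"), ("ASP", "GLU"),
    ("GLN", "ASN"), ("ASN", "GLN"),
    ("GLU", "GLN"), ("ASP", "ASN"),
    ("TYR", "PHE"), ("PHE", "TYR"),
}


@dataclass
class Contact:
    kind: str  # "hbond" or "aromatic"
    focus_key: ResidueKey
    focus_resname: str
    focus_atom: str  # atom name for hbond; "ring" for aromatic
    partner_key: ResidueKey
    partner_resname: str
    partner_atom: str
    distance: float
    detail: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("contact distance must be positive")


def _detail(focus: Residue, focus_atom: str, partner: Residue, partner_atom: str) -> str:
    res3 = focus.res_name.capitalize()
    p3 = partner.res_name.capitalize()
    return f"{res3}({focus_atom})-{p3}{partner.res_seq}({partner_atom})"


def _polar_sidechain_atoms(res: Residue) -> list:
    names = SIDECHAIN_ATOMS.get(res.res_name, set())
    return [a for a in res.atoms if a.name in names and a.element.upper() in ("N", "O")]


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(structure: Structure, focus_key: ResidueKey) -> list[Contact]:
    """Side-chain hydrogen bonds of the focus residue with any other residue."""
    focus = structure.get_residue(*focus_key)
    polar = _polar_sidechain_atoms(focus)
    if focus.res_name == "GLY" or not polar:
        if focus.res_name == "GLY":
            warnings.warn(f"focus residue {focus.res_name}{focus.res_seq} has no side chain")
        return []
    contacts: list[Contact] = []
    for other in structure.residues():
        if other.key == focus.key:
            continue
        for fa in polar:
            ante_name = _ANTECEDENT.get(fa.name)
            ante = focus.atom(ante_name) if ante_name else None
            for pa in other.atoms:
                if pa.element.upper() not in ("N", "O") or not pa.is_heavy:
                    continue
                d = float(np.linalg.norm(fa.coord - pa.coord))
                if d > HBOND_DISTANCE_CUTOFF:
                    continue
                if ante is not None and _angle(ante.coord, fa.coord, pa.coord) < HBOND_MIN_ANGLE:
                    continue
                contacts.append(
                    Contact("hbond", focus.key, focus.res_name, fa.name,
                            other.key, other.res_name, pa.name, d,
                            _detail(focus, fa.name, other, pa.name))
                )
    contacts.sort(key=lambda c: (c.partner_key, c.focus_atom, c.partner_atom))
    return contacts


def _ring(res: Residue) -> tuple[np.ndarray, np.ndarray] | None:
    """(centroid, unit normal) of the aromatic ring, or None if incomplete."""
    names = _RING_ATOMS[res.res_name]
    coords = []
    for n in names:
        a = res.atom(n)
        if a is None:
            return None
        coords.append(a.coord)
    xyz = np.array(coords)
    centroid = xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(xyz - centroid)
    return centroid, vt[2]


def detect_aromatic(structure: Structure, focus_key: ResidueKey) -> list[Contact]:
    """Aromatic ring-ring contacts (stacked or tilted-T) of the focus residue."""
    focus = structure.get_residue(*focus_key)
    if focus.res_name not in AROMATIC_RESIDUES:
        raise ValueError(f"focus residue {focus.res_name}{focus.res_seq} is not aromatic")
    fring = _ring(focus)
    if fring is None:
        raise ValueError(f"focus residue {focus.res_name}{focus.res_seq} has an incomplete ring")
    fc, fn = fring
    contacts: list[Contact] = []
    for other in structure.residues():
        if other.key == focus.key or other.res_name not in AROMATIC_RESIDUES:
            continue
        oring = _ring(other)
        if oring is None:
            warnings.warn(f"skipping incomplete ring in {other.res_name}{other.res_seq}")
            continue
        oc, on = oring
        d = float(np.linalg.norm(fc - oc))
        if d > AROMATIC_CENTROID_CUTOFF:
            continue
        ang = float(np.degrees(np.arccos(np.clip(abs(np.dot(fn, on)), 0.0, 1.0))))
        # normals are sign-ambiguous; fold to [0, 90] and accept stacked/tilted
        if ang <= AROMATIC_ANGLE_LOW or ang >= AROMATIC_ANGLE_HIGH:
            contacts.append(
                Contact("aromatic", focus.key, focus.res_name, "ring",
                        other.key, other.res_name, "ring", d,
                        f"{focus.res_name.capitalize()}{focus.res_seq}-"
                        f"{other.res_name.capitalize()}{other.res_seq}")
            )
    contacts.sort(key=lambda c: c.partner_key)
    return contacts


def contacts_lost(wild_contacts: list[Contact], mutant_aa: str) -> list[Contact]:
    """Wild-type contacts that the mutant side chain cannot maintain.

    Atom-template rule: an H-bond is lost when the mutant residue type lacks
    a side-chain atom with the focus atom's name; an aromatic contact is lost
    when the mutant is not aromatic. Chemically similar substitutions
    (Glu/Asp, Gln/Asn, Tyr/Phe and amide/acid swaps) are annotated
    "possibly preserved" on the returned contacts.
    """
    mutant_aa = mutant_aa.upper()
    if mutant_aa not in SIDECHAIN_ATOMS:
        raise KeyError(f"unknown residue code {mutant_aa!r}")
    lost: list[Contact] = []
    for c in wild_contacts:
        if c.kind == "aromatic":
            is_lost = mutant_aa not in AROMATIC_RESIDUES
        else:
            is_lost = c.focus_atom not in SIDECHAIN_ATOMS[mutant_aa]
        if is_lost:
            note = c.note
            if (c.focus_resname.upper(), mutant_aa) in _SIMILAR_PAIRS:
                note = "possibly preserved (chemically similar substitution)"
            lost.append(Contact(c.kind, c.focus_key, c.focus_resname, c.focus_atom,
                                c.partner_key, c.partner_resname, c.partner_atom,
                                c.distance, c.detail, note))
    return lost
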