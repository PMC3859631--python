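"""Hierarchical structure model, PDB I/O and rigid-body superposition.

Coordinates live on :class:`Atom`; :class:`Residue` and :class:`Structure`
are thin ordered containers keyed by ``(chain_id, res_seq, insertion_code)``.
All geometry downstream is defined on heavy atoms; hydrogens are kept if
present but most channel models lack them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from poremut._tables import STANDARD_AA, vdw_radii

ResidueKey = tuple[str, int, str]  # (chain_id, res_seq, insertion_code)


class PDBParseError(ValueError):
    """Malformed fixed-width PDB record; message names the line number."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coord: np.ndarray
    vdw_radius: float
    chain_id: str
    res_seq: int
    res_name: str
    insertion_code: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.serial} has invalid coordinates {self.coord}")
        if not self.vdw_radius > 0:
            raise ValueError(f"atom {self.serial} has non-positive vdW radius")

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.res_seq, self.insertion_code)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Residue:
    res_seq: int
    res_name: str
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.res_name}{self.res_seq} has no atoms")
        for a in self.atoms:
            if a.chain_id != self.chain_id or a.res_seq != self.res_seq:
                raise ValueError(
                    f"atom {a.serial} does not belong to residue "
                    f"{self.chain_id}/{self.res_seq}"
                )

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.res_seq, self.insertion_code)

    @property
    def is_standard(self) -> bool:
        return self.res_name in STANDARD_AA

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms if a.is_heavy])


class Structure:
    """Ordered chains of residues; residue keys are unique."""

    def __init__(self, title: str = "") -> None:
        self.title = title
        self._chains: dict[str, list[Residue]] = {}
        self._index: dict[ResidueKey, Residue] = {}

    # -- construction -------------------------------------------------
    def add_residue(self, residue: Residue) -> None:
        if residue.key in self._index:
            raise ValueError(f"duplicate residue key {residue.key}")
        self._chains.setdefault(residue.chain_id, []).append(residue)
        self._index[residue.key] = residue

    # -- access -------------------------------------------------------
    @property
    def chain_ids(self) -> list[str]:
        return list(self._chains)

    def chain(self, chain_id: str) -> list[Residue]:
        if chain_id not in self._chains:
            raise KeyError(f"no chain {chain_id!r} in structure")
        return self._chains[chain_id]

    def chain_view(self, chain_id: str) -> "Structure":
        """Single-chain sub-structure sharing the residue objects."""
        sub = Structure(title=f"{self.title}:{chain_id}")
        for res in self.chain(chain_id):
            sub.add_residue(res)
        return sub

    def residues(self) -> Iterator[Residue]:
        for chain in self._chains.values():
            yield from chain

    def get_residue(self, chain_id: str, res_seq: int, icode: str = "") -> Residue:
        key = (chain_id, res_seq, icode)
        if key not in self._index:
            raise KeyError(f"no residue {key} in structure")
        return self._index[key]

    def has_residue(self, chain_id: str, res_seq: int, icode: str = "") -> bool:
        return (chain_id, res_seq, icode) in self._index

    def atoms(self) -> Iterator[Atom]:
        for res in self.residues():
            yield from res.atoms

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms() if a.is_heavy]

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms()])

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    chain_id: str | None = None, title: str | None = None) -> "Structure":
        """Rigid-transformed deep copy; optionally relabel the (single) chain."""
        out = Structure(title=self.title if title is None else title)
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        for res in self.residues():
            cid = chain_id if chain_id is not None else res.chain_id
            atoms = [
                Atom(a.serial, a.name, a.element, R @ a.coord + t, a.vdw_radius,
                     cid, a.res_seq, a.res_name, a.insertion_code, a.occupancy)
                for a in res.atoms
            ]
            out.add_residue(Residue(res.res_seq, res.res_name, cid, atoms, res.insertion_code))
        return out


@dataclass
class AnalysisConfig:
    """Shared knobs for the geometric stages.

    probe_radius : solvent probe for SASA (Å); 1.4 approximates water.
    excluded_ranges : (chain_id, start_res, end_res) stretches left out of
        reported results, e.g. regions disordered in the template.
    sphere_points : test points per atom in the SASA lattice.
    grid_spacing : pore-search grid pitch (Å).
    probe_min : minimum clearance for a pore grid node to be traversable (Å).
    """

    probe_radius: float = 1.4
    excluded_ranges: list[tuple[str, int, int]] = field(default_factory=list)
    sphere_points: int = 960
    grid_spacing: float = 0.8
    probe_min: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.probe_radius > 0:
            raise ValueError("probe_radius must be > 0")
        if not (0.1 < self.grid_spacing <= 2.0):
            raise ValueError("grid_spacing must be in (0.1, 2.0]")
        for chain, start, end in self.excluded_ranges:
            if start > end:
                raise ValueError(f"excluded range {chain}:{start}-{end} has start > end")

    def is_excluded(self, key: ResidueKey) -> bool:
        chain_id, res_seq, _ = key
        return any(c == chain_id and s <= res_seq <= e for c, s, e in self.excluded_ranges)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def _infer_element(atom_name: str, res_name: str) -> str:
    """Element from an ATOM-record atom name when columns 77-78 are blank."""
    stripped = atom_name.strip()
    bare = stripped.lstrip("0123456789")
    if not bare:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    table = vdw_radii()
    two = bare[:2].upper()
    # Two-letter elements only when the name is left-justified into column 13
    # (PDB convention); otherwise a leading C/N/O/S/H/P is the element.
    if two in table and len(stripped) == 4 and two not in {"CA", "CD", "CE", "CG", "CZ", "CB", "NE", "ND", "NZ", "NH", "OD", "OE", "OG", "OH", "SD", "SG"}:
        return two
    return bare[0].upper()


def read_pdb(path, model_index: int = 0, *, include_het: bool = False,
             radius_table: dict[str, float] | None = None) -> Structure:
    """Parse fixed-width ATOM records into a :class:`Structure`.

    One residue per (chain, res_seq, insertion code). Elements come from
    columns 77-78 when present, else are inferred from the atom name; vdW
    radii are assigned from ``radius_table`` (packaged element set by
    default). HETATM records and waters are skipped unless ``include_het``.
    Alternate locations keep the highest-occupancy conformer (first on tie).
    """
    radii = radius_table if radius_table is not None else vdw_radii()
    model = 0
    # (residue_key, atom_name) -> chosen Atom, for altloc resolution
    chosen: dict[tuple[ResidueKey, str], Atom] = {}
    order: list[tuple[ResidueKey, str]] = []
    res_names: dict[ResidueKey, str] = {}
    title = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "TITLE ":
                title = (title + " " + line[10:].strip()).strip()
            elif rec == "MODEL ":
                try:
                    model = int(line[10:14]) - 1
                except ValueError:
                    model = 0
            elif rec == "ENDMDL":
                model += 1
            elif rec in ("ATOM  ", "HETATM"):
                if model != model_index:
                    continue
                res_name = line[17:20].strip()
                if rec == "HETATM" and (not include_het or res_name in _WATER_NAMES):
                    continue
                if res_name in _WATER_NAMES:
                    continue
                try:
                    serial = int(line[6:11])
                    atom_name = line[12:16].strip()
                    altloc = line[16].strip()
                    chain_id = line[21].strip() or " "
                    res_seq = int(line[22:26])
                    icode = line[26].strip()
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                    occ_field = line[54:60].strip()
                    occupancy = float(occ_field) if occ_field else 1.0
                    element = line[76:78].strip().upper() if len(line) >= 78 else ""
                except (ValueError, IndexError) as exc:
                    raise PDBParseError(f"line {lineno}: malformed ATOM record ({exc})") from None
                if not element:
                    element = _infer_element(line[12:16], res_name)
                if element not in radii:
                    raise PDBParseError(
                        f"line {lineno}: unknown element {element!r} for atom "
                        f"{serial} {atom_name} in {res_name} {chain_id}{res_seq}"
                    )
                key = (chain_id, res_seq, icode)
                atom = Atom(serial, atom_name, element, np.array([x, y, z]),
                            radii[element], chain_id, res_seq, res_name, icode, occupancy)
                slot = (key, atom_name)
                prev = chosen.get(slot)
                if prev is None:
                    chosen[slot] = atom
                    order.append(slot)
                    res_names[key] = res_name
                elif altloc and atom.occupancy > prev.occupancy:
                    chosen[slot] = atom
    if not chosen:
        raise ValueError(f"{path}: no ATOM records")
    structure = Structure(title=title)
    by_res: dict[ResidueKey, list[Atom]] = {}
    res_order: list[ResidueKey] = []
    for slot in order:
        key = slot[0]
        if key not in by_res:
            by_res[key] = []
            res_order.append(key)
        by_res[key].append(chosen[slot])
    for key in res_order:
        chain_id, res_seq, icode = key
        structure.add_residue(
            Residue(res_seq, res_names[key], chain_id, by_res[key], icode)
        )
    return structure


def write_pdb(structure: Structure, path) -> None:
    """Write fixed-width ATOM records, a TER after each chain, then END.

    Round-trip with :func:`read_pdb` preserves identifiers exactly and
    coordinates to 3 decimals.
    """
    if structure.n_atoms() == 0:
        raise ValueError("cannot write empty structure")
    lines: list[str] = []
    if structure.title:
        lines.append(f"TITLE     {structure.title}"[:80])
    serial = 0
    for chain_id in structure.chain_ids:
        last = None
        for res in structure.chain(chain_id):
            if len(res.res_name) > 3:
                raise ValueError(f"residue name {res.res_name!r} longer than 3 characters")
            for a in res.atoms:
                serial += 1
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s} {res.res_name:>3s} {chain_id:1s}"
                    f"{res.res_seq:4d}{res.insertion_code or ' ':1s}   "
                    f"{a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
                    f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
                )
            last = res
        if last is not None:
            serial += 1
            lines.append(
                f"TER   {serial:5d}      {last.res_name:>3s} {chain_id:1s}{last.res_seq:4d}"
            )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Rigid superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired point sets.

    Returns ``(rotation, translation, rmsd)`` with ``rotation`` a proper
    rotation (det = +1) such that ``rotation @ mobile.T + translation``
    best matches ``target``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError(f"point count mismatch: {mobile.shape} vs {target.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("expected N x 3 coordinate arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("at least 3 point pairs required")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    mc = mobile - cm
    tc = target - ct
    if np.linalg.matrix_rank(mc, tol=1e-8) < 2:
        raise ValueError("mobile points are collinear; superposition is degenerate")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on exact fits
        rot, _ = Rotation.align_vectors(tc, mc)
    R = rot.as_matrix()
    t = ct - R @ cm
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return R, t, rmsd


def _ca_coords(structure: Structure, res_seqs: Sequence[int]) -> np.ndarray:
    chain_id = structure.chain_ids[0]
    coords = []
    missing = []
    for seq in res_seqs:
        res = structure.get_residue(chain_id, seq)
        ca = res.atom("CA")
        if ca is None:
            missing.append(f"{chain_id}/{res.res_name}{seq}")
        else:
            coords.append(ca.coord)
    if missing:
        raise ValueError("mapped residues missing CA atoms: " + ", ".join(missing))
    return np.array(coords)


def assemble_dimer(monomer: Structure, template_chain_a: Structure,
                   template_chain_b: Structure,
                   mapping: Iterable[tuple[int, int]]) -> Structure:
    """Build a two-chain assembly from two superposed copies of a monomer.

    ``mapping`` pairs monomer residue numbers with template residue numbers
    (CA atoms are matched). The monomer is superposed once onto each
    template chain; the copies are relabeled "A" and "B".
    """
    pairs = list(mapping)
    if len(pairs) < 3:
        raise ValueError("mapping must pair at least 3 residues")
    mono_seqs = [p[0] for p in pairs]
    templ_seqs = [p[1] for p in pairs]
    mobile = _ca_coords(monomer, mono_seqs)
    dimer = Structure(title=f"{monomer.title} dimer".strip())
    for new_chain, template in (("A", template_chain_a), ("B", template_chain_b)):
        target = _ca_coords(template, templ_seqs)
        R, t, _ = kabsch_superpose(mobile, target)
        copy = monomer.transformed(R, t, chain_id=new_chain)
        for res in copy.residues():
            dimer.add_residue(res)
    return dimer
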