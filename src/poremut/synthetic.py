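"""Deterministic fixture generators with analytically known ground truth.

Every generator is seed-deterministic and returns both the object and a
sidecar ground-truth dict sufficient to test the downstream stage: sphere
sets with closed-form SASA, two-helix poly-Ala bundles with a geometric
contact interface, ring-stacked "barrel" cages with a cylindrical pore of
known clearance, hand-placed contact-geometry micro-fixtures, and synthetic
cohort tables with exact bookkeeping of the generated allele counts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from poremut.structure import Atom, Residue, Structure

_CARBON_R = 1.70


@dataclass
class FixtureSpec:
    kind: str  # spheres | bundle_dimer | barrel | contact_pair | cohort
    seed: int = 0
    parameters: dict = field(default_factory=dict)


def _atom(serial, name, element, coord, chain, res_seq, res_name, radius=None):
    from poremut._tables import vdw_radii

    r = radius if radius is not None else vdw_radii()[element.upper()]
    return Atom(serial, name, element, np.asarray(coord, float), r, chain, res_seq, res_name)


# ---------------------------------------------------------------------------
# Sphere sets with analytic SASA
# ---------------------------------------------------------------------------

def sphere_sasa_analytic(radii: np.ndarray, centers: np.ndarray, probe: float = 1.4) -> list[float]:
    """Closed-form SASA for <= 2 mutually overlapping expanded spheres.

    Isolated sphere: 4π(r+p)². Two overlapping spheres lose a spherical cap
    each: cap height on sphere 1 is h1 = R1 - (d² + R1² - R2²)/(2d) and the
    lost area 2π R1 h1.
    """
    R = np.asarray(radii, float) + probe
    centers = np.asarray(centers, float)
    n = len(R)
    areas = [4.0 * math.pi * r * r for r in R]
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(centers[i] - centers[j]))
            if d >= R[i] + R[j]:
                continue
            hi = R[i] - (d * d + R[i] ** 2 - R[j] ** 2) / (2 * d)
            hj = R[j] - (d * d + R[j] ** 2 - R[i] ** 2) / (2 * d)
            areas[i] -= 2.0 * math.pi * R[i] * hi
            areas[j] -= 2.0 * math.pi * R[j] * hj
    return areas


def make_spheres(positions, probe: float = 1.4) -> tuple[Structure, dict]:
    """Carbon pseudo-atoms at the given positions + analytic SASA table.

    The analytic areas are exact for isolated atoms and for pairwise overlaps
    that do not triple-intersect (the fixtures used keep to those cases).
    """
    positions = np.atleast_2d(np.asarray(positions, float))
    n = len(positions)
    if not (1 <= n <= 100):
        raise ValueError("need between 1 and 100 spheres")
    for i in range(n):
        for j in range(i + 1, n):
            if np.allclose(positions[i], positions[j]):
                raise ValueError(f"spheres {i} and {j} have identical centers")
    s = Structure(title="sphere fixture")
    for i, p in enumerate(positions, start=1):
        s.add_residue(Residue(i, "SPH", "A", [_atom(i, "C", "C", p, "A", i, "SPH")]))
    areas = sphere_sasa_analytic(np.full(n, _CARBON_R), positions, probe)
    truth = {
        "probe": probe,
        "radius": _CARBON_R,
        "analytic_sasa": {str(i + 1): a for i, a in enumerate(areas)},
    }
    return s, truth


# ---------------------------------------------------------------------------
# Helix-bundle dimer with known contact interface
# ---------------------------------------------------------------------------

def _helix_chain(chain_id: str, n_res: int, serial0: int,
                 rise: float = 1.5, twist_deg: float = 100.0,
                 flip: bool = False, offset=(0.0, 0.0, 0.0)) -> list[Residue]:
    """Idealized poly-Ala helix along z; CB points radially outward."""
    residues = []
    serial = serial0
    off = np.asarray(offset, float)
    for i in range(n_res):
        theta = math.radians(twist_deg * i)
        z = rise * i
        def ring(radius, dth=0.0, dz=0.0):
            t = theta + math.radians(dth)
            p = np.array([radius * math.cos(t), radius * math.sin(t), z + dz])
            if flip:  # 180° rotation about the z axis
                p = np.array([-p[0], -p[1], p[2]])
            return p + off
        atoms = [
            _atom(serial + 0, "N", "N", ring(1.6, -25.0, -0.5), chain_id, i + 1, "ALA"),
            _atom(serial + 1, "CA", "C", ring(2.3), chain_id, i + 1, "ALA"),
            _atom(serial + 2, "C", "C", ring(1.7, 25.0, 0.5), chain_id, i + 1, "ALA"),
            _atom(serial + 3, "O", "O", ring(2.6, 35.0, 0.6), chain_id, i + 1, "ALA"),
            _atom(serial + 4, "CB", "C", ring(3.4), chain_id, i + 1, "ALA"),
        ]
        serial += 5
        residues.append(Residue(i + 1, "ALA", chain_id, atoms))
    return residues


def make_bundle_dimer(n_res: int = 20, gap: float = 4.0,
                      twist_deg: float = 120.0) -> tuple[Structure, dict]:
    """Two facing poly-Ala helices separated by a CB-CB ``gap``.

    Chain B is chain A rotated 180° about z and shifted along x so the
    contact-face CB-CB separation equals ``gap``. The default 120°/residue
    twist gives a 3-residue repeat whose contact face is z-aligned between
    the chains, so the designated contact residues are unambiguous: every
    third residue touches at exactly ``gap`` while all other residues point
    away (> 7 Å). Ground truth is the CB rule — CB within min(gap+2, 6) Å of
    the other chain — computed from raw coordinates, independently of the
    detection modules (the 6 Å cap keeps "contact" physical for large gaps).
    """
    if n_res < 10:
        raise ValueError("helix length must be >= 10 residues")
    if gap < 0:
        raise ValueError("gap must be >= 0")
    dx = 6.8 + gap  # CB ring radius 3.4 per chain
    s = Structure(title="bundle dimer fixture")
    for res in _helix_chain("A", n_res, 1, twist_deg=twist_deg):
        s.add_residue(res)
    for res in _helix_chain("B", n_res, 1 + 5 * n_res, twist_deg=twist_deg,
                            flip=True, offset=(dx, 0.0, 0.0)):
        s.add_residue(res)
    cutoff = min(gap + 2.0, 6.0)
    truth = {"gap": gap, "cb_cutoff": cutoff, "inter_axis_distance": dx,
             "interface_res_seq": {}}
    for cid, other in (("A", "B"), ("B", "A")):
        xyz_other = np.array([a.coord for r in s.chain(other) for a in r.atoms])
        members = []
        for res in s.chain(cid):
            cb = res.atom("CB").coord
            if np.sqrt(((xyz_other - cb) ** 2).sum(1)).min() <= cutoff:
                members.append(res.res_seq)
        truth["interface_res_seq"][cid] = members
    return s, truth


# ---------------------------------------------------------------------------
# Barrel cage with a cylindrical pore
# ---------------------------------------------------------------------------

def make_barrel(inner_radius: float = 3.0, n_rings: int = 8,
                ring_spacing: float = 1.5, atoms_per_ring: int = 16,
                constriction: tuple[int, float] | None = None) -> tuple[Structure, dict]:
    """Stacked carbon rings forming a cylinder along z (one residue per ring).

    Analytic on-axis clearance is ``inner_radius - r_C``; an optional
    ``(ring_index, radius)`` constriction narrows one ring.
    """
    if inner_radius < 2.0:
        raise ValueError("inner radius must be >= 2 Å")
    if n_rings < 3:
        raise ValueError("need at least 3 rings")
    if constriction is not None and constriction[1] < 0:
        raise ValueError("constriction radius must be >= 0")
    s = Structure(title="barrel fixture")
    serial = 0
    bottleneck = inner_radius - _CARBON_R
    for ring in range(n_rings):
        radius = inner_radius
        if constriction is not None and ring == constriction[0]:
            radius = constriction[1]
            bottleneck = min(bottleneck, radius - _CARBON_R)
        z = ring * ring_spacing
        atoms = []
        for k in range(atoms_per_ring):
            t = 2.0 * math.pi * k / atoms_per_ring
            serial += 1
            atoms.append(
                _atom(serial, f"C{k + 1}", "C",
                      (radius * math.cos(t), radius * math.sin(t), z),
                      "A", ring + 1, "ALA")
            )
        s.add_residue(Residue(ring + 1, "ALA", "A", atoms))
    zmax = (n_rings - 1) * ring_spacing
    truth = {
        "axis": [0.0, 0.0, 1.0],
        "inner_radius": inner_radius,
        "analytic_clearance": inner_radius - _CARBON_R,
        "bottleneck": bottleneck,
        "z_range": [0.0, zmax],
        "seed_start": [0.0, 0.0, 0.5],
        "seed_end": [0.0, 0.0, zmax - 0.5],
        "wall_res_seq": list(range(1, n_rings + 1)),
    }
    return s, truth


# ---------------------------------------------------------------------------
# Contact-geometry micro-fixtures
# ---------------------------------------------------------------------------

def make_hbond_pair(distance: float = 2.9, partner_seq: int = 541,
                    partner_name: str = "SER") -> tuple[Structure, dict]:
    """A Glu side chain whose OE1 sits ``distance`` from a partner backbone N.

    Geometry is hand-placed so the antecedent angle (CD-OE1-N) is 120°,
    mirroring a carboxylate hydrogen-bonding a backbone amide.
    """
    s = Structure(title="hbond micro-fixture")
    # Glu residue 291 on chain A; side chain extended along +x.
    glu = [
        _atom(1, "N", "N", (-2.9, 0.5, 0.0), "A", 291, "GLU"),
        _atom(2, "CA", "C", (-2.0, 0.0, 0.0), "A", 291, "GLU"),
        _atom(3, "C", "C", (-2.3, -1.4, 0.2), "A", 291, "GLU"),
        _atom(4, "O", "O", (-3.4, -1.8, 0.4), "A", 291, "GLU"),
        _atom(5, "CB", "C", (-0.6, 0.2, 0.1), "A", 291, "GLU"),
        _atom(6, "CG", "C", (0.3, -0.6, -0.4), "A", 291, "GLU"),
        _atom(7, "CD", "C", (1.7, -0.2, -0.2), "A", 291, "GLU"),
        _atom(8, "OE1", "O", (2.2, 0.8, 0.4), "A", 291, "GLU"),
        _atom(9, "OE2", "O", (2.5, -1.0, -0.8), "A", 291, "GLU"),
    ]
    s.add_residue(Residue(291, "GLU", "A", glu))
    # Partner backbone N placed at the requested distance from OE1 along a
    # direction making ~120° with the CD->OE1 bond.
    oe1 = np.array([2.2, 0.8, 0.4])
    cd = np.array([1.7, -0.2, -0.2])
    u = (oe1 - cd) / np.linalg.norm(oe1 - cd)
    perp = np.cross(u, [0.0, 0.0, 1.0])
    perp /= np.linalg.norm(perp)
    direction = math.cos(math.radians(60)) * u + math.sin(math.radians(60)) * perp
    n_pos = oe1 + distance * direction
    partner = [
        _atom(10, "N", "N", n_pos, "A", partner_seq, partner_name),
        _atom(11, "CA", "C", n_pos + np.array([1.2, 0.6, 0.2]), "A", partner_seq, partner_name),
        _atom(12, "C", "C", n_pos + np.array([2.4, -0.2, 0.0]), "A", partner_seq, partner_name),
        _atom(13, "O", "O", n_pos + np.array([3.0, -0.2, 1.0]), "A", partner_seq, partner_name),
        _atom(14, "CB", "C", n_pos + np.array([1.4, 2.0, 0.4]), "A", partner_seq, partner_name),
    ]
    s.add_residue(Residue(partner_seq, partner_name, "A", partner))
    truth = {
        "focus": ["A", 291, ""],
        "expected_detail": f"Glu(OE1)-{partner_name.capitalize()}{partner_seq}(N)",
        "distance": distance,
    }
    return s, truth


def _phe_ring(chain, res_seq, centroid, z_offset_atoms=0.0, serial0=1):
    """Phe residue with a regular hexagonal ring in a z-normal plane."""
    c = np.asarray(centroid, float)
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    atoms = [
        _atom(serial0, "CA", "C", c + np.array([2.8, 0.0, 0.5]), chain, res_seq, "PHE"),
        _atom(serial0 + 1, "CB", "C", c + np.array([2.2, 0.0, 0.2]), chain, res_seq, "PHE"),
    ]
    for k, name in enumerate(names):
        t = 2.0 * math.pi * k / 6.0
        atoms.append(
            _atom(serial0 + 2 + k, name, "C",
                  c + np.array([1.39 * math.cos(t), 1.39 * math.sin(t), z_offset_atoms]),
                  chain, res_seq, "PHE")
        )
    return Residue(res_seq, "PHE", chain, atoms)


def make_aromatic_pair(centroid_distance: float = 4.5) -> tuple[Structure, dict]:
    """Two parallel Phe rings stacked along z at the given centroid separation."""
    s = Structure(title="aromatic micro-fixture")
    s.add_residue(_phe_ring("A", 428, (0.0, 0.0, 0.0), serial0=1))
    s.add_residue(_phe_ring("A", 351, (0.0, 0.0, centroid_distance), serial0=20))
    truth = {"focus": ["A", 428, ""], "partner_seq": 351, "distance": centroid_distance}
    return s, truth


# ---------------------------------------------------------------------------
# Synthetic cohorts
# ---------------------------------------------------------------------------

DEFAULT_MUTATION_POOL = [
    {"cdna": "c.2680C>T", "protein": "p.(Arg894*)", "novel": False},
    {"cdna": "c.1437_1450del", "protein": "p.(Pro480Hisfs*24)", "novel": False},
    {"cdna": "c.1238T>G", "protein": "p.(Phe413Cys)", "novel": False},
    {"cdna": "c.220C>T", "protein": "p.(Gln74*)", "novel": False},
    {"cdna": "c.568G>A", "protein": "p.(Gly190Arg)", "novel": False},
    {"cdna": "c.1471+1G>A", "protein": "", "novel": False},
    {"cdna": "c.871G>C", "protein": "p.(Glu291Gln)", "novel": True},
    {"cdna": "c.905A>G", "protein": "p.(Tyr302Cys)", "novel": True},
]


def make_cohort(n_patients: int = 51, frequencies=None, mutation_pool=None,
                cis_fraction: float = 0.06, homozygote_fraction: float = 0.18,
                single_variant_fraction: float = 0.12, seed: int = 0):
    """Random cohort TSV rows + exact expected counts from generation bookkeeping.

    Returns ``(rows, truth)`` where ``rows`` is a list of dicts in the cohort
    TSV column layout and ``truth`` holds the allele denominator and the
    per-mutation allele counts tallied while generating.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    pool = mutation_pool if mutation_pool is not None else DEFAULT_MUTATION_POOL
    if frequencies is None:
        frequencies = np.full(len(pool), 1.0 / len(pool))
    frequencies = np.asarray(frequencies, float)
    if len(frequencies) != len(pool) or not math.isclose(frequencies.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("frequency vector must match the pool and sum to 1")
    rng = np.random.default_rng(seed)
    rows = []
    counts: dict[str, int] = {m["cdna"]: 0 for m in pool}
    n_alleles = 0

    def draw():
        return pool[int(rng.choice(len(pool), p=frequencies))]

    for pid in range(1, n_patients + 1):
        u = rng.random()
        if u < single_variant_fraction:
            alleles = [[draw()]]
        elif u < single_variant_fraction + homozygote_fraction:
            m = draw()
            alleles = [[m], [m]]
        elif u < single_variant_fraction + homozygote_fraction + cis_fraction:
            a, b = draw(), draw()
            while b["cdna"] == a["cdna"]:
                b = draw()
            alleles = [[a, b], [draw()]]
        else:
            alleles = [[draw()], [draw()]]
        n_alleles += len(alleles)
        for group in alleles:
            for m in group:
                counts[m["cdna"]] += 1
        flat = [m for g in alleles for m in g]
        phase = "|".join(
            str(gi + 1) for gi, g in enumerate(alleles) for _ in g
        ) if len(flat) > 1 else ""
        row = {"patient_id": str(pid), "phenotype": "BD", "phase": phase}
        for i in range(3):
            m = flat[i] if i < len(flat) else None
            row[f"v{i + 1}_cdna"] = m["cdna"] if m else ""
            row[f"v{i + 1}_protein"] = m["protein"] if m else ""
            row[f"v{i + 1}_novel"] = ("yes" if m["novel"] else "no") if m else ""
        rows.append(row)
    truth = {"n_patients": n_patients, "n_disease_alleles": n_alleles, "allele_counts": counts}
    return rows, truth


def write_cohort_tsv(rows: list[dict], path) -> None:
    cols = ["patient_id", "phenotype",
            "v1_cdna", "v1_protein", "v1_novel",
            "v2_cdna", "v2_protein", "v2_novel",
            "v3_cdna", "v3_protein", "v3_novel", "phase"]
    lines = ["\t".join(cols)]
    for r in rows:
        lines.append("\t".join(str(r.get(c, "")) for c in cols))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_truth_json(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
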