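"""Structure model, PDB round-trips and rigid superposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from poremut import synthetic
from poremut.structure import (
    AnalysisConfig,
    PDBParseError,
    assemble_dimer,
    kabsch_superpose,
    read_pdb,
    write_pdb,
)

MINIMAL_PDB = (
    "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
    "END\n"
)


class TestReadPdb:
    def test_minimal_single_atom(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(MINIMAL_PDB)
        s = read_pdb(p)
        assert s.chain_ids == ["A"]
        residues = list(s.residues())
        assert len(residues) == 1
        atom = residues[0].atoms[0]
        assert atom.element == "C"
        assert atom.vdw_radius == pytest.approx(1.70)
        np.testing.assert_allclose(atom.coord, [1.0, 2.0, 3.0])

    def test_bundle_fixture_counts(self, tmp_path, bundle_dimer):
        s, _ = bundle_dimer
        p = tmp_path / "bundle.pdb"
        write_pdb(s, p)
        loaded = read_pdb(p)
        assert loaded.chain_ids == ["A", "B"]
        assert len(loaded.chain("A")) == len(s.chain("A"))
        assert len(loaded.chain("B")) == len(s.chain("B"))

    def test_hetatm_only_is_empty(self, tmp_path):
        p = tmp_path / "het.pdb"
        p.write_text(
            "HETATM    1 CL    CL A   1       0.000   0.000   0.000  1.00  0.00          CL\n"
            "END\n"
        )
        with pytest.raises(ValueError, match="no ATOM records"):
            read_pdb(p)

    def test_malformed_record_names_line(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("ATOM      1  CA  ALA A   1       1.0     xxx     3.0\n")
        with pytest.raises(PDBParseError, match="line 1"):
            read_pdb(p)

    def test_element_inferred_from_name(self, tmp_path):
        p = tmp_path / "noelem.pdb"
        p.write_text("ATOM      1  OG  SER A   1       0.000   0.000   0.000  1.00  0.00\n")
        s = read_pdb(p)
        assert next(s.residues()).atoms[0].element == "O"

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C\n"
            "ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.60  0.00           C\n"
            "END\n"
        )
        s = read_pdb(p)
        atoms = list(s.atoms())
        assert len(atoms) == 1
        assert atoms[0].coord[0] == pytest.approx(9.0)


class TestWritePdb:
    def test_roundtrip_identifiers_and_coordinates(self, tmp_path, barrel):
        s, _ = barrel
        p = tmp_path / "rt.pdb"
        write_pdb(s, p)
        s2 = read_pdb(p)
        assert np.abs(s.coords() - s2.coords()).max() <= 1e-3
        for r1, r2 in zip(s.residues(), s2.residues()):
            assert (r1.key, r1.res_name) == (r2.key, r2.res_name)
            assert [a.name for a in r1.atoms] == [a.name for a in r2.atoms]

    def test_ter_between_chains(self, tmp_path, bundle_dimer):
        s, _ = bundle_dimer
        p = tmp_path / "ter.pdb"
        write_pdb(s, p)
        lines = p.read_text().splitlines()
        ters = [i for i, l in enumerate(lines) if l.startswith("TER")]
        assert len(ters) == 2
        chain_of = [l[21] for l in lines if l.startswith("ATOM")]
        assert chain_of.index("B") == chain_of.count("A")  # A block, TER, then B

    def test_long_residue_name_rejected(self, tmp_path):
        s, _ = synthetic.make_spheres([[0, 0, 0]])
        next(s.residues()).res_name = "ABCD"
        with pytest.raises(ValueError, match="longer than 3"):
            write_pdb(s, tmp_path / "x.pdb")


class TestKabsch:
    def test_identity(self, rng):
        pts = rng.normal(size=(5, 3))
        R, t, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t, 0.0, atol=1e-9)

    def test_recovers_rigid_transform(self, rng):
        pts = rng.normal(size=(8, 3))
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        shift = np.array([1.0, 2.0, 3.0])
        target = pts @ Rz.T + shift
        R, t, rmsd = kabsch_superpose(pts, target)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(R, Rz, atol=1e-8)
        np.testing.assert_allclose(t, shift, atol=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_matches_brute_force_rotation_grid(self):
        """Optimal rmsd agrees with exhaustive search over sampled rotations."""
        mobile = np.array(
            [[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [0.0, 2.0, 0.0], [0.0, 0.0, 2.0]]
        )
        target = mobile.copy()
        target[3] += np.array([0.6, -0.5, 0.6])  # ~1 Å perturbation
        _, _, rmsd = kabsch_superpose(mobile, target)

        cm, ct = mobile.mean(0), target.mean(0)
        best = np.inf
        grid = np.deg2rad(np.arange(0, 360, 6.0))
        fine = np.deg2rad(np.arange(-30, 31, 6.0))
        for a in fine:
            for b in fine:
                for c in grid[:15]:
                    R = Rotation.from_euler("xyz", [a, b, c]).as_matrix()
                    moved = (mobile - cm) @ R.T + ct
                    best = min(best, np.sqrt(np.mean(np.sum((moved - target) ** 2, 1))))
        assert rmsd <= best + 1e-12
        assert best - rmsd < 0.05  # coarse grid cannot beat the closed form by much

    def test_preconditions(self):
        pts = np.zeros((2, 3))
        with pytest.raises(ValueError):
            kabsch_superpose(pts, pts)
        with pytest.raises(ValueError, match="mismatch"):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        line = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), angle=st.floats(-180, 180))
    def test_rmsd_invariant_under_common_rigid_transform(self, seed, angle):
        rng = np.random.default_rng(seed)
        mobile = rng.normal(size=(6, 3))
        target = mobile + rng.normal(scale=0.3, size=(6, 3))
        _, _, rmsd0 = kabsch_superpose(mobile, target)
        R = Rotation.from_euler("xyz", [angle, angle / 2, angle / 3], degrees=True).as_matrix()
        shift = rng.normal(scale=5.0, size=3)
        _, _, rmsd1 = kabsch_superpose(mobile @ R.T + shift, target @ R.T + shift)
        assert rmsd1 == pytest.approx(rmsd0, rel=1e-8, abs=1e-8)
        _, _, rmsd_sym = kabsch_superpose(target, mobile)
        assert rmsd_sym == pytest.approx(rmsd0, rel=1e-8, abs=1e-8)


class TestAssembleDimer:
    def test_self_template_gives_overlapping_chains(self, bundle_dimer):
        s, _ = bundle_dimer
        mono = s.chain_view("A")
        mapping = [(i, i) for i in (1, 5, 10, 15)]
        dimer = assemble_dimer(mono, mono, mono, mapping)
        assert dimer.chain_ids == ["A", "B"]
        ca = np.array([r.atom("CA").coord for r in dimer.chain("A")])
        cb = np.array([r.atom("CA").coord for r in dimer.chain("B")])
        assert np.sqrt(((ca - cb) ** 2).sum(1).mean()) == pytest.approx(0.0, abs=1e-9)

    def test_reproduces_template_geometry(self, bundle_dimer):
        s, truth = bundle_dimer
        mono = s.chain_view("A")
        dimer = assemble_dimer(mono, s.chain_view("A"), s.chain_view("B"),
                               [(i, i) for i in range(1, 21)])

        def centroid_gap(structure):
            centers = [
                np.array([r.atom("CA").coord for r in structure.chain(cid)]).mean(0)
                for cid in structure.chain_ids
            ]
            return np.linalg.norm(centers[0] - centers[1])

        assert centroid_gap(dimer) == pytest.approx(centroid_gap(s), abs=0.01)

    def test_short_mapping_rejected(self, bundle_dimer):
        s, _ = bundle_dimer
        mono = s.chain_view("A")
        with pytest.raises(ValueError, match="at least 3"):
            assemble_dimer(mono, mono, mono, [(1, 1), (2, 2)])


class TestAnalysisConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"probe_radius": 0.0},
            {"grid_spacing": 3.0},
            {"excluded_ranges": [("A", 10, 5)]},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AnalysisConfig(**kwargs)

    def test_excluded_range_lookup(self):
        cfg = AnalysisConfig(excluded_ranges=[("A", 319, 347)])
        assert cfg.is_excluded(("A", 330, ""))
        assert not cfg.is_excluded(("A", 348, ""))
        assert not cfg.is_excluded(("B", 330, ""))
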