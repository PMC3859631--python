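"""Volume/charge/polarity classification and the per-mutation report."""

import itertools

import pytest

from poremut.impact import (
    AAPropertyTable,
    Mutation,
    annotate_mutation,
    charge_change,
    classify_localization,
    delta_volume,
    load_reference_mutations,
    polarity_change,
    round_half_away,
    tabulate_effect_correlation,
    volume_destabilizing,
)
from poremut.interface import find_interface_residues
from poremut.pore import PoreLining
from poremut.structure import AnalysisConfig

TABLE = AAPropertyTable()


class TestElementaryRules:
    @pytest.mark.parametrize(
        "wt,mut,expected",
        [("GLU", "LYS", 30), ("GLY", "TRP", 168), ("MET", "VAL", -23), ("GLU", "GLN", 5)],
    )
    def test_delta_volume_rounds_to_printed_integers(self, wt, mut, expected):
        assert round_half_away(delta_volume(wt, mut, TABLE)) == expected

    def test_delta_volume_antisymmetric(self):
        for wt, mut in itertools.combinations(["GLY", "ALA", "GLU", "TRP", "HIS"], 2):
            assert delta_volume(wt, mut, TABLE) == -delta_volume(mut, wt, TABLE)

    def test_identity_is_zero(self):
        assert delta_volume("ALA", "ALA", TABLE) == 0.0

    @pytest.mark.parametrize(
        "delta,expected",
        [(30.0, True), (-29.9, False), (-101.0, True), (29.999, False), (-30.0, True)],
    )
    def test_volume_destabilizing_boundary_inclusive(self, delta, expected):
        assert volume_destabilizing(delta) is expected

    @pytest.mark.parametrize(
        "wt,mut,expected",
        [("GLU", "LYS", True), ("THR", "MET", False), ("LEU", "PHE", False),
         ("TYR", "HIS", True), ("GLU", "ASP", False)],
    )
    def test_charge_change_uses_three_classes(self, wt, mut, expected):
        assert charge_change(wt, mut, TABLE) is expected

    @pytest.mark.parametrize(
        "wt,mut,expected",
        [("PHE", "SER", True), ("GLU", "GLN", False), ("ALA", "THR", False),
         ("ILE", "ASN", True)],
    )
    def test_polarity_change_three_way_partition(self, wt, mut, expected):
        assert polarity_change(wt, mut, TABLE) is expected

    def test_charge_and_polarity_symmetric(self):
        for wt, mut in itertools.combinations(["GLU", "LYS", "SER", "PHE", "HIS"], 2):
            assert charge_change(wt, mut, TABLE) == charge_change(mut, wt, TABLE)
            assert polarity_change(wt, mut, TABLE) == polarity_change(mut, wt, TABLE)

    def test_unknown_code_rejected(self):
        with pytest.raises(KeyError):
            delta_volume("XYZ", "ALA", TABLE)


class TestMutation:
    def test_from_hgvs(self):
        m = Mutation.from_hgvs("p.(Glu291Lys)")
        assert (m.position, m.wt, m.mut) == (291, "GLU", "LYS")

    @pytest.mark.parametrize("bad", ["p.(Glu291Glu)", "p.(Xxx291Lys)", "c.871G>C"])
    def test_invalid_labels_rejected(self, bad):
        with pytest.raises(ValueError):
            Mutation.from_hgvs(bad)


class TestReferenceTableRegression:
    """The packaged interface/pathway/novel table reproduces 18 of the 21
    printed ΔV/charge/polarity triples; the remaining 3 are documented
    divergences (a ΔV value, a ΔV sign, a charge flag) that no standard
    residue-volume set reproduces."""

    @pytest.fixture()
    def frame(self):
        df = load_reference_mutations()
        return df[df["printed_dv"] != ""]

    def test_row_count(self, frame):
        assert len(frame) == 21

    def test_all_undiverged_rows_match_printed_triples(self, frame):
        clean = frame[frame["divergence"] == ""]
        assert len(clean) == 18
        for _, r in clean.iterrows():
            dv = int(round_half_away(delta_volume(r["wt"], r["mut"], TABLE)))
            cc = "Yes" if charge_change(r["wt"], r["mut"], TABLE) else "No"
            pc = "Yes" if polarity_change(r["wt"], r["mut"], TABLE) else "No"
            assert (dv, cc, pc) == (
                int(r["printed_dv"]), r["printed_charge"], r["printed_polarity"]
            ), r["label"]

    def test_documented_divergences(self, frame):
        div = frame[frame["divergence"] != ""].set_index("label")
        assert set(div.index) == {"p.(Tyr302His)", "p.(Met485Val)", "p.(Ile556Asn)"}
        # Tyr302His: computed -40, printed -35 (value slip)
        r = div.loc["p.(Tyr302His)"]
        assert round_half_away(delta_volume(r["wt"], r["mut"], TABLE)) == -40
        assert int(r["printed_dv"]) == -35
        # Met485Val: magnitude matches, printed sign flipped
        r = div.loc["p.(Met485Val)"]
        dv = round_half_away(delta_volume(r["wt"], r["mut"], TABLE))
        assert dv == -23 and int(r["printed_dv"]) == 23
        # Ile556Asn: both residues neutral, yet printed charge flag is Yes
        r = div.loc["p.(Ile556Asn)"]
        assert charge_change(r["wt"], r["mut"], TABLE) is False
        assert r["printed_charge"] == "Yes"


class TestLocalization:
    def test_precedence_chain(self, bundle_dimer, config):
        s, truth = bundle_dimer
        iset = find_interface_residues(s, config, method="distance")
        interface_seq = truth["interface_res_seq"]["A"][0]
        non_contact = next(
            r.res_seq for r in s.chain("A")
            if r.res_seq not in truth["interface_res_seq"]["A"]
        )
        lining = PoreLining({("A", non_contact, "")}, 3.0)
        rsa = []
        model_range = (1, 20)

        m_if = Mutation(interface_seq, "ALA", "GLY")
        assert classify_localization(m_if, iset, lining, rsa, model_range, s) == "interface"
        m_pore = Mutation(non_contact, "ALA", "GLY")
        assert classify_localization(m_pore, iset, lining, rsa, model_range, s) == "pore"
        m_out = Mutation(600, "ALA", "GLY")
        assert classify_localization(m_out, iset, lining, rsa, model_range, s) == "outside_model"

    def test_surface_when_exposed(self, bundle_dimer, config):
        s, truth = bundle_dimer
        iset = find_interface_residues(s, config, method="distance")
        from poremut.surface import relative_sasa, shrake_rupley

        rsa = relative_sasa(shrake_rupley(s, config), s)
        non_contact = next(
            r.res_seq for r in s.chain("A")
            if r.res_seq not in truth["interface_res_seq"]["A"]
        )
        m = Mutation(non_contact, "ALA", "GLY")
        loc = classify_localization(m, iset, None, rsa, (1, 20), s)
        assert loc in ("surface", "buried_other", "near_interface")
        # exposed poly-Ala outward face in a 2-helix bundle is a surface site
        rec = next(r for r in rsa if r.key == ("A", non_contact, ""))
        if rec.buried is False:
            assert loc == "surface"


class TestAnnotateMutation:
    def test_full_report_on_interface_residue(self, bundle_dimer, config):
        s, truth = bundle_dimer
        iset = find_interface_residues(s, config, method="distance")
        pos = truth["interface_res_seq"]["A"][2]
        m = Mutation(pos, "ALA", "VAL")
        rep = annotate_mutation(m, s, iset, None, config)
        assert rep.localization == "interface"
        assert round_half_away(rep.delta_volume) == 51
        assert rep.charge_change is False and rep.polarity_change is True
        assert rep.volume_destabilizing is True
        assert rep.triple == "+51/No/Yes"
        assert rep.rsa is not None

    def test_wild_type_mismatch_names_both(self, bundle_dimer, config):
        s, _ = bundle_dimer
        m = Mutation(5, "GLU", "LYS")  # structure has ALA at 5
        with pytest.raises(ValueError, match="expected GLU.*ALA"):
            annotate_mutation(m, s, None, None, config)

    def test_outside_model_has_no_structural_fields(self, bundle_dimer, config):
        s, _ = bundle_dimer
        m = Mutation(600, "GLU", "LYS")
        rep = annotate_mutation(m, s, None, None, config, model_range=(1, 20))
        assert rep.localization == "outside_model"
        assert rep.rsa is None and rep.buried is None
        assert rep.charge_change is True  # property flags still computed

    def test_excluded_region_noted(self, bundle_dimer):
        s, _ = bundle_dimer
        cfg = AnalysisConfig(excluded_ranges=[("A", 2, 3)])
        m = Mutation(2, "ALA", "VAL")
        rep = annotate_mutation(m, s, None, None, cfg)
        assert rep.in_excluded_region
        assert "disordered" in rep.note


class TestEffectCorrelation:
    @staticmethod
    def _reports_from(section):
        df = load_reference_mutations()
        sub = df[df["section"] == section]
        reports, ann = [], {}
        loc = "interface" if section == "interface" else "pore"
        for _, r in sub.iterrows():
            m = Mutation(int(r["position"]), r["wt"], r["mut"], r["label"])
            dv = delta_volume(r["wt"], r["mut"], TABLE)
            from poremut.impact import MutationImpactReport

            reports.append(
                MutationImpactReport(
                    m, dv, volume_destabilizing(dv),
                    charge_change(r["wt"], r["mut"], TABLE),
                    polarity_change(r["wt"], r["mut"], TABLE),
                    rsa=None, buried=None, localization=loc,
                )
            )
            ann[r["label"]] = r["effect"]
        return reports, ann

    def test_interface_section_tally(self):
        reports, ann = self._reports_from("interface")
        table = tabulate_effect_correlation(reports, ann)
        assert table.loc["interface", "pronounced_DN"] == 14
        assert table.loc["interface", "weak_DN"] == 2
        assert table.loc["interface", "no_DN"] == 1

    def test_pathway_section_tally(self):
        reports, ann = self._reports_from("pathway")
        table = tabulate_effect_correlation(reports, ann)
        assert table.loc["pore", "pronounced_DN"] == 1
        assert table.loc["pore", "weak_DN"] == 2
        assert table.loc["pore", "no_DN"] == 3

    def test_empty_input_gives_zero_table(self):
        table = tabulate_effect_correlation([], {})
        assert (table.to_numpy() == 0).all()

    def test_missing_annotation_rejected(self):
        reports, ann = self._reports_from("interface")
        del ann["p.(Glu291Lys)"]
        with pytest.raises(KeyError, match="Glu291Lys"):
            tabulate_effect_correlation(reports, ann)
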