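"""Walker-A/Walker-B/Switch-I/W_cat identification rules."""

import numpy as np
import pytest

from ploopkit.config import DEFAULT_CONFIG
from ploopkit.geometry import carboxylate_oxygens, hydroxyl_oxygen, mg_coordination_shell
from ploopkit.motifs import (
    IONIZABLE,
    annotate_site,
    find_switch_i,
    find_walker_a,
    find_walker_b,
    find_wcat,
    wcat_polar_contacts,
)
from ploopkit.pipeline import process_structure
from ploopkit.sites import find_nucleotide_sites
from ploopkit.synth import SiteBlueprint, build_ideal_site


class TestWalkerA:
    def test_ideal_recovers_planted_triple(self, ideal_result):
        model, truth, result = ideal_result
        ann = result.annotation
        assert ann.lys_wa.auth_seq_num == truth.lys_wa_num
        assert ann.k_plus_1.auth_seq_num == truth.k_plus_1_num
        assert ann.k_minus_3.auth_seq_num == truth.k_minus_3_num
        assert ann.k_plus_1.res_name == "THR"

    def test_nearest_of_two_lysines_brute_force(self):
        """The chosen Lys minimises NZ-to-β-O distance over all lysines."""
        model, truth = build_ideal_site(
            SiteBlueprint(lys_nz_beta_target=3.0, extra_lys_nz=(4.5,)))
        site = find_nucleotide_sites(model)[0]
        lys, *_ = find_walker_a(site, model)
        beta = site.ligand.beta_oxygens()
        best = min(
            (r for r in model.polymer_residues()
             if r.res_name == "LYS" and r.atom("NZ") is not None),
            key=lambda r: min(r.atom("NZ").distance(a) for a in beta),
        )
        assert lys.key() == best.key() == (("A", truth.lys_wa_num, ""))

    def test_closer_decoy_wins(self):
        model, truth = build_ideal_site(
            SiteBlueprint(lys_nz_beta_target=3.5, extra_lys_nz=(2.8,)))
        site = find_nucleotide_sites(model)[0]
        lys, *_ = find_walker_a(site, model)
        assert lys.auth_seq_num != truth.lys_wa_num  # the 2.8 Å decoy

    def test_no_lys_in_range_rejects_site(self):
        model, _ = build_ideal_site(SiteBlueprint())
        for res in model.chains["A"]:
            if res.res_name == "LYS":
                nz = res.atom("NZ")
                nz.coords = nz.coords + np.array([0.0, 0.0, 30.0])
        site = find_nucleotide_sites(model)[0]
        assert find_walker_a(site, model) is None
        ann = annotate_site(site, model)
        assert site.reject_reason == "no P-loop Lys"

    def test_gly_k1_flagged(self):
        model, _ = build_ideal_site(SiteBlueprint(k1_name="GLY"))
        site = find_nucleotide_sites(model)[0]
        lys, k1, k3, warnings = find_walker_a(site, model)
        assert k1.res_name == "GLY"
        assert any("not Ser/Thr" in w for w in warnings)


class TestWalkerB:
    def test_clean_window_accepted_without_fallback(self, ideal_result):
        model, truth, result = ideal_result
        ann = result.annotation
        assert ann.wb_residue.auth_seq_num == truth.wb_num
        assert not ann.wb_fallback_used
        assert ann.wb_distance == pytest.approx(truth.wb_k1_distance, abs=0.01)

    def test_decoy_with_ionizable_window_skipped(self):
        """Nearest Asp has Ser in its window; a farther clean Glu wins."""
        model, truth = build_ideal_site(SiteBlueprint(
            wb_k1_target=2.8, wb_window=("LEU", "SER", "VAL"),
            extra_carboxylates=(("GLU", 3.4, ("LEU", "ILE", "VAL")),),
        ))
        result = process_structure(model, compute_sasa=False)[0]
        ann = result.annotation
        assert ann.wb_residue.res_name == "GLU"
        assert ann.wb_residue.auth_seq_num == 60
        assert not ann.wb_fallback_used
        assert ann.wb_distance == pytest.approx(3.4, abs=0.01)

    def test_all_windows_fail_uses_fallback(self):
        model, truth = build_ideal_site(SiteBlueprint(wb_window=("LEU", "SER", "VAL")))
        result = process_structure(model, compute_sasa=False)[0]
        ann = result.annotation
        assert ann.wb_residue.auth_seq_num == truth.wb_num
        assert ann.wb_fallback_used
        assert truth.wb_fallback_expected

    def test_absent_beyond_threshold(self):
        model, _ = build_ideal_site(SiteBlueprint(wb_k1_target=5.5))
        result = process_structure(model, compute_sasa=False)[0]
        assert result.annotation.wb_residue is None

    def test_empty_ionizable_set_degenerates_to_nearest(self):
        """Oracle equivalence: no hydrophobicity check == plain nearest carboxylate."""
        for bp in (SiteBlueprint(wb_window=("LEU", "SER", "VAL")),
                   SiteBlueprint(wb_k1_target=2.8,
                                 extra_carboxylates=(("GLU", 2.6, ("SER", "SER", "SER")),))):
            model, _ = build_ideal_site(bp)
            result = process_structure(model, compute_sasa=False)[0]
            k1 = result.annotation.k_plus_1
            wb, fallback, d = find_walker_b(k1, model, ionizable=frozenset())
            oh = hydroxyl_oxygen(k1)
            candidates = [
                (min(o.distance(oh) for o in carboxylate_oxygens(r)), r.key(), r)
                for r in model.chain(k1.chain_id)
                if r.res_name in ("ASP", "GLU") and carboxylate_oxygens(r)
            ]
            nearest = min(c for c in candidates if c[0] <= DEFAULT_CONFIG.wb_search_max)
            assert wb.key() == nearest[2].key()
            assert not fallback


class TestSwitchI:
    def test_present_at_shell_position(self):
        model, truth = build_ideal_site(SiteBlueprint(include_switch_i=True))
        result = process_structure(model, compute_sasa=False)[0]
        ann = result.annotation
        assert ann.switch_i is not None
        assert ann.switch_i.auth_seq_num == truth.switch_i_num
        shell_pos = {lig.position: lig.residue.auth_seq_num for lig in result.shell.ligands}
        assert shell_pos[3] == truth.switch_i_num

    def test_absent_when_water_at_position_3(self, ideal_result):
        _, _, result = ideal_result
        assert result.annotation.switch_i is None

    def test_recovered_under_jitter(self):
        hits = 0
        for seed in range(100):
            model, truth = build_ideal_site(
                SiteBlueprint(include_switch_i=True, jitter_sd=0.1, seed=seed))
            result = process_structure(model, compute_sasa=False)[0]
            sw = result.annotation.switch_i
            if sw is not None and sw.auth_seq_num == truth.switch_i_num:
                hits += 1
        assert hits == 100


class TestWcat:
    def test_apical_water_selected(self):
        model, truth = build_ideal_site(
            SiteBlueprint(gamma_moiety="ALF4", include_wcat=True,
                          wcat_angle=170.0, wcat_distance=3.2))
        result = process_structure(model, compute_sasa=False)[0]
        ann = result.annotation
        assert ann.wcat is not None
        assert ann.wcat.auth_seq_num == truth.wcat_num
        assert not ann.wcat_is_surrogate

    def test_water_below_angle_threshold_ignored(self):
        model, _ = build_ideal_site(
            SiteBlueprint(gamma_moiety="ALF4", include_wcat=True, wcat_angle=90.0))
        result = process_structure(model, compute_sasa=False)[0]
        assert result.annotation.wcat is None

    def test_larger_angle_wins_among_candidates(self):
        model, truth = build_ideal_site(SiteBlueprint(
            gamma_moiety="ALF4", include_wcat=True, wcat_angle=165.0,
            extra_waters=((150.0, 3.0),)))
        site = find_nucleotide_sites(model)[0]
        site.ligand_class = "ts_analog"
        res, atom, surrogate = find_wcat(site, model)
        assert res.auth_seq_num == truth.wcat_num  # the 165 degree water

    def test_vanadate_apical_oxygen_surrogate(self):
        model, _ = build_ideal_site(SiteBlueprint(gamma_moiety="VO4"))
        result = process_structure(model, compute_sasa=False)[0]
        ann = result.annotation
        assert ann.wcat is not None and ann.wcat.res_name == "VO4"
        assert ann.wcat_is_surrogate


class TestWcatContacts:
    def test_carboxylates_listed_and_nearest_selected(self):
        model, _ = build_ideal_site(SiteBlueprint(
            gamma_moiety="ALF4", include_wcat=True,
            wcat_carboxylates=(("GLU", 2.8), ("ASP", 3.4))))
        result = process_structure(model, compute_sasa=False)[0]
        ann = result.annotation
        by_atom = {(r.res_name, a): d for r, a, d in ann.wcat_ligands}
        assert by_atom[("GLU", "OE1")] == pytest.approx(2.8, abs=0.01)
        assert by_atom[("ASP", "OD1")] == pytest.approx(3.4, abs=0.01)
        assert ann.catalytic_carboxylate.res_name == "GLU"

    def test_contact_list_matches_brute_force(self):
        model, _ = build_ideal_site(SiteBlueprint(
            gamma_moiety="ALF4", include_wcat=True, wcat_carboxylates=(("GLU", 2.8),)))
        result = process_structure(model, compute_sasa=False)[0]
        ann = result.annotation
        site = result.site
        excluded = {site.ligand.residue.key(), site.ligand.mimic_residue.key()}
        brute = sorted(
            (round(a.distance(ann.wcat_atom), 2), r.key(), a.atom_name)
            for r in model.all_residues() if r.key() not in excluded
            for a in r.atoms
            if a.element in ("N", "O") and a is not ann.wcat_atom
            and a.distance(ann.wcat_atom) <= 3.6
        )
        got = sorted((d, r.key(), a) for r, a, d in ann.wcat_ligands)
        assert got == brute

    def test_no_polar_atoms_in_range(self):
        model, _ = build_ideal_site(SiteBlueprint(gamma_moiety="ALF4", include_wcat=True))
        result = process_structure(model, compute_sasa=False)[0]
        ann = result.annotation
        contacts, carbox = wcat_polar_contacts(ann.wcat_atom, result.site, model,
                                               DEFAULT_CONFIG.with_overrides(polar_contact_max=0.5))
        assert contacts == [] and carbox is None


def test_recovery_on_jittered_fixtures():
    """Planted LysWA / K+1 / AspWB recovered at jitter sd up to 0.2 Å."""
    for sd, n in ((0.1, 50), (0.2, 50)):
        for seed in range(n):
            model, truth = build_ideal_site(SiteBlueprint(jitter_sd=sd, seed=seed))
            ann = process_structure(model, compute_sasa=False)[0].annotation
            assert ann.lys_wa.auth_seq_num == truth.lys_wa_num
            assert ann.k_plus_1.auth_seq_num == truth.k_plus_1_num
            assert ann.wb_residue.auth_seq_num == truth.wb_num


def test_reported_distances_rigid_invariant(rotation):
    rot, trans = rotation
    model, _ = build_ideal_site(SiteBlueprint(gamma_moiety="ALF4", include_wcat=True))
    moved = model.transformed(rot, trans)
    r0 = process_structure(model, compute_sasa=False)[0].record
    r1 = process_structure(moved, compute_sasa=False)[0].record
    for field in ("wb_k1_distance", "hnk3_o2g_distance", "k1_mg_distance",
                  "mg_wb_distance", "shell_edge_mean"):
        assert getattr(r0, field) == pytest.approx(getattr(r1, field), abs=0.01)


def test_ionizable_set_matches_documented_rule():
    assert IONIZABLE == {"GLU", "ASP", "SER", "THR", "TYR", "LYS", "ARG", "HIS"}
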