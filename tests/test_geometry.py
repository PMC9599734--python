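"""Distance measurements, Mg shell analytics, calibrations, superposition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_residue
from ploopkit.geometry import (
    Contact,
    classify_hbond,
    contact_inventory,
    beta_pi_distance,
    delta_pka_estimate,
    hnk3_gamma_distance,
    kabsch,
    mg_coordination_shell,
    superpose_ploop,
    wb_k1_distance,
)
from ploopkit.motifs import MotifAnnotation
from ploopkit.pipeline import process_structure
from ploopkit.sites import CatalyticSite, NucleotideLigand
from ploopkit.synth import SiteBlueprint, build_ideal_site


class TestWbK1Distance:
    def test_simple_pair(self):
        wb = make_residue("A", 5, "ASP", [("OD1", "O", (0, 0, 0)), ("OD2", "O", (1.2, 0.8, 0))])
        k1 = make_residue("A", 2, "THR", [("OG1", "O", (0, 0, 2.5))])
        ann = MotifAnnotation(k_plus_1=k1, wb_residue=wb)
        assert wb_k1_distance(ann) == pytest.approx(2.50)

    def test_min_over_both_oxygens(self):
        wb = make_residue("A", 5, "ASP", [("OD1", "O", (3.1, 0, 0)), ("OD2", "O", (2.6, 0, 0))])
        k1 = make_residue("A", 2, "SER", [("OG", "O", (0, 0, 0))])
        ann = MotifAnnotation(k_plus_1=k1, wb_residue=wb)
        assert wb_k1_distance(ann) == pytest.approx(2.60)

    def test_missing_atoms_give_none(self):
        k1 = make_residue("A", 2, "GLY", [("CA", "C", (0, 0, 0))])
        wb = make_residue("A", 5, "ASP", [("OD1", "O", (1, 0, 0))])
        assert wb_k1_distance(MotifAnnotation(k_plus_1=k1, wb_residue=wb)) is None
        assert wb_k1_distance(MotifAnnotation(k_plus_1=None, wb_residue=wb)) is None

    @pytest.mark.parametrize("target", [2.4, 2.65, 3.0])
    def test_equals_planted_target(self, target):
        model, truth = build_ideal_site(SiteBlueprint(wb_k1_target=target))
        rec = process_structure(model, compute_sasa=False)[0].record
        assert rec.wb_k1_distance == pytest.approx(target, abs=0.005)


class TestHnk3Gamma:
    def test_simple_geometry(self):
        k3 = make_residue("A", 13, "ALA", [("N", "N", (0, 0, 0))])
        lig = NucleotideLigand(
            residue=make_residue("A", 500, "ATP", [
                ("PB", "P", (9, 9, 9)), ("O2G", "O", (3, 0, 0)),
                ("O1G", "O", (5, 0, 0)), ("O3G", "O", (4, 4, 0))], hetero=True),
            base_component="ATP")
        site = CatalyticSite(ligand=lig)
        ann = MotifAnnotation(k_minus_3=k3)
        assert hnk3_gamma_distance(ann, site) == pytest.approx(3.00)

    def test_mimic_fluoride_used(self):
        model, truth = build_ideal_site(SiteBlueprint(gamma_moiety="ALF4"))
        rec = process_structure(model, compute_sasa=False)[0].record
        assert rec.hnk3_o2g_distance == pytest.approx(truth.hnk3_distance, abs=0.005)

    def test_planted_value_recovered(self, ideal_result):
        model, truth, result = ideal_result
        assert result.record.hnk3_o2g_distance == pytest.approx(truth.hnk3_distance, abs=0.005)

    def test_no_gamma_gives_none(self):
        model, _ = build_ideal_site(SiteBlueprint(gamma_moiety="none"))
        rec = process_structure(model, compute_sasa=False)[0].record
        assert rec.hnk3_o2g_distance is None


class TestMgShell:
    def test_ideal_octahedron_analytics(self, ideal_result):
        model, truth, result = ideal_result
        shell = result.shell
        assert shell.complete and len(shell.ligands) == 6
        b = truth.mg_bond_length
        assert len(shell.edges) == 12
        for e in shell.edges:
            assert e == pytest.approx(b * math.sqrt(2), abs=1e-3)
        ion = shell.ion
        for i in range(6):
            for j in range(i + 1, 6):
                u = shell.ligands[i].atom.coords - ion.coords
                v = shell.ligands[j].atom.coords - ion.coords
                ang = math.degrees(math.acos(
                    np.clip(np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v), -1, 1)))
                assert ang == pytest.approx(90.0, abs=1e-4) or ang == pytest.approx(180.0, abs=1e-4)

    @pytest.mark.parametrize("b", [2.05, 2.08, 2.12])
    def test_edges_in_proton_transfer_range(self, b):
        """Mg–O bonds of 2.05–2.12 Å put every shell edge in 2.9–3.0 Å."""
        model, _ = build_ideal_site(SiteBlueprint(mg_bond_length=b))
        shell = process_structure(model, compute_sasa=False)[0].shell
        for e in shell.edges:
            assert 2.89 <= e <= 3.01

    def test_position_labels(self, ideal_result):
        model, truth, result = ideal_result
        pos = {lig.position: (lig.residue.auth_seq_num, lig.atom.atom_name)
               for lig in result.shell.ligands}
        for p, expected in truth.shell_positions.items():
            assert pos[p] == expected
        assert result.shell.k1_trans_to_gamma

    def test_deleted_water_incomplete(self):
        model, _ = build_ideal_site(SiteBlueprint())
        # remove one first-shell water (position #5/#6 region)
        model.waters = [w for w in model.waters if w.auth_seq_num != 602]
        result = process_structure(model, compute_sasa=False)[0]
        assert len(result.shell.ligands) == 5
        assert not result.shell.complete

    def test_same_atoms_under_jitter(self):
        for seed in range(100):
            model, truth = build_ideal_site(SiteBlueprint(jitter_sd=0.1, seed=seed))
            result = process_structure(model, compute_sasa=False)[0]
            got = {(lig.residue.auth_seq_num, lig.atom.atom_name)
                   for lig in result.shell.ligands}
            expected_core = set(truth.shell_positions.values())
            assert expected_core <= got
            assert len(got) == 6


class TestHbondClass:
    @pytest.mark.parametrize("d,cls", [
        (2.2, "short"), (2.5, "short"), (2.699, "short"),
        (2.7, "typical"), (2.9, "typical"), (3.2, "typical"),
        (3.21, "long"), (4.0, "long"),
    ])
    def test_boundaries(self, d, cls):
        assert classify_hbond(d) == cls

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            classify_hbond(0.0)

    @given(st.floats(min_value=0.01, max_value=10), st.floats(min_value=0.01, max_value=10))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_class_order(self, a, b):
        """Decreasing distance never moves the class away from short."""
        order = {"short": 0, "typical": 1, "long": 2}
        lo, hi = sorted((a, b))
        assert order[classify_hbond(lo)] <= order[classify_hbond(hi)]


class TestDeltaPka:
    @pytest.mark.parametrize("d,expected", [
        (2.4, 0.0), (2.9, 20.0), (2.65, 10.0), (2.2, 0.0), (3.5, 20.0)])
    def test_calibration(self, d, expected):
        assert delta_pka_estimate(d) == pytest.approx(expected)

    @given(st.floats(min_value=0.1, max_value=6), st.floats(min_value=0.1, max_value=6))
    @settings(max_examples=200, derandomize=True)
    def test_nondecreasing_and_bounded(self, a, b):
        lo, hi = sorted((a, b))
        pa, pb = delta_pka_estimate(lo), delta_pka_estimate(hi)
        assert 0.0 <= pa <= 20.0 and 0.0 <= pb <= 20.0
        assert pa <= pb


class TestSuperposition:
    def test_self_rmsd_zero(self, ideal_result):
        model, _, result = ideal_result
        _, _, rmsd = superpose_ploop(model, result.annotation, model, result.annotation)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigidly_moved_copy_rmsd_zero(self, ideal_result, rotation):
        model, _, result = ideal_result
        rot, trans = rotation
        moved = model.transformed(rot, trans)
        res2 = process_structure(moved, compute_sasa=False)[0]
        _, _, rmsd = superpose_ploop(moved, res2.annotation, model, result.annotation)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_jittered_copy_rmsd_in_band(self, ideal_result):
        model, _, result = ideal_result
        jit, _ = build_ideal_site(SiteBlueprint(jitter_sd=0.1, seed=3))
        resj = process_structure(jit, compute_sasa=False)[0]
        _, _, rmsd = superpose_ploop(jit, resj.annotation, model, result.annotation)
        assert 0.05 <= rmsd <= 0.25

    def test_rmsd_invariant_under_premotion(self, ideal_result, rotation):
        model, _, result = ideal_result
        jit, _ = build_ideal_site(SiteBlueprint(jitter_sd=0.1, seed=3))
        resj = process_structure(jit, compute_sasa=False)[0]
        _, _, rmsd0 = superpose_ploop(jit, resj.annotation, model, result.annotation)
        rot, trans = rotation
        moved = jit.transformed(rot, trans)
        resm = process_structure(moved, compute_sasa=False)[0]
        _, _, rmsd1 = superpose_ploop(moved, resm.annotation, model, result.annotation)
        assert rmsd0 == pytest.approx(rmsd1, abs=1e-6)

    def test_kabsch_matches_scipy(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(0)
        x = rng.normal(size=(15, 3))
        r_true = Rotation.from_euler("zyx", [0.3, -0.8, 1.2]).as_matrix()
        y = (r_true @ x.T).T + np.array([1.0, 2.0, 3.0]) + rng.normal(0, 0.05, (15, 3))
        rot, trans, rmsd = kabsch(x, y)
        est, ssd = Rotation.align_vectors(y - y.mean(0), x - x.mean(0))
        np.testing.assert_allclose(rot, est.as_matrix(), atol=1e-6)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_incomplete_window_raises(self, ideal_result):
        model, _, result = ideal_result
        clipped = model.transformed(np.eye(3), np.zeros(3))
        clipped.chains["A"] = [r for r in clipped.chains["A"] if r.auth_seq_num > 6]
        res2 = process_structure(clipped, compute_sasa=False)[0]
        with pytest.raises(ValueError):
            superpose_ploop(clipped, res2.annotation, model, result.annotation)


class TestContactInventory:
    def test_matches_brute_force(self):
        model, _ = build_ideal_site(SiteBlueprint(
            gamma_moiety="ALF4", include_wcat=True, wcat_carboxylates=(("GLU", 2.8),)))
        result = process_structure(model, compute_sasa=False)[0]
        contacts = contact_inventory(result.site, result.annotation, model)
        probes = [result.site.ligand.gamma_center_atom()] + \
            result.site.ligand.gamma_peripheral_atoms() + [result.annotation.wcat_atom]
        brute = []
        for res in model.polymer_residues():
            for a in res.atoms:
                if a.element in ("N", "O"):
                    for p in probes:
                        d = a.distance(p)
                        if d <= 3.6:
                            brute.append((res.key(), a.atom_name, round(d, 2)))
        got = [(c.residue.key(), c.atom, c.distance) for c in contacts]
        assert sorted(got) == sorted(brute)
        for c in contacts:
            assert c.strength == ("moderate" if c.distance <= 3.2 else "weak")

    def test_moderate_and_weak_labels(self):
        model, _ = build_ideal_site(SiteBlueprint(gamma_moiety="ALF4"))
        result = process_structure(model, compute_sasa=False)[0]
        site, ann = result.site, result.annotation
        # plant a Lys NZ at 2.9 and 3.4 Å from two fluorides
        fl = site.ligand.gamma_peripheral_atoms()
        nz1 = fl[0].coords + 2.9 * np.array([0, 0, 1.0])
        nz2 = fl[1].coords + 3.4 * np.array([0, 0, 1.0])
        probe_res = make_residue("B", 1, "LYS", [("NZ", "N", tuple(nz1))])
        probe_res2 = make_residue("B", 2, "LYS", [("NZ", "N", tuple(nz2))])
        model.chains["B"] = [probe_res, probe_res2]
        contacts = contact_inventory(site, ann, model)
        mine = [c for c in contacts if c.residue.chain_id == "B"]
        strengths = {(c.residue.auth_seq_num, c.strength) for c in mine
                     if c.distance in (2.9, 3.4)}
        assert (1, "moderate") in strengths and (2, "weak") in strengths

    def test_empty_when_nothing_close(self):
        model, _ = build_ideal_site(SiteBlueprint(gamma_moiety="ALF4"))
        result = process_structure(model, compute_sasa=False)[0]
        far = model.transformed(np.eye(3), np.zeros(3))
        # move all polymer atoms far away
        for res in far.chains["A"]:
            for a in res.atoms:
                a.coords = a.coords + np.array([200.0, 0, 0])
        res_far = process_structure(far, compute_sasa=False)[0]
        assert res_far.reject_reason == "no P-loop Lys"
        contacts = contact_inventory(res_far.site, MotifAnnotation(), far)
        assert contacts == []


class TestBetaPi:
    def test_planted_distance(self):
        model, truth = build_ideal_site(SiteBlueprint(gamma_moiety="PI", pi_o2b_target=2.45))
        result = process_structure(model, compute_sasa=False)[0]
        d, bonding = beta_pi_distance(result.site)
        assert d == pytest.approx(2.45, abs=0.01) and bonding
        assert d == pytest.approx(truth.pi_beta_distance, abs=0.01)

    def test_distant_pi_flagged_nonbonding(self):
        lig = NucleotideLigand(
            residue=make_residue("A", 500, "ADP", [
                ("PB", "P", (0, 0, 0)), ("O1B", "O", (1.5, 0, 0)),
                ("O2B", "O", (-0.7, 1.3, 0)), ("O3B", "O", (-0.7, -1.3, 0))], hetero=True),
            base_component="ADP")
        pi = make_residue("A", 520, "PO4", [("P", "P", (8, 0, 0)), ("O1", "O", (6.5, 0, 0))],
                          hetero=True)
        site = CatalyticSite(ligand=lig, pi_residue=pi)
        d, bonding = beta_pi_distance(site)
        assert d == pytest.approx(5.0, abs=0.01) and not bonding

    def test_none_without_pi(self, ideal_result):
        _, _, result = ideal_result
        assert beta_pi_distance(result.site) is None

    def test_min_rule_matches_brute_force(self):
        model, _ = build_ideal_site(SiteBlueprint(gamma_moiety="PI"))
        result = process_structure(model, compute_sasa=False)[0]
        site = result.site
        d, _ = beta_pi_distance(site)
        brute = min(a.distance(b) for a in site.ligand.beta_oxygens()
                    for b in site.pi_residue.atoms if b.element == "O")
        assert d == pytest.approx(brute, abs=0.005)
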