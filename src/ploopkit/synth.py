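"""Synthetic catalytic-site factory with ground-truth labels.

Builds idealised (and optionally noise-perturbed) P-loop NTPase catalytic
sites so that every pipeline stage is testable without downloading
structures. The geometry emulates the conserved arrangement of real
sites:

* a Mg²⁺ ion at the origin with an ideal octahedral shell of O ligands at
  ``mg_bond_length`` along the axes — O2B at position #1, the γ-phosphate
  O1G (or its mimic stand-in) at #2, water or the Switch-I hydroxyl at #3,
  the [Ser/Thr]K+1 hydroxyl at #4 (trans to #2), and waters at #5/#6;
* an extended di-/tri-phosphate with IUPAC atom names (PA/PB/PG,
  O1A..O3G), built with standard bond lengths and near-tetrahedral
  phosphorus centres;
* a P-loop-like backbone (residues K−12 .. K+7) carrying the Walker-A Lys
  (NZ planted near O1B), the K+1 Ser/Thr, and the K−3 residue whose
  backbone N is planted near O2G;
* a Walker-B strand whose Asp (or Glu) carboxylate oxygen sits at exactly
  ``wb_k1_target`` from the K+1 hydroxyl oxygen, preceded by a
  controllable three-residue window (the *hhhh*D motif, or deliberately
  ionizable decoy windows);
* optional γ-mimic moieties (square-planar AlF4, trigonal AlF3/MgF3/BeF3,
  tetrahedral VO4, or a free Pi), an apical catalytic water at a
  controllable O3B–X–Ow angle, decoy carboxylates and decoy lysines;
* Gaussian coordinate jitter applied with the blueprint seed.

Peptide geometry is minimal-but-legal: bond lengths are standard, but no
Ramachandran realism is attempted — the pipeline consumes only distances
and angles. Class-conditional distance distributions drawn by
:func:`build_batch` are test scaffolding, not survey data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import write_structure
from .model import AtomRecord, Residue, StructureModel

GAMMA_CHOICES = ("PO3", "ALF4", "ALF3", "MGF3", "BEF3", "VO4", "PI", "none")

#: residue numbering layout of the synthetic chain A
LYS_WA_NUM = 16          # P-loop block spans 4..23 (K-12 .. K+7)
SWITCH_BLOCK = (34, 36)  # Gly-Thr-Gly carrying the Switch-I Thr
WB_ASP_NUM = 53          # Walker-B block spans 44..53
LIGAND_NUM, MIMIC_NUM, PI_NUM, ION_NUM = 500, 510, 520, 400
WATER_START = 601


@dataclass(frozen=True)
class SiteBlueprint:
    """Complete recipe for one synthetic site; blueprint+seed fixes the output."""

    mg_bond_length: float = 2.1
    wb_k1_target: float = 2.65
    wb_window: tuple[str, str, str] = ("LEU", "ILE", "VAL")  # N→C, immediately before Asp
    wb_res_name: str = "ASP"
    gamma_moiety: str = "PO3"
    base_component: Optional[str] = None  # default: ATP for PO3, ADP otherwise
    include_ion: bool = True
    include_wcat: bool = False
    wcat_angle: float = 170.0
    wcat_distance: float = 3.2
    extra_waters: tuple[tuple[float, float], ...] = ()  # (angle, distance) distractors
    include_switch_i: bool = False
    k1_name: str = "THR"
    k_minus_3_name: str = "ALA"
    lys_nz_beta_target: float = 3.0
    hnk3_target: float = 3.0
    pi_o2b_target: float = 2.45
    extra_lys_nz: tuple[float, ...] = ()
    extra_carboxylates: tuple[tuple[str, float, tuple[str, str, str]], ...] = ()
    wcat_carboxylates: tuple[tuple[str, float], ...] = ()  # planted near W_cat
    jitter_sd: float = 0.0
    seed: int = 0
    structure_id: str = "SYNTH"
    resolution: float = 1.5

    def validate(self) -> None:
        if self.gamma_moiety not in GAMMA_CHOICES:
            raise ValueError(f"gamma_moiety must be one of {GAMMA_CHOICES}")
        if not 1.5 <= self.mg_bond_length <= 3.0:
            raise ValueError("mg_bond_length outside the physically sensible 1.5-3.0 Å")
        if self.wb_k1_target < 1.5:
            raise ValueError("wb_k1_target below 1.5 Å is sterically infeasible")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        if len(self.wb_window) != 3:
            raise ValueError("wb_window must name exactly three residues")
        if not 0 < self.wcat_angle <= 180:
            raise ValueError("wcat_angle must be in (0, 180]")


@dataclass
class GroundTruth:
    """Planted labels and distances of a built site (pre-jitter geometry)."""

    structure_id: str
    ligand_class: str
    gamma_species: Optional[str]
    lys_wa_num: int = LYS_WA_NUM
    k_plus_1_num: int = LYS_WA_NUM + 1
    k_minus_3_num: int = LYS_WA_NUM - 3
    wb_num: Optional[int] = WB_ASP_NUM
    wb_fallback_expected: bool = False
    switch_i_num: Optional[int] = None
    wcat_num: Optional[int] = None
    wb_k1_distance: Optional[float] = None
    hnk3_distance: Optional[float] = None
    pi_beta_distance: Optional[float] = None
    k1_mg_distance: Optional[float] = None
    mg_bond_length: float = 2.1
    shell_positions: dict[int, tuple[int, str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# small vector helpers


def _unit(v) -> np.ndarray:
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


def _perp(v: np.ndarray) -> np.ndarray:
    v = _unit(v)
    other = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(v, other))


def _tetrahedral_completion(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing a near-tetrahedral centre given bonds a, b."""
    m = -_unit(a + b)
    n = _unit(np.cross(a, b))
    phi = math.radians(54.735)  # half the tetrahedral angle
    return _unit(m * math.cos(phi) + n * math.sin(phi)), _unit(m * math.cos(phi) - n * math.sin(phi))


def _cone_dirs(axis: np.ndarray, angle_deg: float, count: int, phase: np.ndarray) -> list[np.ndarray]:
    """`count` unit vectors at `angle_deg` from axis, evenly spaced, first toward `phase`."""
    axis = _unit(axis)
    e1 = _unit(phase - np.dot(phase, axis) * axis) if np.linalg.norm(
        phase - np.dot(phase, axis) * axis) > 1e-8 else _perp(axis)
    e2 = _unit(np.cross(axis, e1))
    out = []
    for k in range(count):
        t = 2 * math.pi * k / count
        out.append(_unit(axis * math.cos(math.radians(angle_deg))
                         + (e1 * math.cos(t) + e2 * math.sin(t)) * math.sin(math.radians(angle_deg))))
    return out


def _trilaterate(c1: np.ndarray, r1: float, c2: np.ndarray, r2: float, hint: np.ndarray) -> np.ndarray:
    """A point at distance r1 from c1 and r2 from c2, nearest to `hint`."""
    d = np.linalg.norm(c2 - c1)
    if d > r1 + r2 or d < abs(r1 - r2):
        raise ValueError("spheres do not intersect; infeasible geometric constraint")
    ex = _unit(c2 - c1)
    x = (d * d + r1 * r1 - r2 * r2) / (2 * d)
    h2 = r1 * r1 - x * x
    h = math.sqrt(max(h2, 0.0))
    center = c1 + x * ex
    if h < 1e-9:
        return center
    rad = hint - center
    rad = rad - np.dot(rad, ex) * ex
    if np.linalg.norm(rad) < 1e-9:
        rad = _perp(ex)
    return center + h * _unit(rad)


def _zigzag(start: np.ndarray, end: np.ndarray, n_bonds: int, bond: float) -> list[np.ndarray]:
    """Interior points of a zig-zag chain with equal bond lengths start→end.

    Interior points alternate between the axis and a parallel offset line;
    with offset h = sqrt(bond² − step²) every consecutive pair is exactly
    one bond apart (ends sit on the axis, so n_bonds should be even for an
    exactly closed zig-zag; odd counts leave the last bond slightly long).
    """
    start, end = np.asarray(start, float), np.asarray(end, float)
    span = np.linalg.norm(end - start)
    step = span / n_bonds
    if step > bond + 1e-9:
        raise ValueError("anchors too far apart for the requested bond count")
    h = math.sqrt(max(bond * bond - step * step, 0.0))
    axis = _unit(end - start)
    p = _perp(axis)
    return [start + axis * step * i + p * h * (i % 2) for i in range(1, n_bonds)]


# ---------------------------------------------------------------------------
# residue assembly helpers


def _res(chain: str, num: int, name: str, atoms: list[tuple[str, str, np.ndarray]],
         hetero: bool = False) -> Residue:
    records = [AtomRecord(an, el, np.asarray(xyz, float), 1.0, "", hetero)
               for an, el, xyz in atoms]
    return Residue(chain, num, name, records, "", hetero)


def _backbone_residues(chain: str, numbers: Sequence[int], names: Sequence[str],
                       ca_trace: Sequence[np.ndarray], outward_from: np.ndarray,
                       n_overrides: dict[int, np.ndarray] | None = None,
                       extra_atoms: dict[int, list[tuple[str, str, np.ndarray]]] | None = None,
                       ) -> list[Residue]:
    """Residues with N/CA/C/O built from a CA trace (standard bond lengths).

    Residues listed in ``extra_atoms`` supply their own side chain; everyone
    else (except Gly) gets a generic outward-pointing CB.
    """
    n_overrides = n_overrides or {}
    extra_atoms = extra_atoms or {}
    residues = []
    ncas = len(ca_trace)
    for i, (num, name) in enumerate(zip(numbers, names)):
        ca = np.asarray(ca_trace[i], float)
        nxt = np.asarray(ca_trace[i + 1], float) if i + 1 < ncas else ca + np.array([3.8, 0, 0])
        prv = np.asarray(ca_trace[i - 1], float) if i > 0 else ca - (nxt - ca)
        t_fwd = _unit(nxt - ca)
        t_back = _unit(prv - ca)
        p = _perp(t_fwd)
        c = ca + 1.52 * t_fwd
        o = c + 1.23 * _unit(p + 0.3 * t_back)
        n = n_overrides.get(num, ca + 0.95 * t_back + 1.11 * p)
        atoms = [("N", "N", n), ("CA", "C", ca), ("C", "C", c), ("O", "O", o)]
        if name != "GLY" and num not in extra_atoms:
            atoms.append(("CB", "C", ca + 1.53 * _unit(ca - outward_from)))
        atoms.extend(extra_atoms.get(num, []))
        residues.append(_res(chain, num, name, atoms))
    return residues


# ---------------------------------------------------------------------------
# the builder


def build_ideal_site(bp: SiteBlueprint) -> tuple[StructureModel, GroundTruth]:
    """Construct one synthetic catalytic site and its ground truth.

    The returned ground truth records the planted residue numbers, shell
    position labels and key distances measured on the ideal (pre-jitter)
    geometry; jitter, when requested, is applied afterwards with the
    blueprint seed.
    """
    bp.validate()
    b = bp.mg_bond_length
    origin = np.zeros(3)

    # octahedral shell anchor positions
    P1 = np.array([b, 0.0, 0.0])        # O2B
    P2 = np.array([0.0, b, 0.0])        # O1G role
    P3 = np.array([0.0, 0.0, b])        # W3 / Switch-I
    P4 = np.array([0.0, -b, 0.0])       # K+1 hydroxyl
    P5 = np.array([0.0, 0.0, -b])
    P6 = np.array([-b, 0.0, 0.0])

    model = StructureModel(id=bp.structure_id, resolution=bp.resolution)
    truth = GroundTruth(
        structure_id=bp.structure_id,
        ligand_class="",
        gamma_species=None,
        mg_bond_length=b,
    )

    # ---- triphosphate scaffold -------------------------------------------
    # phosphorus centres first: PG 1.52 Å behind the #2 ligand, PB 1.52 Å
    # behind O2B, P–P ≈ 2.9 Å (P–O3B–P bridge with a ~130° angle); the
    # bridging O3B is then equidistant from both
    gamma_dir = _unit(np.array([0.3, 1.0, 0.15]))
    X = P2 + 1.52 * gamma_dir                    # γ central atom position
    to_o1g = _unit(P2 - X)
    PB = _trilaterate(P1, 1.52, X, 2.90, hint=np.array([3.5, 1.5, 1.2]))
    O3B = _trilaterate(PB, 1.60, X, 1.59, hint=PB + np.array([0.5, 0.5, 1.5]))
    rest = _tetrahedral_completion(to_o1g, _unit(O3B - X))
    O2G = X + 1.52 * rest[0]
    O3G = X + 1.52 * rest[1]
    to_o3b = _unit(O3B - PB)
    to_o2b = _unit(P1 - PB)
    u1, u2 = _tetrahedral_completion(to_o3b, to_o2b)
    O1B = PB + 1.48 * u1
    O3A = PB + 1.60 * u2
    PA = O3A + 1.60 * _unit(O3A - PB)
    pa_dirs = _cone_dirs(_unit(PB - PA), 109.47, 3, np.array([0.0, 0.0, 1.0]))
    O1A = PA + 1.48 * pa_dirs[0]
    O2A = PA + 1.48 * pa_dirs[1]

    base = bp.base_component or ("ATP" if bp.gamma_moiety == "PO3" else "ADP")
    lig_atoms = [
        ("PA", "P", PA), ("O1A", "O", O1A), ("O2A", "O", O2A), ("O3A", "O", O3A),
        ("PB", "P", PB), ("O1B", "O", O1B), ("O2B", "O", P1), ("O3B", "O", O3B),
    ]
    if bp.gamma_moiety == "PO3":
        lig_atoms += [("PG", "P", X), ("O1G", "O", P2), ("O2G", "O", O2G), ("O3G", "O", O3G)]
    ligand = _res("A", LIGAND_NUM, base, lig_atoms, hetero=True)
    model.hetero.append(ligand)

    mimic_res: Optional[Residue] = None
    gamma_axis = _unit(X - O3B)  # apical axis (O3B → center, extended)
    if bp.gamma_moiety in ("ALF4", "ALF3", "MGF3", "BEF3"):
        element, species, bond = {
            "ALF4": ("AL", "AlF4", 1.70), "ALF3": ("AL", "AlF3", 1.70),
            "MGF3": ("MG", "MgF3", 1.80), "BEF3": ("BE", "BeF3", 1.55),
        }[bp.gamma_moiety]
        nf = 4 if bp.gamma_moiety == "ALF4" else 3
        code = {"ALF4": "ALF", "ALF3": "AF3", "MGF3": "MGF", "BEF3": "BEF"}[bp.gamma_moiety]
        fdirs = _cone_dirs(gamma_axis, 90.0, nf, phase=P2 - X)
        atoms = [({"AL": "AL1", "MG": "MG1", "BE": "BE1"}[element], element, X)]
        atoms += [(f"F{k + 1}", "F", X + bond * d) for k, d in enumerate(fdirs)]
        mimic_res = _res("A", MIMIC_NUM, code, atoms, hetero=True)
        model.hetero.append(mimic_res)
        truth.gamma_species = species
    elif bp.gamma_moiety == "VO4":
        odirs = [gamma_axis] + _cone_dirs(gamma_axis, 109.47, 3, phase=P2 - X)
        atoms = [("V1", "V", X)] + [(f"O{k + 1}", "O", X + 1.66 * d)
                                    for k, d in enumerate(odirs)]
        mimic_res = _res("A", PI_NUM - 5, "VO4", atoms, hetero=True)
        model.hetero.append(mimic_res)
        truth.gamma_species = "VO4"
    elif bp.gamma_moiety == "PI":
        # free phosphate within association range of O3B, one O aimed at O2B;
        # scan the admissible circle of P positions for the orientation where
        # the planted O(Pi)–O2B pair is the strict minimum over all O–O pairs
        beta_o = [P1, O3B]

        def _pi_atoms(hint: np.ndarray):
            p = _trilaterate(O3B, 3.4, P1, bp.pi_o2b_target + 1.55, hint=hint)
            aim = _unit(P1 - p)
            dirs = _cone_dirs(aim, 109.47, 3, phase=p - O3B)
            return [("P", "P", p), ("O1", "O", p + 1.55 * aim)] + [
                (f"O{k + 2}", "O", p + 1.55 * d) for k, d in enumerate(dirs)]

        def _margin(atoms) -> float:
            others = min(np.linalg.norm(xyz - bo) for nm, el, xyz in atoms[2:]
                         for bo in beta_o + [O1B])
            o1_o1b = np.linalg.norm(atoms[1][2] - O1B)
            o1_o3b = np.linalg.norm(atoms[1][2] - O3B)
            return min(others, o1_o1b, o1_o3b) - bp.pi_o2b_target

        axis0 = _unit(np.cross(P1 - O3B, np.array([0.0, 0.0, 1.0])))
        hints = [O3B + 4.0 * (math.cos(a) * axis0
                              + math.sin(a) * _unit(np.cross(P1 - O3B, axis0)))
                 for a in np.linspace(0, 2 * math.pi, 36, endpoint=False)]
        atoms = max((_pi_atoms(h) for h in hints), key=_margin)
        pi_res = _res("A", PI_NUM, "PO4", atoms, hetero=True)
        model.hetero.append(pi_res)
        truth.pi_beta_distance = round(min(
            float(np.linalg.norm(xyz - bo)) for nm, el, xyz in atoms[1:]
            for bo in (P1, O3B, O1B)), 4)

    # ---- cofactor ion and waters -----------------------------------------
    if bp.include_ion:
        model.hetero.append(_res("A", ION_NUM, "MG", [("MG", "MG", origin)], hetero=True))

    water_num = WATER_START
    def _water(pos: np.ndarray) -> Residue:
        nonlocal water_num
        res = _res("A", water_num, "HOH", [("O", "O", pos)], hetero=True)
        water_num += 1
        model.waters.append(res)
        return res

    if bp.include_ion:
        if not bp.include_switch_i:
            _water(P3)
        _water(P5)
        _water(P6)
    if bp.k1_name not in ("SER", "THR") and bp.include_ion:
        _water(P4)  # something must occupy shell position #4

    def _wcat_pos(angle: float, dist: float) -> np.ndarray:
        v1 = _unit(O3B - X)
        p = _perp(v1)
        d = v1 * math.cos(math.radians(angle)) + p * math.sin(math.radians(angle))
        return X + dist * d

    wcat_pos: Optional[np.ndarray] = None
    if bp.include_wcat and bp.gamma_moiety not in ("none", "PI", "VO4"):
        wcat_pos = _wcat_pos(bp.wcat_angle, bp.wcat_distance)
        w = _water(wcat_pos)
        truth.wcat_num = w.auth_seq_num
    for angle, dist in bp.extra_waters:
        _water(_wcat_pos(angle, dist))

    # ---- P-loop peptide ---------------------------------------------------
    k1_og = P4
    k1_has_oh = bp.k1_name in ("SER", "THR")
    cb_dir = _unit(np.array([0.15, -1.0, 0.45]))
    k1_cb = k1_og + 1.43 * cb_dir
    k1_ca = k1_cb + 1.53 * _unit(np.array([0.75, -0.8, -0.35]))

    # NZ above the β/γ bridge (LysWA straddles O1B and O2G in real sites),
    # at exactly the planted distance from O1B
    NZ = O1B + bp.lys_nz_beta_target * _unit(np.array([0.0, 0.5, 1.0]))
    lys_ca = _trilaterate(k1_ca, 3.8, NZ, 6.2, hint=k1_ca + np.array([-2.0, 2.0, 4.0]))

    # K-3 backbone N planted near O2G (or the matching mimic atom)
    if bp.gamma_moiety == "PO3":
        hn_anchor = O2G
    elif mimic_res is not None:
        periph = [a for a in mimic_res.atoms if a.element in ("F", "O")]
        hn_anchor = min(periph, key=lambda a: np.linalg.norm(a.coords - O2G)).coords
    else:
        hn_anchor = None
    if hn_anchor is not None:
        n_k3 = hn_anchor + bp.hnk3_target * _unit(hn_anchor - X)
    else:
        n_k3 = O3B + 3.0 * _unit(O3B - PB) + np.array([0.0, 0.0, 2.0])
    k3_ca = n_k3 + 1.46 * _unit(lys_ca - n_k3)

    # CA trace K-12..K+7 through the three anchors
    ca = {LYS_WA_NUM: lys_ca, LYS_WA_NUM + 1: k1_ca, LYS_WA_NUM - 3: k3_ca}
    for i, pos in enumerate(_zigzag(k3_ca, lys_ca, 3, 3.8)):
        ca[LYS_WA_NUM - 2 + i] = pos
    back_dir = _unit(k3_ca - lys_ca + np.array([0.0, 2.0, 1.0]))
    wig = _perp(back_dir)
    for j in range(1, 10):  # K-4 .. K-12
        ca[LYS_WA_NUM - 3 - j] = k3_ca + 3.6 * j * back_dir + 1.2 * wig * (j % 2)
    fwd_dir = _unit(k1_ca - lys_ca + np.array([0.5, -2.0, -1.0]))
    wig2 = _perp(fwd_dir)
    for j in range(1, 7):  # K+2 .. K+7
        ca[LYS_WA_NUM + 1 + j] = k1_ca + 3.6 * j * fwd_dir + 1.2 * wig2 * (j % 2)

    numbers = list(range(LYS_WA_NUM - 12, LYS_WA_NUM + 8))
    names = []
    for num in numbers:
        if num == LYS_WA_NUM:
            names.append("LYS")
        elif num == LYS_WA_NUM + 1:
            names.append(bp.k1_name)
        elif num == LYS_WA_NUM - 3:
            names.append(bp.k_minus_3_name)
        else:
            names.append("GLY" if (num % 3 == 0) else "ALA")

    extra: dict[int, list[tuple[str, str, np.ndarray]]] = {}
    lys_side = _zigzag(lys_ca, NZ, 5, 1.53)
    extra[LYS_WA_NUM] = [(nm, "C", pos) for nm, pos in zip(("CB", "CG", "CD", "CE"), lys_side)]
    extra[LYS_WA_NUM].append(("NZ", "N", NZ))
    if k1_has_oh:
        og_name = "OG1" if bp.k1_name == "THR" else "OG"
        extra[LYS_WA_NUM + 1] = [("CB", "C", k1_cb), (og_name, "O", k1_og)]
        if bp.k1_name == "THR":
            extra[LYS_WA_NUM + 1].append(("CG2", "C", k1_cb + 1.52 * _unit(np.array([-0.8, -0.6, 0.8]))))

    ploop = _backbone_residues("A", numbers, names, [ca[n] for n in numbers],
                               outward_from=origin,
                               n_overrides={LYS_WA_NUM - 3: n_k3},
                               extra_atoms=extra)
    chain_a: list[Residue] = list(ploop)

    # ---- Switch-I block ---------------------------------------------------
    if bp.include_switch_i:
        sw_og = P3
        sw_cb = sw_og + 1.43 * _unit(np.array([0.3, 0.5, 1.0]))
        sw_ca = sw_cb + 1.53 * _unit(np.array([-0.4, 0.8, 0.9]))
        trace = [sw_ca - np.array([3.8, 0.4, 0.0]), sw_ca, sw_ca + np.array([3.5, 0.6, 1.2])]
        sw = _backbone_residues("A", range(SWITCH_BLOCK[0], SWITCH_BLOCK[1] + 1),
                                ["GLY", "THR", "GLY"], trace, outward_from=origin,
                                extra_atoms={SWITCH_BLOCK[0] + 1: [("CB", "C", sw_cb),
                                                                   ("OG1", "O", sw_og)]})
        chain_a.extend(sw)
        truth.switch_i_num = SWITCH_BLOCK[0] + 1

    # ---- Walker-B strand --------------------------------------------------
    # WB carboxylate on the #3/#6 side (toward +z), as in the conserved fold
    wb_dir = _unit(np.array([0.75, -0.25, 0.62]))
    od1 = k1_og + bp.wb_k1_target * wb_dir
    chain_a.extend(_carboxylate_segment(
        "A", WB_ASP_NUM, bp.wb_res_name, bp.wb_window, od1,
        away=_unit(od1 - k1_og), origin=origin))
    if not k1_has_oh:
        truth.wb_num = None

    # carboxylates planted near W_cat (the "catalytic" Glu/Asp of most
    # non-TRAFAC classes), numbered 70, 72, ...
    if wcat_pos is not None:
        for k, (resname, dist) in enumerate(bp.wcat_carboxylates):
            cdir = _unit(np.array([0.8 - 0.5 * k, 0.4 + 0.4 * k, 0.45]))
            o_pos = wcat_pos + dist * cdir
            chain_a.extend(_carboxylate_segment(
                "A", 130 + 10 * k, resname, ("LEU", "ILE", "VAL"), o_pos,
                away=cdir, origin=origin))

    # decoy carboxylates: numbered 60, 70, ... with their own windows
    for k, (resname, dist, window) in enumerate(bp.extra_carboxylates):
        ddir = _unit(np.array([-0.6 - 0.2 * k, -0.55, -0.58 + 0.25 * k]))
        o_pos = k1_og + dist * ddir
        chain_a.extend(_carboxylate_segment(
            "A", 60 + 10 * k, resname, tuple(window), o_pos,
            away=_unit(o_pos - k1_og), origin=origin))

    # decoy lysines, NZ at stated distances from O1B
    for k, dist in enumerate(bp.extra_lys_nz):
        ldir = _unit(np.array([0.4, 0.9, -0.8 + 0.5 * k]))
        nz = O1B + dist * ldir
        lca = nz + 6.0 * _unit(ldir + np.array([0.3, 0.2, 0.1]))
        side = _zigzag(lca, nz, 5, 1.53)
        atoms = [("N", "N", lca + np.array([0.0, 1.4, 0.4])), ("CA", "C", lca),
                 ("C", "C", lca + np.array([1.4, -0.4, 0.4])),
                 ("O", "O", lca + np.array([1.9, -1.3, 0.0]))]
        atoms += [(nm, "C", pos) for nm, pos in zip(("CB", "CG", "CD", "CE"), side)]
        atoms.append(("NZ", "N", nz))
        chain_a.append(_res("A", 90 + 2 * k, "LYS", atoms))

    chain_a.sort(key=lambda r: r.auth_seq_num)
    model.chains["A"] = chain_a

    # ---- ground truth (measured on the ideal geometry) -------------------
    truth.ligand_class = _expected_class(bp)
    if k1_has_oh and truth.wb_num is not None:
        truth.wb_k1_distance = round(float(bp.wb_k1_target), 4)
    if hn_anchor is not None:
        gamma_atoms = ([P2, O2G, O3G] if bp.gamma_moiety == "PO3"
                       else [a.coords for a in mimic_res.atoms if a.element in ("F", "O")])
        truth.hnk3_distance = round(min(float(np.linalg.norm(n_k3 - g)) for g in gamma_atoms), 4)
    if bp.include_ion and k1_has_oh:
        truth.k1_mg_distance = round(b, 4)
    if bp.include_ion:
        truth.shell_positions = _expected_shell(bp)
    if any(window_name in ("GLU", "ASP", "SER", "THR", "TYR", "LYS", "ARG", "HIS")
           for window_name in bp.wb_window):
        truth.wb_fallback_expected = not bp.extra_carboxylates

    if bp.jitter_sd > 0:
        rng = np.random.default_rng(bp.seed)
        for res in model.all_residues():
            for atom in res.atoms:
                atom.coords = atom.coords + rng.normal(0.0, bp.jitter_sd, 3)
    return model, truth


def _carboxylate_segment(chain: str, asp_num: int, res_name: str,
                         window: tuple[str, str, str], o_anchor: np.ndarray,
                         away: np.ndarray, origin: np.ndarray) -> list[Residue]:
    """A 7-residue strand ending in an Asp/Glu whose OD1/OE1 sits at o_anchor."""
    names = ["GLY", "ALA", "GLY"] + list(window) + [res_name]
    numbers = list(range(asp_num - 6, asp_num + 1))
    onames = ("OE1", "OE2") if res_name == "GLU" else ("OD1", "OD2")
    w = _unit(away + np.array([0.1, -0.2, 0.1]))
    carboxyl_c = o_anchor + 1.25 * w            # CG of Asp / CD of Glu
    o2 = carboxyl_c + 1.25 * _unit(w + _perp(w))
    cb = carboxyl_c + 1.52 * _unit(w + 0.3 * _perp(w))
    ca_end = cb + 1.53 * _unit(w)
    strand_dir = _unit(w + np.array([0.2, 0.1, -0.3]))
    trace = [ca_end + 3.5 * strand_dir * (len(numbers) - 1 - i) for i in range(len(numbers))]
    trace[-1] = ca_end
    side: list[tuple[str, str, np.ndarray]] = [("CB", "C", cb)]
    if res_name == "GLU":
        side += [("CG", "C", 0.5 * (cb + carboxyl_c)), ("CD", "C", carboxyl_c)]
    else:
        side += [("CG", "C", carboxyl_c)]
    side += [(onames[0], "O", o_anchor), (onames[1], "O", o2)]
    return _backbone_residues(chain, numbers, names, trace, outward_from=origin,
                              extra_atoms={asp_num: side})


def _expected_class(bp: SiteBlueprint) -> str:
    if bp.gamma_moiety == "PO3":
        base = bp.base_component or "ATP"
        return "native" if base in ("ATP", "GTP") else "non_hydrolyzable"
    if bp.gamma_moiety in ("ALF4", "MGF3", "VO4"):
        return "ts_analog"
    if bp.gamma_moiety in ("ALF3", "BEF3"):
        return "substrate_analog"
    return "ndp_only"


def _expected_shell(bp: SiteBlueprint) -> dict[int, tuple[int, str]]:
    out: dict[int, tuple[int, str]] = {1: (LIGAND_NUM, "O2B")}
    if bp.gamma_moiety == "PO3":
        out[2] = (LIGAND_NUM, "O1G")
    elif bp.gamma_moiety in ("ALF4", "ALF3", "MGF3", "BEF3"):
        out[2] = (MIMIC_NUM, "F1")
    elif bp.gamma_moiety == "VO4":
        out[2] = (PI_NUM - 5, "O2")
    if bp.k1_name in ("SER", "THR"):
        out[4] = (LYS_WA_NUM + 1, "OG1" if bp.k1_name == "THR" else "OG")
    if bp.include_switch_i:
        out[3] = (SWITCH_BLOCK[0] + 1, "OG1")
    return out


# ---------------------------------------------------------------------------
# batches

#: class-conditional WB–K+1 draws for batches: test scaffolding echoing the
#: ordering (TS analogues shortest), NOT survey data.
BATCH_WB_K1 = {
    "native": (2.65, 0.08),
    "non_hydrolyzable": (2.65, 0.08),
    "substrate_analog": (2.65, 0.08),
    "ts_analog": (2.50, 0.05),
}

BATCH_GAMMA = {
    "native": "PO3",
    "non_hydrolyzable": "PO3",
    "substrate_analog": "BEF3",
    "ts_analog": "ALF4",
}


def batch_blueprints(n_per_class: int, seed: int,
                     classes: Sequence[str] = tuple(BATCH_WB_K1),
                     jitter_sd: float = 0.02,
                     include_switch_i: bool = False) -> list[SiteBlueprint]:
    """Deterministic per-class blueprints with class-conditional WB–K+1 draws."""
    rng = np.random.default_rng(seed)
    bps = []
    for cls in classes:
        mu, sd = BATCH_WB_K1[cls]
        gamma = BATCH_GAMMA[cls]
        base = "ANP" if cls == "non_hydrolyzable" else None
        for i in range(n_per_class):
            target = float(np.clip(rng.normal(mu, sd), 2.3, 3.2))
            bps.append(SiteBlueprint(
                wb_k1_target=round(target, 3),
                gamma_moiety=gamma,
                base_component=base,
                include_wcat=(gamma != "PO3"),
                include_switch_i=include_switch_i,
                jitter_sd=jitter_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
                structure_id=f"SYN-{cls.replace('_', '')[:3].upper()}-{i:03d}",
            ))
    return bps


def build_batch(out_dir: str | Path, n_per_class: int = 10, seed: int = 0,
                classes: Sequence[str] = tuple(BATCH_WB_K1),
                jitter_sd: float = 0.02,
                include_switch_i: bool = False) -> pd.DataFrame:
    """Write a directory of synthetic PDB files plus a ground-truth TSV.

    Returns the truth table (one row per file). Identical arguments produce
    byte-identical outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for bp in batch_blueprints(n_per_class, seed, classes, jitter_sd, include_switch_i):
        model, truth = build_ideal_site(bp)
        path = out_dir / f"{bp.structure_id}.pdb"
        write_structure(model, path)
        rows.append({
            "structure_id": truth.structure_id,
            "file": path.name,
            "ligand_class": truth.ligand_class,
            "gamma_species": truth.gamma_species,
            "lys_wa_num": truth.lys_wa_num,
            "k_plus_1_num": truth.k_plus_1_num,
            "k_minus_3_num": truth.k_minus_3_num,
            "wb_num": truth.wb_num,
            "wb_k1_distance": truth.wb_k1_distance,
            "hnk3_distance": truth.hnk3_distance,
            "seed": bp.seed,
        })
    df = pd.DataFrame(rows)
    header = ("# synthetic ground truth; class-conditional distances are test "
              "scaffolding, not survey data\n")
    tsv = out_dir / "ground_truth.tsv"
    with open(tsv, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)
    return df
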