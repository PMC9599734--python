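"""Distance and angle measurements around the catalytic site.

This module implements the quantitative heart of the survey:

* the Walker-B–[Ser/Thr]K+1 hydrogen-bond length, the single most
  diagnostic distance (short, < 2.7 Å, in most sites; shortest with
  transition-state analogues bound);
* the backbone HN(K−3) to γ-phosphate oxygen distance (heavy-atom N–O/F
  proxy for the amide H-bond);
* the octahedral Mg²⁺ coordination shell with the field's position labels
  #1–#6 (#1 = O2B, #2 = O1G or its mimic stand-in, #4 = K+1 hydroxyl);
* H-bond classification (short < 2.7 Å, typical 2.7–3.2 Å, long > 3.2 Å)
  and the linear H-bond-length → ΔpKa calibration (0 at 2.4 Å, 20 at
  2.9 Å, clamped);
* Kabsch superposition of the 20-residue β1-strand/P-loop/α1-helix window
  (K−12 .. K+7) between annotated structures;
* the donor/acceptor contact inventory around the γ-moiety and the
  catalytic water, and the β-phosphate–Pi distance of post-hydrolysis
  sites.

All distances are heavy-atom distances in Å, recorded at 0.01 Å precision;
display rounding to 0.1 Å is left to the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .model import AtomRecord, Residue, StructureModel

if TYPE_CHECKING:  # pragma: no cover
    from .motifs import MotifAnnotation
    from .sites import CatalyticSite

HYDROXYL_NAMES = ("OG", "OG1")
CARBOXYLATE_O = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BACKBONE_NAMES = ("N", "CA", "C", "O")

#: ΔpKa calibration endpoints: donor–acceptor O–O distance (Å) → ΔpKa units.
PKA_CAL_SHORT = (2.4, 0.0)
PKA_CAL_LONG = (2.9, 20.0)

#: H-bond class boundaries (Å): short < 2.7 <= typical <= 3.2 < long.
HBOND_SHORT_MAX = 2.7
HBOND_TYPICAL_MAX = 3.2


def angle_at(center: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Angle a–center–b in degrees."""
    u = np.asarray(a, float) - np.asarray(center, float)
    v = np.asarray(b, float) - np.asarray(center, float)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


# ---------------------------------------------------------------------------
# Scalar calibrations


def classify_hbond(d: float) -> str:
    """Classify a donor–acceptor distance as short / typical / long.

    The boundary convention follows the survey: short bonds are < 2.7 Å,
    the typical range is 2.7–3.2 Å inclusive, anything longer is long.
    """
    if d <= 0:
        raise ValueError(f"distance must be positive, got {d}")
    if d < HBOND_SHORT_MAX:
        return "short"
    if d <= HBOND_TYPICAL_MAX:
        return "typical"
    return "long"


def delta_pka_estimate(d: float) -> float:
    """Estimate the donor/acceptor pKa mismatch from an O—H···O distance.

    Empirically, ΔpKa decreases linearly from 20 to 0 as the O–O distance
    contracts from 2.9 Å to 2.4 Å; outside this interval the estimate is
    clamped to [0, 20]. A value near 0 (bond near 2.4 Å) indicates matched
    proton affinities, i.e. a low-barrier hydrogen bond.
    """
    d0, p0 = PKA_CAL_SHORT
    d1, p1 = PKA_CAL_LONG
    t = (d - d0) / (d1 - d0)
    return float(min(max(p0 + t * (p1 - p0), 0.0), 20.0))


# ---------------------------------------------------------------------------
# Pairwise site distances


def _min_pair_distance(atoms_a: list[AtomRecord], atoms_b: list[AtomRecord]) -> Optional[float]:
    if not atoms_a or not atoms_b:
        return None
    xa = np.array([a.coords for a in atoms_a])
    xb = np.array([b.coords for b in atoms_b])
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
    return float(d.min())


def carboxylate_oxygens(res: Residue) -> list[AtomRecord]:
    names = CARBOXYLATE_O.get(res.res_name, ())
    return res.atoms_named(*names)


def hydroxyl_oxygen(res: Residue) -> Optional[AtomRecord]:
    for name in HYDROXYL_NAMES:
        a = res.atom(name)
        if a is not None:
            return a
    return None


def wb_k1_distance(annotation: "MotifAnnotation") -> Optional[float]:
    """Min distance from the Walker-B carboxylate oxygens to the K+1 hydroxyl O.

    Reported at 0.01 Å precision; ``None`` when either partner or its
    required atoms are absent.
    """
    if annotation.wb_residue is None or annotation.k_plus_1 is None:
        return None
    oh = hydroxyl_oxygen(annotation.k_plus_1)
    if oh is None:
        return None
    d = _min_pair_distance(carboxylate_oxygens(annotation.wb_residue), [oh])
    return None if d is None else round(d, 2)


def hnk3_gamma_distance(annotation: "MotifAnnotation", site: "CatalyticSite") -> Optional[float]:
    """Backbone N of the K−3 residue to the nearest γ-phosphate O (or mimic F/O)."""
    if annotation.k_minus_3 is None:
        return None
    n = annotation.k_minus_3.atom("N")
    if n is None:
        return None
    gamma = site.ligand.gamma_peripheral_atoms()
    d = _min_pair_distance([n], gamma)
    return None if d is None else round(d, 2)


def beta_pi_distance(site: "CatalyticSite") -> Optional[tuple[float, bool]]:
    """Min O–O distance between β-phosphate and a bound inorganic phosphate.

    Returns ``(distance, bonding)`` where ``bonding`` is False when the
    minimum exceeds the 3.6 Å H-bond ceiling; ``None`` when no Pi present.
    """
    if site.pi_residue is None:
        return None
    beta = site.ligand.beta_oxygens()
    pi_o = [a for a in site.pi_residue.atoms if a.element == "O"]
    d = _min_pair_distance(beta, pi_o)
    if d is None:
        return None
    return round(d, 2), d <= 3.6


# ---------------------------------------------------------------------------
# Mg2+ coordination shell


@dataclass
class ShellLigand:
    atom: AtomRecord
    residue: Residue
    position: Optional[int]  # 1..6, None if unassigned
    distance: float


@dataclass
class MgShell:
    """The first coordination shell of the cofactor ion.

    ``edges`` are the distances between cis ligand pairs (Mg-centred angle
    < 120°); in an ideal octahedron with bond length b there are 12 of
    them, each b·√2. ``k1_trans_to_gamma`` records whether the K+1
    hydroxyl (#4) is the ligand opposite to O1G (#2), the arrangement
    conserved across the superfamily.
    """

    ion: AtomRecord
    ligands: list[ShellLigand] = field(default_factory=list)
    edges: list[float] = field(default_factory=list)
    complete: bool = False
    k1_trans_to_gamma: Optional[bool] = None

    def by_position(self, pos: int) -> Optional[ShellLigand]:
        for lig in self.ligands:
            if lig.position == pos:
                return lig
        return None

    @property
    def edge_mean(self) -> Optional[float]:
        return float(np.mean(self.edges)) if self.edges else None


def mg_coordination_shell(
    site: "CatalyticSite",
    model: StructureModel,
    annotation: Optional["MotifAnnotation"] = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> MgShell:
    """Detect and label the octahedral coordination shell of the site's ion.

    The six nearest O/N/F atoms within ``config.shell_max`` of the ion form
    the shell. Position labels follow the conserved arrangement:
    #1 = O2B of β-phosphate, #2 = the γ-moiety ligand (O1G or a mimic
    fluoride/oxygen), #4 = the K+1 hydroxyl; the ligand trans to #1 is #6,
    and of the remaining trans pair the one nearer the Walker-B carboxylate
    is #3, the other #5.
    """
    if site.ion is None:
        raise ValueError("site has no cofactor ion; shell undefined")
    ion = site.ion.atoms[0]
    ligand_res = site.ligand.residue
    mimic_res = site.ligand.mimic_residue

    candidates: list[ShellLigand] = []
    for res, atom in model.all_atoms():
        if res is site.ion or atom is ion:
            continue
        if atom.element not in ("O", "N", "F"):
            continue
        d = atom.distance(ion)
        if d <= config.shell_max:
            candidates.append(ShellLigand(atom, res, None, round(d, 3)))
    candidates.sort(key=lambda s: (s.distance, s.residue.key(), s.atom.atom_name))
    ligands = candidates[:6]

    shell = MgShell(ion=ion, ligands=ligands, complete=len(ligands) == 6)

    # --- fixed labels
    def _assign(pred, pos):
        for lig in ligands:
            if lig.position is None and pred(lig):
                lig.position = pos
                return lig
        return None

    gamma_atoms = {id(a) for a in site.ligand.gamma_peripheral_atoms()}
    l1 = _assign(lambda s: s.residue.key() == ligand_res.key() and s.atom.atom_name == "O2B", 1)
    l2 = _assign(lambda s: id(s.atom) in gamma_atoms
                 or (mimic_res is not None and s.residue.key() == mimic_res.key()), 2)
    l4 = None
    if annotation is not None and annotation.k_plus_1 is not None:
        oh = hydroxyl_oxygen(annotation.k_plus_1)
        if oh is not None:
            l4 = _assign(lambda s: s.atom is oh, 4)

    def _trans_partner(ref: ShellLigand) -> Optional[ShellLigand]:
        best, best_angle = None, 0.0
        for lig in ligands:
            if lig is ref or lig.position is not None:
                continue
            ang = angle_at(ion.coords, ref.atom.coords, lig.atom.coords)
            if ang > best_angle:
                best, best_angle = lig, ang
        return best if best is not None and best_angle >= 120.0 else None

    if l1 is not None:
        l6 = _trans_partner(l1)
        if l6 is not None:
            l6.position = 6
    if l2 is not None and l4 is not None:
        shell.k1_trans_to_gamma = angle_at(ion.coords, l2.atom.coords, l4.atom.coords) >= 120.0

    remaining = [lig for lig in ligands if lig.position is None]
    if remaining:
        wb_oxy = carboxylate_oxygens(annotation.wb_residue) if (
            annotation is not None and annotation.wb_residue is not None) else []

        def _wb_dist(lig: ShellLigand) -> float:
            d = _min_pair_distance([lig.atom], wb_oxy)
            return d if d is not None else math.inf

        remaining.sort(key=lambda s: (_wb_dist(s), s.distance, s.atom.atom_name))
        remaining[0].position = 3
        if len(remaining) > 1:
            remaining[1].position = 5
        if len(remaining) > 2 and l4 is None:
            remaining[2].position = 4  # unannotated shells: keep labels exhaustive

    coords = np.array([lig.atom.coords for lig in ligands]) if ligands else np.empty((0, 3))
    edges = []
    for i in range(len(ligands)):
        for j in range(i + 1, len(ligands)):
            if angle_at(ion.coords, coords[i], coords[j]) < 120.0:
                edges.append(round(float(np.linalg.norm(coords[i] - coords[j])), 3))
    shell.edges = edges
    return shell


# ---------------------------------------------------------------------------
# P-loop superposition


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of point sets (R, t, RMSD).

    Returns rotation R and translation t such that ``R @ x + t`` maps the
    mobile points onto the reference frame, and the post-fit RMSD.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    h = (mobile - cm).T @ (reference - cr)
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rot = vt.T @ d @ u.T
    trans = cr - rot @ cm
    moved = (rot @ mobile.T).T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rot, trans, rmsd


def ploop_window(model: StructureModel, annotation: "MotifAnnotation",
                 start: int = -12, stop: int = 7) -> list[Residue]:
    """The K−12 .. K+7 residue window around the Walker-A lysine."""
    lys = annotation.lys_wa
    if lys is None:
        raise ValueError("annotation has no Walker-A lysine")
    chain = model.chain(lys.chain_id)
    i = model.residue_index(lys)
    lo, hi = i + start, i + stop
    if lo < 0 or hi >= len(chain):
        raise ValueError(
            f"P-loop window K{start}..K+{stop} incomplete: chain {lys.chain_id} "
            f"has residues {chain[0].auth_seq_num}..{chain[-1].auth_seq_num}"
        )
    return chain[lo:hi + 1]


def superpose_ploop(
    mobile_model: StructureModel, mobile_annotation: "MotifAnnotation",
    ref_model: StructureModel, ref_annotation: "MotifAnnotation",
) -> tuple[np.ndarray, np.ndarray, float]:
    """Superpose the 20-residue β1/P-loop/α1 window onto a reference.

    Backbone N/CA/C/O atoms of residues K−12 .. K+7 (20 residues) are
    matched positionally; missing backbone atoms raise with the offending
    residue named.
    """
    windows = []
    for model, ann in ((mobile_model, mobile_annotation), (ref_model, ref_annotation)):
        window = ploop_window(model, ann)
        coords, missing = [], []
        for res in window:
            for name in BACKBONE_NAMES:
                a = res.atom(name)
                if a is None:
                    missing.append(f"{res.label}:{name}")
                else:
                    coords.append(a.coords)
        if missing:
            raise ValueError(f"{model.id}: backbone atoms missing in P-loop window: {missing}")
        windows.append(np.array(coords))
    return kabsch(windows[0], windows[1])


# ---------------------------------------------------------------------------
# Contact inventory


@dataclass
class Contact:
    probe_atom: str         # atom of the γ-moiety or W_cat
    residue: Residue        # protein partner
    atom: str               # partner atom name
    distance: float
    strength: str           # moderate (≤ 3.2 Å) or weak (3.2–3.6 Å)


def contact_inventory(
    site: "CatalyticSite",
    annotation: "MotifAnnotation",
    model: StructureModel,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[Contact]:
    """All H-bond-range contacts of the γ-moiety (and W_cat) with protein N/O.

    Every donor/acceptor heavy-atom pair at ≤ 3.6 Å between the probe set
    (γ-phosphate or mimic peripheral+central atoms, plus the catalytic
    water oxygen when identified) and polymer N/O atoms is listed, labelled
    moderate (≤ 3.2 Å) or weak (3.2–3.6 Å).
    """
    probes: list[tuple[str, AtomRecord]] = []
    center = site.ligand.gamma_center_atom()
    if center is not None:
        probes.append((center.atom_name, center))
    probes += [(a.atom_name, a) for a in site.ligand.gamma_peripheral_atoms()]
    if annotation.wcat is not None and annotation.wcat.res_name == "HOH":
        ow = annotation.wcat.atom("O")
        if ow is not None:
            probes.append(("Wcat:O", ow))

    contacts: list[Contact] = []
    for res in model.polymer_residues():
        for atom in res.atoms:
            if atom.element not in ("N", "O"):
                continue
            for pname, probe in probes:
                d = atom.distance(probe)
                if d <= config.polar_contact_max:
                    strength = "moderate" if d <= config.hbond_moderate_max else "weak"
                    contacts.append(Contact(pname, res, atom.atom_name, round(d, 2), strength))
    contacts.sort(key=lambda c: (c.distance, c.residue.key(), c.atom, c.probe_atom))
    return contacts


# ---------------------------------------------------------------------------
# Output row


@dataclass
class SiteRecord:
    """One output row of the survey table (TSV column schema in ploopkit.io)."""

    structure_id: str
    chain: str
    site_label: str
    ligand_class: str
    resolution: Optional[float] = None
    lys_wa: Optional[str] = None
    k_plus_1: Optional[str] = None
    k_minus_3: Optional[str] = None
    wb_residue: Optional[str] = None
    wb_fallback_used: bool = False
    wb_k1_distance: Optional[float] = None
    hbond_class: Optional[str] = None
    delta_pka: Optional[float] = None
    hnk3_o2g_distance: Optional[float] = None
    k1_mg_distance: Optional[float] = None
    mg_wb_distance: Optional[float] = None
    shell_edge_mean: Optional[float] = None
    shell_complete: Optional[bool] = None
    asp_wb_rel_sasa: Optional[float] = None
    switch_i: Optional[str] = None
    wcat: Optional[str] = None
    catalytic_carboxylate: Optional[str] = None
    qc_all_pass: bool = False
    warnings: str = ""

    def as_dict(self) -> dict:
        return dict(self.__dict__)
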