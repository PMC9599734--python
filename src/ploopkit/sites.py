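"""Locating and classifying Mg-NTP catalytic sites.

A candidate site is one bound nucleoside di-/tri-phosphate. Diphosphates
(ADP/GDP) only count as full catalytic sites when a γ-phosphate-mimicking
moiety (AlF4⁻, AlF3, MgF3⁻, BeF3, VO4³⁻) sits on the O3B oxygen; the
composite NDP+mimic is then treated as one ligand. Accepted sites fall
into four mutually exclusive classes:

``native``
    intact ATP/GTP;
``non_hydrolyzable``
    β,γ-imido/methylene/γ-thio analogues (ANP, GNP, ACP, GCP, AGS, GSP);
``substrate_analog``
    NDP:BeF3 or NDP:AlF3 — ground-state mimics;
``ts_analog``
    NDP:AlF4⁻, NDP:MgF3⁻ or ADP:VO4³⁻ — transition-state mimics.

Metal-fluoride species are re-identified from their geometry (square-planar
AlF4 vs trigonal-planar AlF3/MgF3/BeF3) because deposited component codes
are occasionally wrong; geometry overrides the code on conflict. An NDP
with a separate inorganic phosphate nearby is recorded as a post-hydrolysis
site (class ``ndp_only`` with ``pi_present``), used only for the
β-phosphate–Pi distance measurement.

Site integrity (QC) combines four checks: a P-loop Lys within 5 Å of the
β-phosphate, presence of the γ-moiety, [Ser/Thr]K+1–Mg²⁺ ≤ 2.5 Å, and
Mg²⁺–Walker-B carboxylate ≤ 6 Å.
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

LIGAND_CLASSES = ("native", "non_hydrolyzable", "substrate_analog", "ts_analog")

#: central-atom elements of γ-phosphate mimics (and of γ-phosphate itself)
MIMIC_CENTER_ELEMENTS = {"AL", "BE", "MG", "V", "P"}

#: fallback species by deposited component code, used when geometry is inconclusive
SPECIES_BY_CODE = {"ALF": "AlF4", "AF3": "AlF3", "MGF": "MgF3", "BEF": "BeF3", "VO4": "VO4"}

SPECIES_CLASS = {
    "AlF4": "ts_analog",
    "MgF3": "ts_analog",
    "VO4": "ts_analog",
    "AlF3": "substrate_analog",
    "BeF3": "substrate_analog",
}

GAMMA_PERIPHERAL_NAMES = ("O1G", "O2G", "O3G", "S1G")


@dataclass
class NucleotideLigand:
    """A bound nucleotide, possibly composite (NDP + γ-mimic)."""

    residue: Residue
    base_component: str
    mimic_residue: Optional[Residue] = None
    mimic_species: Optional[str] = None

    def atom(self, name: str) -> Optional[AtomRecord]:
        return self.residue.atom(name)

    def beta_oxygens(self) -> list[AtomRecord]:
        return self.residue.atoms_named("O1B", "O2B", "O3B")

    def o3b(self) -> Optional[AtomRecord]:
        return self.residue.atom("O3B")

    def has_gamma(self) -> bool:
        return self.residue.atom("PG") is not None or self.mimic_residue is not None

    def gamma_center_atom(self) -> Optional[AtomRecord]:
        """PG of an intact (tri)phosphate, or the mimic's central Al/Be/Mg/V atom."""
        if self.mimic_residue is not None:
            return mimic_center(self.mimic_residue)
        return self.residue.atom("PG")

    def gamma_peripheral_atoms(self) -> list[AtomRecord]:
        """The γ oxygens (O1G/O2G/O3G, S1G for γ-thio) or the mimic's F/O atoms."""
        if self.mimic_residue is not None:
            center = mimic_center(self.mimic_residue)
            return [a for a in self.mimic_residue.atoms
                    if a.element in ("F", "O") and a is not center]
        return self.residue.atoms_named(*GAMMA_PERIPHERAL_NAMES)

    def o1g_role_atom(self) -> Optional[AtomRecord]:
        """The γ atom standing in O1G's role (the Mg²⁺ ligand position #2).

        For an intact γ-phosphate this is O1G itself; for a mimic it is the
        peripheral atom nearest to O2B (#2 and #1 are cis shell neighbours,
        so the coordinating fluorine/oxygen is the one closest to O2B).
        """
        if self.mimic_residue is None:
            return self.residue.atom("O1G")
        o2b = self.residue.atom("O2B")
        periph = self.gamma_peripheral_atoms()
        if not periph:
            return None
        if o2b is None:
            return periph[0]
        return min(periph, key=lambda a: a.distance(o2b))


@dataclass
class QCResult:
    lys_near_beta: bool = False
    gamma_moiety_present: bool = False
    k1_mg_ok: bool = False
    mg_wb_ok: bool = False
    k1_mg_distance: Optional[float] = None
    mg_wb_distance: Optional[float] = None
    lys_beta_distance: Optional[float] = None
    reasons: list[str] = field(default_factory=list)

    @property
    def all_pass(self) -> bool:
        return self.lys_near_beta and self.gamma_moiety_present and self.k1_mg_ok and self.mg_wb_ok


@dataclass
class CatalyticSite:
    ligand: NucleotideLigand
    ion: Optional[Residue] = None
    ligand_class: Optional[str] = None
    qc: Optional[QCResult] = None
    pi_residue: Optional[Residue] = None
    reject_reason: Optional[str] = None

    @property
    def chain_id(self) -> str:
        return self.ligand.residue.chain_id

    @property
    def label(self) -> str:
        lig = self.ligand.residue.label
        if self.ligand.mimic_residue is not None:
            lig += "+" + self.ligand.mimic_residue.label
        return lig

    @property
    def accepted(self) -> bool:
        return (self.reject_reason is None and self.ion is not None
                and self.qc is not None and self.qc.all_pass
                and self.ligand_class in LIGAND_CLASSES)


def mimic_center(res: Residue) -> Optional[AtomRecord]:
    for atom in res.atoms:
        if atom.element in MIMIC_CENTER_ELEMENTS:
            return atom
    return None


# ---------------------------------------------------------------------------


def find_nucleotide_sites(
    model: StructureModel, config: PipelineConfig = DEFAULT_CONFIG
) -> list[CatalyticSite]:
    """One candidate site per bound nucleotide hetero-residue.

    NDP ligands get the nearest mimic residue whose central atom lies
    within ``config.mimic_assoc_max`` of O3B attached; a nearby inorganic
    phosphate is attached as ``pi_residue`` instead. Nucleotides missing
    the β-phosphorus are returned with a reject reason.
    """
    ndp_codes = config.codes("ndp")
    mimics = [r for r in model.hetero if r.res_name in config.codes("mimic")]
    phosphates = [r for r in model.hetero if r.res_name in config.codes("phosphate")]

    sites: list[CatalyticSite] = []
    for res in model.hetero:
        if res.res_name not in (config.nucleotide_codes | ndp_codes):
            continue
        ligand = NucleotideLigand(residue=res, base_component=res.res_name)
        site = CatalyticSite(ligand=ligand)
        if res.atom("PB") is None:
            site.reject_reason = "incomplete ligand"
            sites.append(site)
            continue
        if res.res_name in ndp_codes:
            o3b = res.atom("O3B")
            if o3b is not None:
                ligand.mimic_residue = _nearest_by_center(mimics, o3b, config.mimic_assoc_max)
                if ligand.mimic_residue is None:
                    site.pi_residue = _nearest_by_center(phosphates, o3b, config.mimic_assoc_max)
        sites.append(site)
    sites.sort(key=lambda s: s.ligand.residue.key())
    return sites


def _nearest_by_center(
    residues: list[Residue], anchor: AtomRecord, cutoff: float
) -> Optional[Residue]:
    best, best_d = None, math.inf
    for res in residues:
        center = mimic_center(res)
        if center is None:
            continue
        d = center.distance(anchor)
        if d <= cutoff and d < best_d:
            best, best_d = res, d
    return best


def validate_fluoride_geometry(mimic: Residue) -> str:
    """Identify a γ-mimic species from its own geometry.

    Four fluorines in a near-square plane (max deviation from their
    least-squares plane ≤ 0.3 Å) identify AlF4; three fluorines coplanar
    with the central atom identify AlF3/MgF3/BeF3 by element; vanadium
    with four oxygens is vanadate. Anything else is ``unknown``.
    """
    center = mimic_center(mimic)
    if center is None:
        return "unknown"
    element = center.element
    fluorines = [a for a in mimic.atoms if a.element == "F"]
    oxygens = [a for a in mimic.atoms if a.element == "O"]

    if element == "V":
        return "VO4" if len(oxygens) == 4 else "unknown"
    if element == "P":
        return "unknown"  # inorganic phosphate is not a γ-mimic species
    if len(fluorines) >= 4:
        pts = np.array([a.coords for a in fluorines[:4]])
        if _max_plane_deviation(pts) <= 0.3:
            return "AlF4" if element == "AL" else "unknown"
        return "unknown"
    if len(fluorines) == 3:
        pts = np.array([a.coords for a in fluorines] + [center.coords])
        if _max_plane_deviation(pts) <= 0.3:
            return {"AL": "AlF3", "MG": "MgF3", "BE": "BeF3"}.get(element, "unknown")
        return "unknown"
    return "unknown"


def _max_plane_deviation(points: np.ndarray) -> float:
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    normal = vt[2]
    return float(np.max(np.abs(centered @ normal)))


def classify_ligand(site: CatalyticSite, config: PipelineConfig = DEFAULT_CONFIG) -> str:
    """Assign one of the four ligand classes (or ``ndp_only``).

    For composite ligands the mimic species confirmed by
    :func:`validate_fluoride_geometry` takes precedence over the deposited
    component code.
    """
    code = site.ligand.base_component
    if code in config.codes("ntp"):
        return "native"
    if code in config.codes("non_hydrolyzable"):
        return "non_hydrolyzable"
    if code in config.codes("ndp"):
        mimic = site.ligand.mimic_residue
        if mimic is None:
            return "ndp_only"
        species = validate_fluoride_geometry(mimic)
        if species == "unknown":
            species = SPECIES_BY_CODE.get(mimic.res_name, "unknown")
        site.ligand.mimic_species = species
        return SPECIES_CLASS.get(species, "ndp_only")
    return "ndp_only"


def find_cofactor_ion(
    model: StructureModel, site: CatalyticSite, config: PipelineConfig = DEFAULT_CONFIG
) -> Optional[Residue]:
    """The Mg/Mn/Ca ion serving the site, or None.

    The candidate nearest to the midpoint of the O2B and O1G-role anchors
    is returned, provided it lies within ``config.ion_anchor_max`` of
    either anchor.
    """
    anchors = [a for a in (site.ligand.atom("O2B"), site.ligand.o1g_role_atom()) if a is not None]
    if not anchors:
        return None
    midpoint = np.mean([a.coords for a in anchors], axis=0)
    best, best_d = None, math.inf
    for res in model.hetero:
        if res.res_name not in config.codes("ion") or not res.atoms:
            continue
        ion_atom = res.atoms[0]
        d_mid = float(np.linalg.norm(ion_atom.coords - midpoint))
        if d_mid < best_d and any(ion_atom.distance(a) <= config.ion_anchor_max for a in anchors):
            best, best_d = res, d_mid
    return best


def qc_site(
    site: CatalyticSite,
    annotation: "MotifAnnotation",
    config: PipelineConfig = DEFAULT_CONFIG,
) -> QCResult:
    """Apply the four integrity criteria to an annotated site.

    All distances are heavy-atom minima: Lys NZ to any β-phosphate O,
    the K+1 hydroxyl O to the ion, and the ion to the nearest Walker-B
    carboxylate O.
    """
    from .geometry import carboxylate_oxygens, hydroxyl_oxygen

    qc = QCResult()
    qc.gamma_moiety_present = site.ligand.has_gamma()
    if not qc.gamma_moiety_present:
        qc.reasons.append("no gamma-phosphate moiety or mimic")

    beta = site.ligand.beta_oxygens()
    if annotation.lys_wa is not None and beta:
        nz = annotation.lys_wa.atom("NZ")
        if nz is not None:
            d = min(nz.distance(a) for a in beta)
            qc.lys_beta_distance = round(d, 2)
            qc.lys_near_beta = d <= config.lys_beta_max
    if not qc.lys_near_beta:
        qc.reasons.append("no P-loop Lys within cutoff of beta-phosphate")

    ion_atom = site.ion.atoms[0] if (site.ion is not None and site.ion.atoms) else None
    if ion_atom is None:
        qc.reasons.append("no cofactor ion")
    else:
        oh = hydroxyl_oxygen(annotation.k_plus_1) if annotation.k_plus_1 is not None else None
        if oh is None:
            qc.reasons.append("K+1 lacks a side-chain hydroxyl")
        else:
            qc.k1_mg_distance = round(oh.distance(ion_atom), 2)
            qc.k1_mg_ok = qc.k1_mg_distance <= config.k1_mg_max
            if not qc.k1_mg_ok:
                qc.reasons.append("K+1 hydroxyl too far from ion")
        if annotation.wb_residue is not None:
            oxy = carboxylate_oxygens(annotation.wb_residue)
            if oxy:
                d = min(o.distance(ion_atom) for o in oxy)
                qc.mg_wb_distance = round(d, 2)
                qc.mg_wb_ok = d <= config.mg_wb_max
                if not qc.mg_wb_ok:
                    qc.reasons.append("ion too far from Walker-B carboxylate")
        else:
            qc.reasons.append("no Walker-B residue")
    return qc
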