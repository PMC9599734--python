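"""Geometric identification of the catalytically relevant residues.

Identification is sequence-agnostic by design: the conserved residues are
found from the coordinates of the bound Mg-NTP moiety, not from sequence
motifs.

* **Walker-A Lys (LysWA)** — the lysine whose NZ is nearest to (and within
  5 Å of) any β-phosphate oxygen. The residue immediately after it is
  **K+1** (normally Ser/Thr, whose hydroxyl is Mg²⁺ ligand #4; flagged
  when it is something else, e.g. Gly in adenylate kinases), and the
  residue three before it is **K−3** (whose backbone amide contacts the
  bridging O3B and, in transition-state-like structures, O2G).
* **Walker-B Asp/Glu (AspWB)** — among the Asp/Glu whose carboxylate comes
  within 5 Å of the K+1 hydroxyl, the nearest one preceded by three
  non-ionizable residues (the *hhhh*D signature); when no candidate has a
  non-ionizable window the plain nearest is used with a fallback flag.
* **Switch-I Thr/Ser** — a second Ser/Thr whose side-chain O occupies a
  Mg²⁺ shell position (ligand #3, TRAFAC class); absent when water takes
  that position.
* **W_cat** — the catalytic water: apical to the O3B–PG axis (angle
  O3B–X–Ow ≥ 140°, Ow within 2–4 Å of the γ central atom X); in vanadate
  complexes the apical vanadate oxygen itself occupies W_cat's position
  and is returned as a surrogate.
* Polar atoms within 3.6 Å of W_cat are inventoried; the nearest Asp/Glu
  carboxylate among them is the "catalytic" carboxylate that links W_cat
  to the Mg²⁺ shell in most non-TRAFAC classes.

Ties anywhere break deterministically by (chain ID, residue number,
atom name).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .config import DEFAULT_CONFIG, PipelineConfig
from .geometry import angle_at, carboxylate_oxygens, hydroxyl_oxygen
from .model import AtomRecord, Residue, StructureModel
from .sites import CatalyticSite

#: residues excluded from the Walker-B preceding window (ionizable side chains)
IONIZABLE = frozenset({"GLU", "ASP", "SER", "THR", "TYR", "LYS", "ARG", "HIS"})


@dataclass
class MotifAnnotation:
    lys_wa: Optional[Residue] = None
    k_plus_1: Optional[Residue] = None
    k_minus_3: Optional[Residue] = None
    wb_residue: Optional[Residue] = None
    wb_fallback_used: bool = False
    wb_distance: Optional[float] = None
    switch_i: Optional[Residue] = None
    wcat: Optional[Residue] = None
    wcat_atom: Optional[AtomRecord] = None
    wcat_is_surrogate: bool = False
    catalytic_carboxylate: Optional[Residue] = None
    wcat_ligands: list[tuple[Residue, str, float]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def find_walker_a(
    site: CatalyticSite, model: StructureModel, config: PipelineConfig = DEFAULT_CONFIG
) -> Optional[tuple[Residue, Optional[Residue], Optional[Residue], list[str]]]:
    """Locate (LysWA, K+1, K−3) from proximity of Lys NZ to the β-phosphate.

    Returns None when no lysine NZ lies within ``config.lys_beta_max`` of
    a β-phosphate oxygen (the site is then rejected as "no P-loop Lys").
    The last tuple element lists warnings (e.g. a non-Ser/Thr K+1).
    """
    beta = site.ligand.beta_oxygens()
    if not beta:
        return None
    best: tuple[float, tuple, Residue] | None = None
    for res in model.polymer_residues():
        if res.res_name != "LYS":
            continue
        nz = res.atom("NZ")
        if nz is None:
            continue
        d = min(nz.distance(a) for a in beta)
        if d <= config.lys_beta_max:
            key = (d, res.key())
            if best is None or key < (best[0], best[1]):
                best = (d, res.key(), res)
    if best is None:
        return None
    lys = best[2]
    warnings: list[str] = []
    k_plus_1 = model.following_residue(lys)
    if k_plus_1 is None:
        warnings.append("chain ends at LysWA; no K+1 residue")
    elif k_plus_1.res_name not in ("SER", "THR"):
        warnings.append(f"K+1 is {k_plus_1.res_name}, not Ser/Thr")
    chain = model.chain(lys.chain_id)
    i = model.residue_index(lys)
    k_minus_3 = chain[i - 3] if i >= 3 else None
    if k_minus_3 is None:
        warnings.append("chain too short for a K-3 residue")
    return lys, k_plus_1, k_minus_3, warnings


def find_walker_b(
    k_plus_1: Residue,
    model: StructureModel,
    config: PipelineConfig = DEFAULT_CONFIG,
    ionizable: frozenset[str] = IONIZABLE,
) -> tuple[Optional[Residue], bool, Optional[float]]:
    """Identify the Walker-B Asp/Glu H-bonded to the K+1 hydroxyl.

    Candidates are Asp/Glu in K+1's own chain whose nearest carboxylate
    oxygen is within ``config.wb_search_max`` of the K+1 hydroxyl oxygen.
    The primary rule picks the nearest candidate whose three N-terminal
    neighbours (i−1..i−3) are all non-ionizable; if none qualifies the
    nearest candidate is returned with the fallback flag set; with an empty
    candidate set the residue is absent at the threshold distance.

    Returns ``(residue or None, fallback_used, distance)``.
    """
    oh = hydroxyl_oxygen(k_plus_1)
    if oh is None:
        return None, False, None

    candidates: list[tuple[float, tuple, Residue]] = []
    for res in model.chain(k_plus_1.chain_id):
        if res.res_name not in ("ASP", "GLU") or res.key() == k_plus_1.key():
            continue
        oxy = carboxylate_oxygens(res)
        if not oxy:
            continue
        d = min(o.distance(oh) for o in oxy)
        if d <= config.wb_search_max:
            candidates.append((d, res.key(), res))
    if not candidates:
        return None, False, None
    candidates.sort()

    def window_ok(res: Residue) -> bool:
        preceding = model.preceding_residues(res, 3)
        return len(preceding) == 3 and all(r.res_name not in ionizable for r in preceding)

    for d, _, res in candidates:
        if window_ok(res):
            return res, False, round(d, 2)
    d, _, res = candidates[0]
    return res, True, round(d, 2)


def find_switch_i(site: CatalyticSite, annotation: MotifAnnotation, shell) -> Optional[Residue]:
    """The Ser/Thr (other than K+1) whose side-chain O is a Mg²⁺ shell ligand."""
    k1_key = annotation.k_plus_1.key() if annotation.k_plus_1 is not None else None
    hits = []
    for lig in shell.ligands:
        res = lig.residue
        if res.res_name in ("SER", "THR") and not res.is_hetero and res.key() != k1_key \
                and lig.atom.atom_name in ("OG", "OG1"):
            hits.append(res)
    hits.sort(key=lambda r: r.key())
    return hits[0] if hits else None


def find_wcat(
    site: CatalyticSite, model: StructureModel, config: PipelineConfig = DEFAULT_CONFIG
) -> tuple[Optional[Residue], Optional[AtomRecord], bool]:
    """The apical catalytic water (or the vanadate oxygen standing in for it).

    Among water oxygens at 2–4 Å from the γ central atom X, the one
    maximising the O3B–X–Ow angle is returned, provided the angle is at
    least ``config.wcat_angle_min``. For vanadate the apical oxygen of
    VO4³⁻ itself occupies W_cat's position and is returned with the
    surrogate flag.

    Returns ``(residue, oxygen atom, is_surrogate)``.
    """
    center = site.ligand.gamma_center_atom()
    o3b = site.ligand.o3b()
    if center is None or o3b is None:
        return None, None, False

    if site.ligand.mimic_species == "VO4":
        mimic = site.ligand.mimic_residue
        best, best_angle = None, -1.0
        for atom in site.ligand.gamma_peripheral_atoms():
            ang = angle_at(center.coords, o3b.coords, atom.coords)
            if ang > best_angle:
                best, best_angle = atom, ang
        if best is not None:
            return mimic, best, True
        return None, None, False

    best_res, best_atom, best_angle = None, None, -1.0
    for water in model.waters:
        ow = water.atom("O")
        if ow is None:
            continue
        d = ow.distance(center)
        if not (config.wcat_dist_min <= d <= config.wcat_dist_max):
            continue
        ang = angle_at(center.coords, o3b.coords, ow.coords)
        if ang >= config.wcat_angle_min and (
            ang > best_angle or (math.isclose(ang, best_angle) and water.key() < best_res.key())
        ):
            best_res, best_atom, best_angle = water, ow, ang
    return best_res, best_atom, False


def wcat_polar_contacts(
    wcat_atom: AtomRecord,
    site: CatalyticSite,
    model: StructureModel,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[list[tuple[Residue, str, float]], Optional[Residue]]:
    """Polar (N/O) atoms within 3.6 Å of W_cat, and the catalytic carboxylate.

    The γ-moiety itself (and its nucleotide) is excluded. Returns the
    distance-sorted contact list and the Asp/Glu whose carboxylate oxygen
    is nearest among the contacts (None when no carboxylate is in range).
    """
    excluded_keys = {site.ligand.residue.key()}
    if site.ligand.mimic_residue is not None:
        excluded_keys.add(site.ligand.mimic_residue.key())

    contacts: list[tuple[Residue, str, float]] = []
    for res in model.all_residues():
        if res.key() in excluded_keys:
            continue
        for atom in res.atoms:
            if atom is wcat_atom or atom.element not in ("N", "O"):
                continue
            d = atom.distance(wcat_atom)
            if d <= config.polar_contact_max:
                contacts.append((res, atom.atom_name, round(d, 2)))
    contacts.sort(key=lambda c: (c[2], c[0].key(), c[1]))

    carboxylate: Optional[Residue] = None
    for res, atom_name, _ in contacts:
        if res.res_name in ("ASP", "GLU") and atom_name in ("OD1", "OD2", "OE1", "OE2"):
            carboxylate = res
            break
    return contacts, carboxylate


def annotate_site(
    site: CatalyticSite, model: StructureModel, config: PipelineConfig = DEFAULT_CONFIG
) -> MotifAnnotation:
    """Run the full residue-identification cascade for one site.

    Walker-A first (rejecting the site when no P-loop Lys is found), then
    Walker-B from the K+1 hydroxyl. Shell-dependent annotations (Switch I)
    are filled in by the pipeline once the shell is computed.
    """
    ann = MotifAnnotation()
    wa = find_walker_a(site, model, config)
    if wa is None:
        site.reject_reason = "no P-loop Lys"
        return ann
    ann.lys_wa, ann.k_plus_1, ann.k_minus_3, warnings = wa
    ann.warnings.extend(warnings)

    if ann.k_plus_1 is not None:
        ann.wb_residue, ann.wb_fallback_used, ann.wb_distance = find_walker_b(
            ann.k_plus_1, model, config
        )
        if ann.wb_residue is None and hydroxyl_oxygen(ann.k_plus_1) is None:
            ann.warnings.append("K+1 lacks a hydroxyl; Walker-B search skipped")

    wcat_res, wcat_atom, surrogate = find_wcat(site, model, config)
    ann.wcat, ann.wcat_atom, ann.wcat_is_surrogate = wcat_res, wcat_atom, surrogate
    if wcat_atom is not None:
        ann.wcat_ligands, ann.catalytic_carboxylate = wcat_polar_contacts(
            wcat_atom, site, model, config
        )
    return ann
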