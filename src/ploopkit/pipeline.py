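"""End-to-end survey pipeline: structure file(s) → per-site records.

For each structure the pipeline finds candidate nucleotide sites,
classifies the bound species, locates the cofactor ion, annotates the
Walker-A/Walker-B/Switch-I residues and the catalytic water, applies the
integrity QC, measures the diagnostic distances and the Mg²⁺ shell, and
(optionally) computes the Walker-B aspartate's relative SASA. Accepted
sites become rows of the survey table; every rejected candidate is logged
with a machine-readable reason, so accepted + rejected = candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from . import sasa as sasa_mod
from .config import DEFAULT_CONFIG, PipelineConfig
from .geometry import (
    MgShell,
    SiteRecord,
    classify_hbond,
    delta_pka_estimate,
    hnk3_gamma_distance,
    mg_coordination_shell,
    wb_k1_distance,
)
from .io import read_structure
from .model import StructureModel
from .motifs import MotifAnnotation, annotate_site, find_switch_i
from .sites import CatalyticSite, classify_ligand, find_cofactor_ion, find_nucleotide_sites, qc_site

log = logging.getLogger("ploopkit")


@dataclass
class SiteResult:
    """Everything the pipeline derived for one candidate site."""

    site: CatalyticSite
    annotation: Optional[MotifAnnotation] = None
    shell: Optional[MgShell] = None
    record: Optional[SiteRecord] = None
    reject_reason: Optional[str] = None


def analyze_site(
    site: CatalyticSite,
    model: StructureModel,
    config: PipelineConfig = DEFAULT_CONFIG,
    compute_sasa: bool = True,
) -> SiteResult:
    """Annotate and measure one candidate site."""
    result = SiteResult(site=site)
    if site.reject_reason is not None:
        result.reject_reason = site.reject_reason
        return result

    site.ligand_class = classify_ligand(site, config)
    site.ion = find_cofactor_ion(model, site, config)

    ann = annotate_site(site, model, config)
    result.annotation = ann
    if site.reject_reason is not None:  # no P-loop Lys
        result.reject_reason = site.reject_reason
        return result

    site.qc = qc_site(site, ann, config)

    shell = None
    if site.ion is not None:
        shell = mg_coordination_shell(site, model, ann, config)
        ann.switch_i = find_switch_i(site, ann, shell)
    result.shell = shell

    d_wb = wb_k1_distance(ann)
    rec = SiteRecord(
        structure_id=model.id,
        chain=site.chain_id,
        site_label=site.label,
        ligand_class=site.ligand_class or "ndp_only",
        resolution=model.resolution,
        lys_wa=ann.lys_wa.label if ann.lys_wa else None,
        k_plus_1=ann.k_plus_1.label if ann.k_plus_1 else None,
        k_minus_3=ann.k_minus_3.label if ann.k_minus_3 else None,
        wb_residue=ann.wb_residue.label if ann.wb_residue else None,
        wb_fallback_used=ann.wb_fallback_used,
        wb_k1_distance=d_wb,
        hbond_class=classify_hbond(d_wb) if d_wb else None,
        delta_pka=round(delta_pka_estimate(d_wb), 2) if d_wb else None,
        hnk3_o2g_distance=hnk3_gamma_distance(ann, site),
        k1_mg_distance=site.qc.k1_mg_distance,
        mg_wb_distance=site.qc.mg_wb_distance,
        shell_edge_mean=round(shell.edge_mean, 3) if shell and shell.edge_mean else None,
        shell_complete=shell.complete if shell else None,
        switch_i=ann.switch_i.label if ann.switch_i else None,
        wcat=ann.wcat.label if ann.wcat else None,
        catalytic_carboxylate=(
            ann.catalytic_carboxylate.label if ann.catalytic_carboxylate else None),
        qc_all_pass=site.qc.all_pass,
        warnings="; ".join(ann.warnings + site.qc.reasons),
    )
    if compute_sasa and ann.wb_residue is not None:
        try:
            rec.asp_wb_rel_sasa = round(sasa_mod.relative_sasa(model, ann.wb_residue), 2)
        except ValueError as exc:
            log.warning("%s: relative SASA unavailable: %s", site.label, exc)
    result.record = rec
    return result


def process_structure(
    model: StructureModel,
    config: PipelineConfig = DEFAULT_CONFIG,
    compute_sasa: bool = True,
) -> list[SiteResult]:
    sites = find_nucleotide_sites(model, config)
    return [analyze_site(s, model, config, compute_sasa) for s in sites]


def scan(
    paths: Sequence[str | Path],
    config: PipelineConfig = DEFAULT_CONFIG,
    compute_sasa: bool = True,
) -> tuple[list[SiteRecord], list[dict]]:
    """Process many files; returns (accepted records, reject log entries).

    A candidate is accepted when it has a cofactor ion, passes all QC
    criteria and belongs to one of the four ligand classes; everything
    else lands in the reject log with a reason code.
    """
    records: list[SiteRecord] = []
    rejects: list[dict] = []
    for path in paths:
        model = read_structure(path)
        for result in process_structure(model, config, compute_sasa):
            site = result.site
            if result.reject_reason is not None:
                rejects.append({"structure_id": model.id, "site": site.label,
                                "reason": result.reject_reason})
                log.info("reject %s %s: %s", model.id, site.label, result.reject_reason)
            elif site.accepted:
                records.append(result.record)
            else:
                reason = (site.ligand_class if site.ligand_class not in
                          ("native", "non_hydrolyzable", "substrate_analog", "ts_analog")
                          else "qc_fail:" + ",".join(site.qc.reasons if site.qc else []))
                rejects.append({"structure_id": model.id, "site": site.label,
                                "reason": reason})
                log.info("exclude %s %s: %s", model.id, site.label, reason)
    return records, rejects


def annotation_report(model: StructureModel, config: PipelineConfig = DEFAULT_CONFIG) -> dict:
    """Human-readable JSON-serialisable report for a single structure."""
    results = process_structure(model, config)
    sites = []
    for r in results:
        entry: dict = {"site": r.site.label, "ligand_class": r.site.ligand_class}
        if r.reject_reason:
            entry["rejected"] = r.reject_reason
        if r.annotation is not None:
            ann = r.annotation
            entry["annotation"] = {
                "lys_wa": ann.lys_wa.label if ann.lys_wa else None,
                "k_plus_1": ann.k_plus_1.label if ann.k_plus_1 else None,
                "k_minus_3": ann.k_minus_3.label if ann.k_minus_3 else None,
                "wb_residue": ann.wb_residue.label if ann.wb_residue else None,
                "wb_fallback_used": ann.wb_fallback_used,
                "switch_i": ann.switch_i.label if ann.switch_i else None,
                "wcat": ann.wcat.label if ann.wcat else None,
                "wcat_is_surrogate": ann.wcat_is_surrogate,
                "catalytic_carboxylate": (ann.catalytic_carboxylate.label
                                          if ann.catalytic_carboxylate else None),
                "wcat_contacts": [
                    {"residue": res.label, "atom": name, "distance": d}
                    for res, name, d in ann.wcat_ligands
                ],
                "warnings": ann.warnings,
            }
        if r.shell is not None:
            entry["mg_shell"] = {
                "complete": r.shell.complete,
                "edge_mean": r.shell.edge_mean,
                "k1_trans_to_gamma": r.shell.k1_trans_to_gamma,
                "ligands": [
                    {"position": lig.position, "residue": lig.residue.label,
                     "atom": lig.atom.atom_name, "distance": lig.distance}
                    for lig in r.shell.ligands
                ],
            }
        if r.site.qc is not None:
            entry["qc"] = {
                "all_pass": r.site.qc.all_pass,
                "lys_near_beta": r.site.qc.lys_near_beta,
                "gamma_moiety_present": r.site.qc.gamma_moiety_present,
                "k1_mg_ok": r.site.qc.k1_mg_ok,
                "mg_wb_ok": r.site.qc.mg_wb_ok,
                "reasons": r.site.qc.reasons,
            }
        if r.record is not None:
            entry["measurements"] = {
                k: v for k, v in r.record.as_dict().items()
                if k.endswith("distance") or k in
                ("hbond_class", "delta_pka", "shell_edge_mean", "asp_wb_rel_sasa")
            }
        sites.append(entry)
    return {"structure_id": model.id, "resolution": model.resolution, "sites": sites}
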