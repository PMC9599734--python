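"""Reading and writing structures and tabular outputs.

Parsing of PDB and mmCIF files is delegated to gemmi; this module reduces
whatever gemmi returns to the single-conformer, heavy-atom-only
:class:`~ploopkit.model.StructureModel` that the rest of the pipeline
consumes:

* only the first model of multi-model entries is kept (single-conformer
  crystal analysis);
* hydrogens and deuteriums are dropped — the corpus is X-ray structures
  where H positions are generally absent, so every measured distance is a
  heavy-atom distance;
* for atoms with alternate locations exactly one conformer is retained:
  the highest occupancy, ties broken by the alphabetically first altloc
  code (deterministic by construction);
* waters (HOH/WAT/DOD) are collected separately and normalised to HOH.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

from .model import WATER_NAMES, AtomRecord, Residue, StructureModel


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class EmptyStructureError(ValueError):
    """Raised when a parsed file contains no polymer atoms."""


_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "cif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Parameters
    ----------
    path:
        Coordinate file. Gzipped files are handled by gemmi transparently.
    format:
        ``"pdb"``, ``"mmcif"`` or ``"auto"`` (detect from extension/content).

    Notes
    -----
    The structure id is the file stem (the PDB-archive convention); the
    4-character HEADER idCode cannot hold the longer ids used for
    synthetic structures.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected pdb, mmcif or auto")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path.name}: {exc}") from exc
    return structure_from_gemmi(st)


def structure_from_gemmi(st: gemmi.Structure) -> StructureModel:
    """Reduce a gemmi Structure to the pipeline's single-model heavy-atom view."""
    model = StructureModel(id=st.name.strip() or "UNNAMED")
    if st.resolution and st.resolution > 0:
        model.resolution = float(st.resolution)
    if len(st) == 0:
        raise EmptyStructureError(f"{model.id}: structure contains no models")
    gm = st[0]  # first model only
    for chain in gm:
        for gres in chain:
            res = _convert_residue(chain.name, gres)
            if res is None:
                continue
            if res.res_name in WATER_NAMES:
                res.res_name = "HOH"
                model.waters.append(res)
            elif res.is_hetero:
                model.hetero.append(res)
            else:
                model.chains.setdefault(chain.name, []).append(res)
    if not any(model.polymer_residues()):
        raise EmptyStructureError(f"{model.id}: no polymer atoms after filtering")
    return model


def _convert_residue(chain_id: str, gres: gemmi.Residue) -> Residue | None:
    chosen: dict[str, gemmi.Atom] = {}
    for atom in gres:
        if atom.element.is_hydrogen:
            continue
        prev = chosen.get(atom.name)
        if prev is None:
            chosen[atom.name] = atom
        else:
            # altloc policy: highest occupancy wins, ties to the
            # alphabetically first altloc code
            better = atom.occ > prev.occ or (
                atom.occ == prev.occ and _altloc_rank(atom) < _altloc_rank(prev)
            )
            if better:
                chosen[atom.name] = atom
    if not chosen:
        return None
    het = gres.het_flag == "H" or gres.is_water()
    atoms = [
        AtomRecord(
            atom_name=a.name,
            element=a.element.name.upper(),
            coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
            occupancy=min(max(a.occ, 0.0), 1.0),
            altloc=a.altloc.strip("\x00 "),
            is_hetero=het,
        )
        for a in chosen.values()
    ]
    icode = gres.seqid.icode.strip()
    return Residue(chain_id, gres.seqid.num, gres.name, atoms, icode, het)


def _altloc_rank(atom: gemmi.Atom) -> str:
    # '' (no altloc) sorts before 'A'; rank used inverted in the max() above
    return atom.altloc.strip("\x00 ") or ""


def structure_to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.id
    if model.resolution:
        st.resolution = model.resolution
    gm = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}

    def _chain(cid: str) -> gemmi.Chain:
        if cid not in chain_map:
            chain_map[cid] = gemmi.Chain(cid)
        return chain_map[cid]

    for res in model.all_residues():
        gres = gemmi.Residue()
        gres.name = res.res_name
        gres.seqid = gemmi.SeqId(res.auth_seq_num, res.insertion_code or " ")
        gres.het_flag = "H" if (res.is_hetero or res.res_name == "HOH") else "A"
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.atom_name
            ga.element = gemmi.Element(a.element.capitalize())
            ga.pos = gemmi.Position(*a.coords)
            ga.occ = a.occupancy
            if a.altloc:
                ga.altloc = a.altloc
            gres.add_atom(ga)
        _chain(res.chain_id).add_residue(gres)
    for ch in chain_map.values():
        gm.add_chain(ch)
    st.add_model(gm)
    return st


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as a PDB file (via gemmi)."""
    structure_to_gemmi(model).write_pdb(str(path))


def fetch_structure(pdb_id: str, dest_dir: str | Path = ".") -> Path:
    """Download a PDB entry from RCSB (requires network access).

    Convenience for reproducing single-accession worked examples; the
    analysis pipeline itself only ever consumes local files.
    """
    import urllib.request

    pdb_id = pdb_id.lower()
    dest = Path(dest_dir) / f"{pdb_id}.pdb"
    if not dest.exists():
        url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
        urllib.request.urlretrieve(url, dest)
    return dest


# ---------------------------------------------------------------------------
# Tabular output

#: Fixed column schema of the per-site table. Missing measurements are "NA".
SITE_RECORD_COLUMNS = [
    "structure_id",
    "chain",
    "site_label",
    "ligand_class",
    "resolution",
    "lys_wa",
    "k_plus_1",
    "k_minus_3",
    "wb_residue",
    "wb_fallback_used",
    "wb_k1_distance",
    "hbond_class",
    "delta_pka",
    "hnk3_o2g_distance",
    "k1_mg_distance",
    "mg_wb_distance",
    "shell_edge_mean",
    "shell_complete",
    "asp_wb_rel_sasa",
    "switch_i",
    "wcat",
    "catalytic_carboxylate",
    "qc_all_pass",
    "warnings",
]


def site_records_frame(records: Iterable) -> pd.DataFrame:
    """Site records (dataclasses or dicts) as a DataFrame with the fixed schema."""
    rows = []
    for rec in records:
        d = rec if isinstance(rec, dict) else rec.as_dict()
        rows.append({col: d.get(col) for col in SITE_RECORD_COLUMNS})
    return pd.DataFrame(rows, columns=SITE_RECORD_COLUMNS)


def write_site_records(records: Sequence, path: str | Path) -> None:
    """Write site records as a tab-separated table, one header row, NA for missing."""
    df = site_records_frame(records)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.4g")


def read_site_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_annotation_json(report: dict, path: str | Path) -> None:
    """Single-structure annotation report as JSON."""
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Residue):
        return obj.label
    raise TypeError(f"not JSON serialisable: {type(obj)}")
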