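"""Shrake–Rupley solvent-accessible surface area.

The classic rolling-probe construction: each atom's van der Waals sphere
is expanded by the probe radius (water, 1.4 Å by default) and sampled with
test points; a point is accessible iff it lies strictly outside every
other atom's expanded sphere, and the atom's SASA is the accessible
fraction of its expanded-sphere area, (exposed / n_points) · 4π(r+probe)².

Test points come from a golden-spiral quadrature rather than random
sampling, so results are bit-reproducible and seed-independent at fixed
``n_points`` (a ``seed`` argument is accepted for interface compatibility
and ignored). 960 points per atom gives single-atom areas accurate to well
under 1%.

Relative SASA of a residue is its heavy-atom SASA as a percentage of a
per-residue-type maximum-accessibility reference (theoretical Gly-X-Gly
maxima); values below ~6% indicate a buried residue. Whole-residue maxima
are used (rather than side-chain-only); this is a documented normalisation
choice.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .model import Residue, StructureModel

#: van der Waals radii (Å) per element; configurable via the functions' ``radii``.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "MG": 1.73, "F": 1.47, "AL": 1.84, "V": 2.00,
    "BE": 1.53, "MN": 1.61, "CA": 2.31, "NA": 2.27, "K": 2.75,
    "CL": 1.75, "ZN": 1.39, "FE": 1.52, "SE": 1.90, "BR": 1.85, "I": 1.98,
}

#: theoretical maximum accessible surface areas (Å², whole residue, Gly-X-Gly)
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

DEFAULT_N_POINTS = 960
DEFAULT_PROBE = 1.4


def golden_spiral_points(n: int) -> np.ndarray:
    """n near-uniform unit-sphere directions (deterministic)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    theta = np.pi * (3.0 - np.sqrt(5.0)) * i
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _gather_atoms(model: StructureModel, radii: dict[str, float]):
    atoms, centers, rads = [], [], []
    for res, atom in model.all_atoms():
        r = radii.get(atom.element.upper())
        if r is None:
            raise ValueError(
                f"no van der Waals radius for element {atom.element!r} "
                f"(atom {atom.atom_name} in {res.label})"
            )
        atoms.append((res, atom))
        centers.append(atom.coords)
        rads.append(r)
    return atoms, np.asarray(centers, float), np.asarray(rads, float)


def shrake_rupley(
    model: StructureModel,
    n_points: int = DEFAULT_N_POINTS,
    probe: float = DEFAULT_PROBE,
    seed: Optional[int] = None,
    radii: dict[str, float] = VDW_RADII,
) -> dict[tuple, float]:
    """Per-atom SASA (Å²) for every heavy atom of the model.

    Returns a dict keyed by ``(chain_id, auth_seq_num, insertion_code,
    atom_name)``. ``seed`` is ignored: the golden-spiral quadrature is
    deterministic.
    """
    if n_points < 100:
        raise ValueError("n_points must be at least 100")
    del seed  # deterministic quadrature; accepted for interface compatibility
    atoms, centers, rads = _gather_atoms(model, radii)
    if not atoms:
        return {}
    expanded = rads + probe
    sphere = golden_spiral_points(n_points)
    tree = cKDTree(centers)
    max_expanded = expanded.max()

    areas: dict[tuple, float] = {}
    for i, (res, atom) in enumerate(atoms):
        ri = expanded[i]
        pts = centers[i] + ri * sphere
        neighbor_idx = [j for j in tree.query_ball_point(centers[i], ri + max_expanded)
                        if j != i]
        if neighbor_idx:
            nb_centers = centers[neighbor_idx]
            nb_r = expanded[neighbor_idx]
            # keep only neighbours whose expanded sphere can reach the test shell
            reach = np.linalg.norm(nb_centers - centers[i], axis=1) < ri + nb_r
            nb_centers, nb_r = nb_centers[reach], nb_r[reach]
        else:
            nb_centers = np.empty((0, 3))
            nb_r = np.empty(0)
        if len(nb_centers):
            d2 = np.sum((pts[:, None, :] - nb_centers[None, :, :]) ** 2, axis=-1)
            buried = np.any(d2 <= (nb_r**2)[None, :], axis=1)
            exposed = int(np.count_nonzero(~buried))
        else:
            exposed = n_points
        area = exposed / n_points * 4.0 * np.pi * ri * ri
        areas[(res.chain_id, res.auth_seq_num, res.insertion_code, atom.atom_name)] = float(area)
    return areas


def residue_sasa(
    model: StructureModel,
    residue: Residue,
    n_points: int = DEFAULT_N_POINTS,
    probe: float = DEFAULT_PROBE,
    radii: dict[str, float] = VDW_RADII,
) -> float:
    """Total heavy-atom SASA (Å²) of one residue in the context of the model."""
    areas = shrake_rupley(model, n_points=n_points, probe=probe, radii=radii)
    key = residue.key()
    return sum(
        a for (cid, num, icode, _), a in areas.items() if (cid, num, icode) == key
    )


def relative_sasa(
    model: StructureModel,
    residue: Residue,
    n_points: int = DEFAULT_N_POINTS,
    probe: float = DEFAULT_PROBE,
    reference: dict[str, float] = MAX_ASA,
    radii: dict[str, float] = VDW_RADII,
) -> float:
    """Residue SASA as % of its residue-type maximum-accessibility reference.

    May exceed 100 for unusual conformers (callers should flag, not clip).
    """
    ref = reference.get(residue.res_name)
    if ref is None:
        raise ValueError(f"no reference maximum ASA for residue type {residue.res_name!r}")
    total = residue_sasa(model, residue, n_points=n_points, probe=probe, radii=radii)
    return 100.0 * total / ref
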