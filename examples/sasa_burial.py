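"""Relative SASA of the Walker-B aspartate: exposed vs buried.

A small synthetic site leaves the Walker-B Asp partly exposed; enclosing
it in a tight pocket of fixture atoms drives its relative SASA below the
6% burial mark that real transition-state-like structures show.
"""

import numpy as np

from ploopkit import relative_sasa
from ploopkit.model import AtomRecord, Residue, StructureModel
from ploopkit.sasa import golden_spiral_points
from ploopkit.synth import SiteBlueprint, build_ideal_site

model, truth = build_ideal_site(SiteBlueprint())
wb = next(r for r in model.chains["A"] if r.auth_seq_num == truth.wb_num)

open_site = relative_sasa(model, wb)
print(f"WB Asp relative SASA in the open synthetic site : {open_site:6.2f} %")

center = np.mean([a.coords for a in wb.atoms], axis=0)
pocket = Residue("P", 1, "UNK", [
    AtomRecord(f"C{i}", "C", p, is_hetero=True)
    for i, p in enumerate(4.5 * golden_spiral_points(250) + center)], "", True)
closed = StructureModel(id="CLOSED")
closed.chains["A"] = [wb]
closed.hetero = [pocket]
buried = relative_sasa(closed, wb)
print(f"WB Asp relative SASA inside a closed pocket     : {buried:6.2f} %")
print(f"buried below the 6% mark: {buried < 6.0}")

# Burial matters mechanistically: a desolvated AspWB in a nonpolar pocket
# has an elevated proton affinity, which is what lets the short AspWB-K+1
# H-bond act as a proton acceptor.
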