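import numpy as np
import pytest

from ploopkit.model import AtomRecord, Residue, StructureModel
from ploopkit.pipeline import process_structure
from ploopkit.synth import SiteBlueprint, build_ideal_site


@pytest.fixture(scope="session")
def ideal():
    """Default ideal synthetic site (ATP, Mg, no jitter) and its truth."""
    return build_ideal_site(SiteBlueprint())


@pytest.fixture(scope="session")
def ideal_result(ideal):
    model, truth = ideal
    results = process_structure(model)
    assert len(results) == 1
    return model, truth, results[0]


@pytest.fixture()
def alf4_site():
    bp = SiteBlueprint(gamma_moiety="ALF4", include_wcat=True)
    return build_ideal_site(bp)


def make_residue(chain, num, name, atom_specs, hetero=False):
    atoms = [AtomRecord(an, el, np.asarray(xyz, float), is_hetero=hetero)
             for an, el, xyz in atom_specs]
    return Residue(chain, num, name, atoms, "", hetero)


def single_residue_model(res, model_id="T"):
    m = StructureModel(id=model_id)
    if res.is_hetero:
        m.chains["A"] = [make_residue("A", 1, "GLY", [("CA", "C", (50, 50, 50))])]
        m.hetero = [res]
    else:
        m.chains[res.chain_id] = [res]
    return m


@pytest.fixture()
def rotation():
    """A proper rotation (det=+1) and translation for invariance tests."""
    theta = 0.7
    rz = np.array([[np.cos(theta), -np.sin(theta), 0],
                   [np.sin(theta), np.cos(theta), 0],
                   [0, 0, 1.0]])
    rx = np.array([[1.0, 0, 0],
                   [0, np.cos(0.4), -np.sin(0.4)],
                   [0, np.sin(0.4), np.cos(0.4)]])
    return rz @ rx, np.array([12.0, -7.0, 3.0])
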