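import numpy as np
import pytest

from astatools.structure import Atom, StructureModel
from astatools import synthetic


def make_model(coords, radius=1.7, element="C", model_id=1,
               resnums=None) -> StructureModel:
    """Bare pseudo-atom model for geometric tests (one atom per residue).
    ``radius`` may be a scalar or a per-atom sequence."""
    coords = np.asarray(coords, dtype=float)
    radii = np.broadcast_to(np.asarray(radius, dtype=float), len(coords))
    atoms = []
    for i, pos in enumerate(coords):
        atoms.append(Atom(serial=i + 1, name="CA", element=element,
                          residue_name="ALA", chain_id="A",
                          residue_number=(resnums[i] if resnums is not None
                                          else i + 1),
                          insertion_code="", position=pos,
                          vdw_radius=float(radii[i])))
    return StructureModel(model_id, atoms)


@pytest.fixture(scope="session")
def tunnel_single():
    spec = synthetic.TunnelComplexSpec(seed=1)
    ensemble, contacts = synthetic.make_tunnel_complex(spec)
    return spec, ensemble, contacts


@pytest.fixture(scope="session")
def tunnel_ensemble():
    spec = synthetic.TunnelComplexSpec(seed=1, n_models=10)
    ensemble, contacts = synthetic.make_tunnel_complex(spec)
    return spec, ensemble, contacts


@pytest.fixture(scope="session")
def planted_msas():
    spec = synthetic.PlantedMSASpec(
        n_group=10, n_family=150, seed=2,
        categories=("both_conserved", "variable_in_both", "group_specific",
                    "fas1_only", "both_conserved", "group_specific",
                    "variable_in_both"))
    return synthetic.make_grouped_msas(spec)
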