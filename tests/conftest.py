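"""Shared fixtures: small synthetic systems built once per session."""
import numpy as np
import pytest

import dnacage as dc


@pytest.fixture(scope="session")
def bdna22():
    """Straight fiber-model duplex with the studied 22-mer sequence."""
    return dc.build_bdna(dc.DD_SEQUENCE)


@pytest.fixture(scope="session")
def dd20_bundle():
    """Assembled DD-20A system + ground truth + pseudo-trajectory."""
    spec = dc.SystemSpec.dd(20.0)
    system, states0 = dc.assemble_two_duplex_system(
        spec, fraction_caged=0.4, seed=11, folded_fraction=0.2
    )
    dyn = dc.DynamicsSpec(p_enter=0.1, p_exit=0.1, noise_sigma=0.8,
                          n_frames=21, frame_dt=25.0, seed=12)
    traj, truth = dc.generate_trajectory(system, dyn, initial_states=states0)
    return {
        "spec": spec,
        "system": system,
        "states0": states0,
        "traj": traj,
        "truth": truth,
        "crit": dc.CageCriterion.for_system("dd20"),
    }


@pytest.fixture(scope="session")
def superhelix_mod():
    return dc.build_superhelix(dc.SuperhelixSpec())


@pytest.fixture(scope="session")
def superhelix_flat():
    return dc.build_superhelix(dc.SuperhelixSpec(modulation_amplitude=0.0))


def make_point_system(points, box=None):
    """System of bare labelled points for RDF fixtures."""
    from dnacage.model import AtomRecord, MolecularSystem

    atoms = [
        AtomRecord(i + 1, "X", "UNK", i + 1, "Z", np.asarray(p, float))
        for i, p in enumerate(points)
    ]
    return MolecularSystem(atoms=atoms, box=box)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
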