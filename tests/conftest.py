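import numpy as np
import pytest

from domainfold.hamiltonian import ForceField, PackedSystem
from domainfold.synthetic_data import (
    ToySpec, make_toy_binding_system, make_toy_multidomain,
)


@pytest.fixture(scope="session")
def fold_toy():
    """Default two-domain folding toy (no charges, no partner)."""
    return make_toy_multidomain()


@pytest.fixture(scope="session")
def binding_toy():
    """Protein + frozen charged partner, single (bound) basin."""
    return make_toy_binding_system()


@pytest.fixture(scope="session")
def dual_basin_toy():
    return make_toy_binding_system(
        ToySpec(
            partner_length=5,
            charge_pattern=("ARG", "GLY", "GLY", "GLY", "GLY", "GLY"),
            dual_basin=True,
        )
    )


@pytest.fixture(scope="session")
def fold_packed(fold_toy):
    ff = ForceField()
    return ff, PackedSystem(fold_toy.model, fold_toy.contacts, ff)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
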