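import numpy as np
import pytest

from pdmpnet.network import GeneKinetics, InteractionParams, NetworkModel


@pytest.fixture(scope="session")
def fig3_kinetics() -> GeneKinetics:
    """Single-gene rates used throughout the validation runs (units h⁻¹)."""
    return GeneKinetics(k0=0.34, k1=0.34, koff=10.0, d0=0.5, d1=0.1, s0=1e3, s1=10.0)


@pytest.fixture(scope="session")
def constant_single_gene(fig3_kinetics) -> NetworkModel:
    """One gene with constant k_on = 0.34 (no regulation)."""
    return NetworkModel(
        kinetics=(fig3_kinetics,),
        interactions=InteractionParams.from_theta(np.zeros((1, 1))),
        interaction_form="constant",
    )


@pytest.fixture(scope="session")
def auto_single_gene() -> NetworkModel:
    """One auto-activating gene (chromatin Hill form with feedback)."""
    kin = GeneKinetics(k0=0.05, k1=2.0, koff=10.0, d0=0.5, d1=0.1, s0=1e3, s1=10.0)
    return NetworkModel(
        kinetics=(kin,),
        interactions=InteractionParams(
            theta=np.array([[4.0]]), hill_m=np.array([[2.0]]), hill_s=np.array([[0.62]])
        ),
    )


@pytest.fixture(scope="session")
def toggle_model() -> NetworkModel:
    from pdmpnet.experiments import toggle_switch

    return toggle_switch()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
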