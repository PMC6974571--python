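import pytest

from paralogpocket.pipeline import default_simulation_params
from paralogpocket.pocketsim import PocketSpec, generate_pocket_structure
from paralogpocket.seqsim import simulate_family_evolution


@pytest.fixture(scope="session")
def demo_simulation():
    """One family simulation under the demo study conditions."""
    return simulate_family_evolution(default_simulation_params(seed=11))


@pytest.fixture(scope="session")
def pocket_pdb_text():
    """A synthetic pocket with planted contacts, one H-bond, one hydrophobic pair."""
    spec = PocketSpec(
        contact_distances=[4.0, 4.9, 5.1],
        hbond_geometries=[(2.8, 5.0, "ligand-carboxyl")],
        hydrophobic_pairs=[3.5],
        ligand_name="LIG",
    )
    return generate_pocket_structure(spec)
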