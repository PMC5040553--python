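import numpy as np
import pytest

from heptflux.model_core import MetabolicModel, Metabolite, Reaction, load_model


@pytest.fixture(scope="session")
def bundled_model() -> MetabolicModel:
    return load_model("ecoli_core_heptanoate")


@pytest.fixture
def chain_model() -> MetabolicModel:
    """Aext -> A -> B -> biomass, unit stoichiometry, uptake fixed at 1.

    The exchange convention makes uptake negative: EX_A: A <=> Aext with
    flux -1 supplies one unit of A.
    """
    return MetabolicModel(
        id="chain",
        metabolites=[
            Metabolite("Aext", external=True),
            Metabolite("A"),
            Metabolite("B"),
            Metabolite("X"),
            Metabolite("Xext", external=True),
        ],
        reactions=[
            Reaction("EX_A", {"A": -1.0, "Aext": 1.0}, lb=-1.0, ub=-1.0),
            Reaction("R1", {"A": -1.0, "B": 1.0}, lb=0.0, ub=10.0),
            Reaction("GROWTH", {"B": -1.0, "X": 1.0}, lb=0.0, ub=10.0),
            Reaction("EX_X", {"X": -1.0, "Xext": 1.0}, lb=0.0, ub=10.0),
        ],
        biomass_id="GROWTH",
        exchange_ids=["EX_A", "EX_X"],
    )


def random_small_model(rng: np.random.Generator) -> MetabolicModel:
    """A random syntactically valid model for round-trip tests."""
    n_met = int(rng.integers(2, 6))
    n_rxn = int(rng.integers(1, 6))
    mets = [
        Metabolite(
            id=f"m{i}",
            name=f"metabolite {i}",
            external=bool(rng.random() < 0.3),
        )
        for i in range(n_met)
    ]
    rxns = []
    for j in range(n_rxn):
        k = int(rng.integers(1, n_met + 1))
        chosen = rng.choice(n_met, size=k, replace=False)
        stoich = {
            f"m{i}": float(rng.choice([-2.0, -1.0, -0.5, 0.25, 1.0, 2.0]))
            for i in chosen
        }
        lb = float(rng.choice([-1000.0, -10.0, 0.0]))
        ub = float(rng.choice([0.0, 10.0, 1000.0]))
        if lb > ub:
            lb, ub = ub, lb
        rxns.append(Reaction(id=f"r{j}", stoichiometry=stoich, lb=lb, ub=ub))
    return MetabolicModel(id="random", metabolites=mets, reactions=rxns)
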