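import numpy as np
import pandas as pd
import pytest

from bedsidebn.cohort_model import Cohort, VariableSpec
from bedsidebn.inference import BayesNet, Cpt
from bedsidebn.structure_learning import Dag
from bedsidebn import synthetic_cohort as syn


def make_cohort(columns: dict, states: dict | None = None,
                roles: dict | None = None) -> Cohort:
    """Cohort from raw python columns; states inferred unless given."""
    states = states or {}
    roles = roles or {}
    specs = []
    data = {}
    for name, values in columns.items():
        values = [str(v) for v in values]
        sts = tuple(states.get(name) or sorted(set(values)) or ("0", "1"))
        specs.append(VariableSpec(name, sts, roles.get(name, "clinical")))
        data[name] = values
    return Cohort(tuple(specs), pd.DataFrame(data, dtype=str))


def random_net(rng: np.random.Generator, n_nodes: int, edge_prob: float = 0.4,
               max_card: int = 3) -> BayesNet:
    """Random DAG (topological order = name order) with Dirichlet CPTs."""
    names = tuple(f"v{i}" for i in range(n_nodes))
    arcs = []
    for j in range(n_nodes):
        for i in range(j):
            if rng.random() < edge_prob:
                arcs.append((names[i], names[j]))
    dag = Dag(names, tuple(arcs))
    states = {v: tuple(str(k) for k in range(rng.integers(2, max_card + 1)))
              for v in names}
    cpts = {}
    for v in names:
        parents = tuple(sorted(dag.parents(v)))
        shape = tuple(len(states[p]) for p in parents) + (len(states[v]),)
        table = rng.dirichlet(np.ones(shape[-1]) * 2.0,
                              size=shape[:-1] or None).reshape(shape)
        cpts[v] = Cpt(v, parents, table)
    return BayesNet(dag, states, cpts)


@pytest.fixture(scope="session")
def gt_spec():
    return syn.default_spec()


@pytest.fixture(scope="session")
def gt_net(gt_spec):
    return syn.build_ground_truth(gt_spec)


@pytest.fixture(scope="session")
def small_cohort(gt_spec):
    """Seeded synthetic cohort at the study's size (outcome included)."""
    return syn.generate(gt_spec, 1073, seed=2024)
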