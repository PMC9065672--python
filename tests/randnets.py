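"""Random small networks for oracle-agreement tests."""

import numpy as np

from siactors.bbn import BayesNet, DiscreteNode


def random_bayes_net(rng: np.random.Generator, max_nodes: int = 7, max_states: int = 3) -> BayesNet:
    """A random DAG with random normalized CPTs (for oracle comparisons)."""
    n = int(rng.integers(2, max_nodes + 1))
    names = [f"N{i}" for i in range(n)]
    cards = rng.integers(2, max_states + 1, size=n)
    nodes = []
    for i, name in enumerate(names):
        # Parents only from earlier nodes: acyclic by construction.
        possible = list(range(i))
        k = int(rng.integers(0, min(3, len(possible)) + 1))
        parents = sorted(rng.choice(possible, size=k, replace=False).tolist())
        shape = tuple(int(cards[p]) for p in parents) + (int(cards[i]),)
        raw = rng.random(shape) + 1e-3
        cpt = raw / raw.sum(axis=-1, keepdims=True)
        states = tuple(f"s{j}" for j in range(int(cards[i])))
        nodes.append(DiscreteNode(name, states, tuple(names[p] for p in parents), cpt))
    return BayesNet(nodes)
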