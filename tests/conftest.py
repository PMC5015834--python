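import numpy as np
import pytest

from homoset import Connectome


def build(chem=(), gap=(), neurons=()):
    """Connectome from (pre, post, weight) chemical and (a, b, weight) gap tuples."""
    c = Connectome()
    for n in neurons:
        c.add_neuron(n)
    for rec in chem:
        pre, post, *w = rec
        c.add_edge(pre, post, "chemical", w[0] if w else 1)
    for rec in gap:
        a, b, *w = rec
        c.add_edge(a, b, "gap", w[0] if w else 1)
    return c


@pytest.fixture
def star_graph():
    """Hub H with 4 leaves, chemical H -> leaf."""
    return build(chem=[("H", f"L{i}") for i in range(4)])


@pytest.fixture
def k4():
    """Complete directed graph on 4 nodes (reciprocal chemical everywhere)."""
    names = ["A", "B", "C", "D"]
    return build(chem=[(a, b) for a in names for b in names if a != b])


def random_connectome(n, p_chem, p_gap=0.0, seed=0, weights=False):
    rng = np.random.default_rng(seed)
    names = [f"N{i:02d}" for i in range(n)]
    c = Connectome()
    for name in names:
        c.add_neuron(name)
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p_chem:
                w = int(rng.integers(1, 6)) if weights else 1
                c.add_edge(names[i], names[j], "chemical", w)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_gap:
                w = int(rng.integers(1, 4)) if weights else 1
                c.add_edge(names[i], names[j], "gap", w)
    return c
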