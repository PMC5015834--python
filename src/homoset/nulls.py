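"""Null-model ensembles for the common-neighbor rule.

Two null generators are provided: degree-preserving edge swaps (chemical
edges swapped as directed pairs, gap junctions as undirected pairs, never
interconverted — the two synapse classes are biologically distinct) and
size-matched Erdős–Rényi graphs with no degree constraint.  The ensemble
test compares the real CNR-curve slope against the null slope distribution
with a two-sided z-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cnr import cnr_curve
from .connectome import Connectome

logger = logging.getLogger(__name__)


def shuffle_degree_preserving(c: Connectome, swap_factor: float = 10.0,
                              seed: int | None = None) -> Connectome:
    """Randomize edges while conserving every degree sequence exactly.

    Attempts ``swap_factor * |E|`` double-edge swaps per channel: a directed
    swap (a->b, c->d) => (a->d, c->b) on chemical edges, an undirected swap
    on gap edges.  Swaps creating self-loops or duplicate records are
    rejected.  Weights ride with their edges, so total weight per channel is
    conserved along with every node's chemical in-degree, chemical
    out-degree and gap degree.
    """
    if len(c.chem) + len(c.gap) == 0:
        raise ValueError("cannot shuffle a connectome with no edges")
    rng = np.random.default_rng(seed)
    out = c.copy()

    chem = list(out.chem.items())        # [((pre, post), w)]
    if len(chem) >= 2:
        present = set(out.chem)
        n_attempt = int(swap_factor * len(chem))
        accepted = 0
        idx = rng.integers(0, len(chem), size=(n_attempt, 2))
        for i, j in idx:
            if i == j:
                continue
            (a, b), w1 = chem[i]
            (cc, d), w2 = chem[j]
            if a == d or cc == b:
                continue
            if (a, d) in present or (cc, b) in present:
                continue
            present.discard((a, b))
            present.discard((cc, d))
            present.add((a, d))
            present.add((cc, b))
            chem[i] = ((a, d), w1)
            chem[j] = ((cc, b), w2)
            accepted += 1
        if accepted == 0 and n_attempt > 0:
            logger.warning("degree-preserving shuffle: no valid chemical swap "
                           "found in %d attempts", n_attempt)
        out.chem = dict(chem)

    gaps = list(out.gap.items())         # [(frozenset, w)]
    if len(gaps) >= 2:
        present_g = set(out.gap)
        n_attempt = int(swap_factor * len(gaps))
        idx = rng.integers(0, len(gaps), size=(n_attempt, 2))
        flips = rng.integers(0, 2, size=(n_attempt, 2))
        for (i, j), (f1, f2) in zip(idx, flips):
            if i == j:
                continue
            e1, w1 = gaps[i]
            e2, w2 = gaps[j]
            a, b = sorted(e1)
            cc, d = sorted(e2)
            if f1:
                a, b = b, a
            if f2:
                cc, d = d, cc
            n1, n2 = frozenset((a, d)), frozenset((cc, b))
            if len(n1) < 2 or len(n2) < 2:
                continue
            if n1 in present_g or n2 in present_g or n1 == n2:
                continue
            present_g.discard(e1)
            present_g.discard(e2)
            present_g.add(n1)
            present_g.add(n2)
            gaps[i] = (n1, w1)
            gaps[j] = (n2, w2)
        out.gap = dict(gaps)
    return out


def er_matched(c: Connectome, seed: int | None = None) -> Connectome:
    """Erdős–Rényi null with the source's node count and directed edge count.

    Gap junctions contribute two directed edges to the matched count; the
    null itself contains chemical edges only (weight 1), with no degree
    constraint.
    """
    rng = np.random.default_rng(seed)
    names = c.names
    n = len(names)
    n_edges = len(c.chem) + 2 * len(c.gap)
    n_slots = n * (n - 1)
    if n_edges > n_slots:
        raise ValueError("more edges than ordered pairs")
    chosen = rng.choice(n_slots, size=n_edges, replace=False)
    out = Connectome()
    for name in names:
        nr = c.neurons[name]
        out.add_neuron(name, nr.layer, nr.soma_position)
    for slot in chosen:
        i, rem = divmod(int(slot), n - 1)
        j = rem if rem < i else rem + 1
        out.add_edge(names[i], names[j], "chemical", 1)
    return out


def generate_null(c: Connectome, generator: str, seed: int | None = None,
                  swap_factor: float = 10.0) -> Connectome:
    if generator in ("degree_preserving", "dp"):
        return shuffle_degree_preserving(c, swap_factor=swap_factor, seed=seed)
    if generator in ("erdos_renyi", "er"):
        return er_matched(c, seed=seed)
    raise ValueError(f"unknown null generator {generator!r}")


@dataclass
class EnsembleResult:
    generator: str
    n_networks: int
    n_dropped: int
    real_slope: float
    slopes: list[float] = field(repr=False, default_factory=list)
    z: float = float("nan")
    p: float = float("nan")
    seed: int | None = None

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["null_slope_mean"] = float(np.mean(self.slopes)) if self.slopes else None
        d["null_slope_std"] = (float(np.std(self.slopes, ddof=1))
                               if len(self.slopes) > 1 else None)
        return d


def ensemble_slope_test(c: Connectome, generator: str = "degree_preserving",
                        n_networks: int = 100, seed: int | None = None,
                        min_pairs_per_bin: int = 5,
                        swap_factor: float = 10.0) -> EnsembleResult:
    """Compare the real CNR slope to a null-ensemble slope distribution.

    Nulls on which the linear fit is infeasible (fewer than two eligible
    bins) are dropped and counted; more than 20% dropped is an error.
    Returns z = (real - mean)/sd and the two-sided normal p.
    """
    if n_networks < 2:
        raise ValueError("n_networks must be >= 2")
    real = cnr_curve(c, min_pairs_per_bin=min_pairs_per_bin)
    if not real.fit_feasible:
        raise ValueError("CNR fit infeasible on the real network")
    rng = np.random.default_rng(seed)
    slopes: list[float] = []
    dropped = 0
    for _ in range(n_networks):
        sub = int(rng.integers(0, 2**31 - 1))
        null = generate_null(c, generator, seed=sub, swap_factor=swap_factor)
        curve = cnr_curve(null, min_pairs_per_bin=min_pairs_per_bin)
        if curve.fit_feasible:
            slopes.append(curve.slope)
        else:
            dropped += 1
    if dropped > 0.2 * n_networks:
        raise RuntimeError(f"{dropped}/{n_networks} null networks had an "
                           "infeasible CNR fit")
    mean = float(np.mean(slopes))
    sd = float(np.std(slopes, ddof=1))
    if sd == 0:
        z = 0.0 if real.slope == mean else float("inf") * np.sign(real.slope - mean)
        p = 1.0 if real.slope == mean else 0.0
    else:
        z = (real.slope - mean) / sd
        p = float(2 * stats.norm.sf(abs(z)))
    return EnsembleResult(generator, n_networks, dropped, real.slope,
                          slopes, z, p, seed)
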