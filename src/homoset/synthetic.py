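"""Synthetic connectome generation with planted common-neighbor sets.

The generator emulates the statistical structure the analysis pipeline
assumes: a directed dual-channel background (optionally heavy-tailed or
distance-dependent), planted homogeneous common-neighbor sets of chosen
triad types, curated layer labels, bilateral L/R name pairs, and 1-D soma
positions — so every downstream stage is testable without any download.

Planted X-Y channel rule (mirroring the empirical composition of the
bidirectional set types): the mutually regulating type (#10) gets a
reciprocal chemical dyad, the mutually regulated (#13) and fully
bidirectional (#15) types get a gap junction, all other connected types get
chemical links.  Background edges never overwrite planted structure: a
background draw that lands on an internal dyad of a planted set is
redrawn elsewhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .connectome import Connectome
from .triads import XYState, ZDyad, type_by_id

#: X-Y channel per planted triad type id (None for unconnected types).
GAP_XY_TYPES = {13, 15}


@dataclass(frozen=True)
class PlantedSetSpec:
    """Recipe for one batch of planted common-neighbor sets."""

    triad_type: int
    n_z: int = 5
    x_layer: str = "unknown"
    y_layer: str = "unknown"
    z_layer: str = "unknown"
    count: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.triad_type <= 21:
            raise ValueError("triad_type must be in 1..21")
        if self.n_z < 5:
            raise ValueError("n_z must be >= 5 (the pipeline's set-size threshold)")
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass
class PlantedSet:
    x: str
    y: str
    z: list[str]
    triad_type: int


@dataclass
class SyntheticGroundTruth:
    planted: list[PlantedSet] = field(default_factory=list)
    background_edges: int = 0
    seed: int | None = None

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({
                "seed": self.seed,
                "background_edges": self.background_edges,
                "planted": [{"x": p.x, "y": p.y, "z": p.z, "triad_type": p.triad_type}
                            for p in self.planted],
            }, fh, indent=1)


def generate_er(n: int, p: float, directed: bool = True,
                seed: int | None = None) -> Connectome:
    """Erdős–Rényi connectome: each (ordered) pair gets a chemical edge with
    probability p, weight 1.  In undirected mode each unordered pair is
    drawn once and realized as a reciprocal chemical dyad."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    width = len(str(n - 1))
    names = [f"N{i:0{width}d}" for i in range(n)]
    c = Connectome()
    for name in names:
        c.add_neuron(name)
    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)
    if directed:
        for i, j in zip(*np.nonzero(mask)):
            c.add_edge(names[i], names[j], "chemical", 1)
    else:
        for i, j in zip(*np.nonzero(np.triu(mask, k=1))):
            c.add_edge(names[i], names[j], "chemical", 1)
            c.add_edge(names[j], names[i], "chemical", 1)
    return c


def generate_preferential(n: int, m: int = 3, seed: int | None = None) -> Connectome:
    """Preferential-attachment connectome with a heavy-tailed degree
    distribution (Barabási–Albert skeleton, each edge oriented at random)."""
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(0, 2**31 - 1)))
    width = len(str(n - 1))
    names = [f"N{i:0{width}d}" for i in range(n)]
    c = Connectome()
    for name in names:
        c.add_neuron(name)
    for a, b in g.edges():
        if rng.random() < 0.5:
            a, b = b, a
        c.add_edge(names[a], names[b], "chemical", 1)
    return c


def generate_spatial(n: int, base_p: float, decay: float = 0.0,
                     seed: int | None = None) -> Connectome:
    """Connectome with uniform [0,1] soma positions and connection
    probability base_p * exp(-decay * distance) per ordered pair.  With
    decay=0 the wiring is distance-independent."""
    rng = np.random.default_rng(seed)
    width = len(str(n - 1))
    names = [f"N{i:0{width}d}" for i in range(n)]
    pos = rng.random(n)
    c = Connectome()
    for name, p0 in zip(names, pos):
        c.add_neuron(name, soma_position=float(p0))
    d = np.abs(pos[:, None] - pos[None, :])
    prob = base_p * np.exp(-decay * d)
    mask = rng.random((n, n)) < prob
    np.fill_diagonal(mask, False)
    for i, j in zip(*np.nonzero(mask)):
        c.add_edge(names[i], names[j], "chemical", 1)
    return c


def _plant_dyad(c: Connectome, a: str, b: str, state: ZDyad, weight_rng) -> None:
    """Realize the role->Z dyad state with chemical edges (weights >= 1)."""
    if state in (ZDyad.OUT, ZDyad.BOTH):
        c.add_edge(a, b, "chemical", weight_rng())
    if state in (ZDyad.IN, ZDyad.BOTH):
        c.add_edge(b, a, "chemical", weight_rng())


def generate_planted(n_per_layer: dict[str, int],
                     planted: list[PlantedSetSpec],
                     p_background: float = 0.0,
                     bilateral_fraction: float = 0.0,
                     weight_high: int = 5,
                     seed: int | None = None
                     ) -> tuple[Connectome, SyntheticGroundTruth]:
    """Plant homogeneous common-neighbor sets over an ER background.

    Every requested set is planted exactly: the X-Y dyad per the channel
    rule, and every Z dyad per the requested triad type.  Layer membership,
    uniform soma positions (bilateral partners share one), and L/R names
    for a ``bilateral_fraction`` of each layer are assigned.  Background
    chemical edges are then overlaid with probability ``p_background`` per
    ordered pair, redrawing any draw that collides with an internal dyad of
    a planted set, so planted triad types survive verbatim.
    """
    rng = np.random.default_rng(seed)
    c = Connectome()
    names_by_layer: dict[str, list[str]] = {}
    prefix = {"sensory": "SN", "inter": "IN", "premotor": "PM",
              "motor": "MN", "unknown": "UN"}
    for layer, count in n_per_layer.items():
        names: list[str] = []
        n_bilateral_pairs = int(bilateral_fraction * count / 2)
        i = 0
        while len(names) < count:
            base = f"{prefix[layer]}{i:03d}"
            if i < n_bilateral_pairs and len(names) + 2 <= count:
                pos = float(rng.random())
                for side in "LR":
                    c.add_neuron(base + side, layer=layer, soma_position=pos)
                    names.append(base + side)
            else:
                c.add_neuron(base, layer=layer, soma_position=float(rng.random()))
                names.append(base)
            i += 1
        names_by_layer[layer] = names

    def weight() -> int:
        return int(rng.integers(1, weight_high + 1))

    free: dict[str, list[str]] = {k: list(v) for k, v in names_by_layer.items()}

    def take(layer: str, k: int) -> list[str]:
        if len(free.get(layer, [])) < k:
            raise ValueError(f"not enough free neurons in layer {layer!r} "
                             f"to host the planted sets")
        picked = [free[layer].pop(int(rng.integers(0, len(free[layer]))))
                  for _ in range(k)]
        return picked

    truth = SyntheticGroundTruth(seed=seed)
    protected: set[frozenset] = set()
    for spec in planted:
        ttype = type_by_id(spec.triad_type)
        for _ in range(spec.count):
            x, y = take(spec.x_layer, 1)[0], take(spec.y_layer, 1)[0]
            zs = take(spec.z_layer, spec.n_z)
            if ttype.xy is XYState.FORWARD:
                c.add_edge(x, y, "chemical", weight())
            elif ttype.xy is XYState.RECIPROCAL:
                if ttype.id in GAP_XY_TYPES:
                    c.add_edge(x, y, "gap", weight())
                else:
                    c.add_edge(x, y, "chemical", weight())
                    c.add_edge(y, x, "chemical", weight())
            protected.add(frozenset((x, y)))
            for z in zs:
                _plant_dyad(c, x, z, ttype.xz, weight)
                _plant_dyad(c, y, z, ttype.yz, weight)
                protected.add(frozenset((x, z)))
                protected.add(frozenset((y, z)))
            truth.planted.append(PlantedSet(x, y, zs, spec.triad_type))

    all_names = [n for v in names_by_layer.values() for n in v]
    n = len(all_names)
    if p_background > 0 and n >= 2:
        n_slots = n * (n - 1)
        n_bg = rng.binomial(n_slots, p_background)
        added = 0
        attempts = 0
        while added < n_bg and attempts < 50 * n_bg + 1000:
            attempts += 1
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            a, b = all_names[int(i)], all_names[int(j)]
            if frozenset((a, b)) in protected:
                continue  # redraw: planted structure is never perturbed
            if (a, b) in c.chem:
                continue
            c.add_edge(a, b, "chemical", 1)
            added += 1
        truth.background_edges = added
    return c, truth
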