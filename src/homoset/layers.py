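"""Layer localization of homogeneous common-neighbor sets.

Neurons carry a curated functional layer (sensory, inter, premotor, motor).
These routines ask where the X-Y pairs of homogeneous sets sit (same layer
vs different layers, and which layer pair), whether particular set types are
enriched in particular layer pairs (hypergeometric test, Bonferroni), what
the X-Y dyad of bidirectional set types is made of (chemical vs gap), and
how results change when gap junctions are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .connectome import Channel, Connectome
from .homogeneity import HomogeneityResult, enrichment_tests, hgt_pvalue
from .triads import XYState, extract_sets


def _layer_pair(r: HomogeneityResult, layers: dict[str, str]) -> tuple[str, str]:
    """X/Y layer pair: ordered for unidirectional set types, else sorted."""
    x_layer, y_layer = layers[r.set.x], layers[r.set.y]
    if r.dominant_type.xy is XYState.FORWARD:
        return (x_layer, y_layer)
    lo, hi = sorted((x_layer, y_layer))
    return (lo, hi)


def layer_pair_histogram(c: Connectome, results: list[HomogeneityResult]
                         ) -> pd.DataFrame:
    """Per homogeneous set type: same/different-layer counts and the full
    layer-pair matrix (one row per (set type, layer pair)).

    Sets whose X or Y has no assigned layer are excluded and counted in the
    ``unknown_excluded`` attribute of the returned frame.
    """
    layers = {n.name: n.layer for n in c.neurons.values()}
    rows = []
    excluded = 0
    for r in results:
        if not r.homogeneous:
            continue
        pair = _layer_pair(r, layers)
        if "unknown" in pair:
            excluded += 1
            continue
        rows.append({
            "set_type": r.dominant_type.id,
            "layer_x": pair[0],
            "layer_y": pair[1],
            "same_layer": pair[0] == pair[1],
        })
    if not rows:
        df = pd.DataFrame(columns=["set_type", "layer_x", "layer_y", "same_layer", "count"])
    else:
        df = (pd.DataFrame(rows)
              .groupby(["set_type", "layer_x", "layer_y", "same_layer"])
              .size().rename("count").reset_index())
    df.attrs["unknown_excluded"] = excluded
    return df


@dataclass
class LayerEnrichment:
    set_type: int
    layer_pair: tuple[str, str]
    count: int
    n: int
    K: int
    N: int
    p_hgt: float
    p_bonferroni: float
    significant: bool

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["layer_pair"] = list(self.layer_pair)
        return d


def layer_enrichment(c: Connectome, results: list[HomogeneityResult],
                     threshold: float = 0.005,
                     background: str = "homogeneous") -> list[LayerEnrichment]:
    """Hypergeometric enrichment of each set type in each layer pair.

    For a (set type, layer pair) cell: population N = all background sets
    with known layers, K = those with that layer pair, n = background sets
    of this type, k = the cell count.  Bonferroni over every cell tested
    (types x layer pairs observed).  ``background`` selects whether the
    population is the homogeneous sets (default) or all scored sets.
    """
    layers = {n.name: n.layer for n in c.neurons.values()}
    if background == "homogeneous":
        pop = [r for r in results if r.homogeneous]
    elif background == "all":
        pop = list(results)
    else:
        raise ValueError(f"unknown background {background!r}")
    labelled = [(r.dominant_type.id, _layer_pair(r, layers)) for r in pop]
    labelled = [(t, p) for (t, p) in labelled if "unknown" not in p]
    N = len(labelled)
    if N == 0:
        return []
    types = sorted({t for t, _ in labelled})
    pairs = sorted({p for _, p in labelled})
    n_cells = len(types) * len(pairs)
    out: list[LayerEnrichment] = []
    for t in types:
        n = sum(1 for tt, _ in labelled if tt == t)
        for pr in pairs:
            K = sum(1 for _, pp in labelled if pp == pr)
            k = sum(1 for tt, pp in labelled if tt == t and pp == pr)
            p = hgt_pvalue(k, n, K, N) if k > 0 else 1.0
            p_b = min(1.0, p * n_cells)
            out.append(LayerEnrichment(t, pr, k, n, K, N, p, p_b,
                                       bool(k > 0 and p_b <= threshold)))
    return out


@dataclass
class SynapseComposition:
    set_type: int
    n_chemical: int
    n_gap: int
    n_sets: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def xy_synapse_composition(c: Connectome, results: list[HomogeneityResult]
                           ) -> list[SynapseComposition]:
    """Chemical vs gap makeup of the X-Y dyad across bidirectional set types.

    For every homogeneous set whose dominant type has a reciprocal X-Y dyad
    (types 10-15), the dyad contributes once to the chemical tally if any
    chemical synapse joins X and Y (either direction) and once to the gap
    tally if a gap junction does; a dyad with both channels counts in both.
    """
    tallies: dict[int, SynapseComposition] = {}
    for r in results:
        if not r.homogeneous or r.dominant_type.xy is not XYState.RECIPROCAL:
            continue
        t = tallies.setdefault(r.dominant_type.id,
                               SynapseComposition(r.dominant_type.id, 0, 0, 0))
        t.n_sets += 1
        x, y = r.set.x, r.set.y
        if (x, y) in c.chem or (y, x) in c.chem:
            t.n_chemical += 1
        if c.has_gap(x, y):
            t.n_gap += 1
    return [tallies[k] for k in sorted(tallies)]


def chemical_only_reanalysis(c: Connectome, min_neighbors: int = 5,
                             connected_only: bool = True, alpha: float = 0.05,
                             majority_fraction: float = 0.5, R: int = 100,
                             seed: int | None = None):
    """Re-run set extraction, homogeneity and enrichment on chemical synapses only.

    Discarding gap junctions removes the bidirectional X-Y links of
    gap-coupled set types, so their overrepresentation should collapse
    while all-chemical types persist.  On a gap-free connectome this is
    identical to the standard pipeline.
    """
    sets = extract_sets(c, min_neighbors=min_neighbors,
                        connected_only=connected_only,
                        channel=Channel.CHEMICAL_ONLY)
    if not sets:
        return None
    return enrichment_tests(sets, R=R, seed=seed, alpha=alpha,
                            majority_fraction=majority_fraction)


def xy_vs_z_layer_distribution(c: Connectome, results: list[HomogeneityResult]
                               ) -> pd.DataFrame:
    """Joint distribution of (set type, X-Y layer pair, Z layer) over members."""
    layers = {n.name: n.layer for n in c.neurons.values()}
    rows = []
    for r in results:
        if not r.homogeneous:
            continue
        pair = _layer_pair(r, layers)
        for z, _ in r.set.members:
            rows.append({
                "set_type": r.dominant_type.id,
                "layer_x": pair[0],
                "layer_y": pair[1],
                "layer_z": layers[z],
            })
    if not rows:
        return pd.DataFrame(columns=["set_type", "layer_x", "layer_y", "layer_z", "count"])
    return (pd.DataFrame(rows)
            .groupby(["set_type", "layer_x", "layer_y", "layer_z"])
            .size().rename("count").reset_index())
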