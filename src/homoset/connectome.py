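"""Dual-channel connectome container and file I/O.

A connectome here is a set of named neurons joined by two kinds of links:

* chemical synapses — directed, weighted by synapse count, at most one record
  per ordered pair (parallel records are summed on load);
* gap junctions — electrical synapses stored once per unordered pair and
  treated as symmetric in every query, weighted by junction count.

Because the directionality of gap junctions is not annotated in available
wiring data, every gap junction is treated as bidirectional throughout.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LAYERS = ("sensory", "inter", "premotor", "motor", "unknown")


class DyadState(enum.Enum):
    """Connectivity state of an ordered neuron pair (a, b)."""

    NONE = "none"
    FORWARD = "forward"        # a -> b only
    BACKWARD = "backward"      # b -> a only
    RECIPROCAL = "reciprocal"  # both directions (a lone gap junction counts)

    def mirror(self) -> "DyadState":
        if self is DyadState.FORWARD:
            return DyadState.BACKWARD
        if self is DyadState.BACKWARD:
            return DyadState.FORWARD
        return self


class Channel(enum.Enum):
    ALL = "all"
    CHEMICAL_ONLY = "chemical_only"
    GAP_ONLY = "gap_only"


@dataclass
class Neuron:
    name: str
    layer: str = "unknown"
    soma_position: float | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r} for neuron {self.name}")


class Connectome:
    """Neurons plus chemical (directed) and gap (symmetric) weighted edges."""

    def __init__(self) -> None:
        self.neurons: dict[str, Neuron] = {}
        self.chem: dict[tuple[str, str], int] = {}
        self.gap: dict[frozenset, int] = {}

    # -- construction -------------------------------------------------

    def add_neuron(self, name: str, layer: str = "unknown",
                   soma_position: float | None = None) -> Neuron:
        if name in self.neurons:
            n = self.neurons[name]
            if layer != "unknown":
                n.layer = layer
            if soma_position is not None:
                n.soma_position = soma_position
            return n
        n = Neuron(name, layer, soma_position)
        self.neurons[name] = n
        return n

    def add_edge(self, pre: str, post: str, kind: str, weight: int = 1) -> None:
        """Add (or accumulate onto) an edge; neurons are created on demand."""
        if pre == post:
            raise ValueError(f"self-edge rejected: {pre}")
        w = int(weight)
        if w < 1:
            raise ValueError(f"edge weight must be >= 1, got {weight}")
        self.add_neuron(pre)
        self.add_neuron(post)
        if kind == "chemical":
            self.chem[(pre, post)] = self.chem.get((pre, post), 0) + w
        elif kind == "gap":
            key = frozenset((pre, post))
            self.gap[key] = self.gap.get(key, 0) + w
        else:
            raise ValueError(f"unknown edge kind {kind!r}")

    def remove_chem(self, pre: str, post: str) -> None:
        del self.chem[(pre, post)]

    def remove_gap(self, a: str, b: str) -> None:
        del self.gap[frozenset((a, b))]

    def copy(self) -> "Connectome":
        c = Connectome()
        for n in self.neurons.values():
            c.add_neuron(n.name, n.layer, n.soma_position)
        c.chem = dict(self.chem)
        c.gap = dict(self.gap)
        return c

    def chemical_only(self) -> "Connectome":
        """The same connectome with every gap junction discarded."""
        c = self.copy()
        c.gap = {}
        return c

    # -- queries ------------------------------------------------------

    @property
    def names(self) -> list[str]:
        return list(self.neurons)

    def __contains__(self, name: str) -> bool:
        return name in self.neurons

    def _require(self, name: str) -> None:
        if name not in self.neurons:
            raise KeyError(f"unknown neuron {name!r}")

    def has_gap(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.gap

    def dyad_state(self, a: str, b: str,
                   channel: Channel | str = Channel.ALL) -> DyadState:
        """Connectivity state of the ordered pair (a, b) under a channel filter.

        Under ``all``, a gap junction alone (or combined with a one-way
        chemical synapse) yields ``RECIPROCAL`` since gap junctions conduct
        both ways.
        """
        channel = Channel(channel)
        if a == b:
            raise ValueError("dyad_state requires two distinct neurons")
        self._require(a)
        self._require(b)
        fwd = bkw = False
        if channel in (Channel.ALL, Channel.CHEMICAL_ONLY):
            fwd = (a, b) in self.chem
            bkw = (b, a) in self.chem
        if channel in (Channel.ALL, Channel.GAP_ONLY) and self.has_gap(a, b):
            fwd = bkw = True
        if fwd and bkw:
            return DyadState.RECIPROCAL
        if fwd:
            return DyadState.FORWARD
        if bkw:
            return DyadState.BACKWARD
        return DyadState.NONE

    def neighbors(self, a: str, channel: Channel | str = Channel.ALL) -> set[str]:
        """All neurons linked to ``a`` in either direction on the channel."""
        channel = Channel(channel)
        self._require(a)
        out: set[str] = set()
        if channel in (Channel.ALL, Channel.CHEMICAL_ONLY):
            for (p, q) in self.chem:
                if p == a:
                    out.add(q)
                elif q == a:
                    out.add(p)
        if channel in (Channel.ALL, Channel.GAP_ONLY):
            for key in self.gap:
                if a in key:
                    out.update(key - {a})
        return out

    def neighbor_sets(self, channel: Channel | str = Channel.ALL) -> dict[str, set[str]]:
        """Direction-blind adjacency sets for every neuron (one pass)."""
        channel = Channel(channel)
        out: dict[str, set[str]] = {n: set() for n in self.neurons}
        if channel in (Channel.ALL, Channel.CHEMICAL_ONLY):
            for (p, q) in self.chem:
                out[p].add(q)
                out[q].add(p)
        if channel in (Channel.ALL, Channel.GAP_ONLY):
            for key in self.gap:
                a, b = tuple(key)
                out[a].add(b)
                out[b].add(a)
        return out

    def undirected_adjacency(self, channel: Channel | str = Channel.ALL
                             ) -> tuple[list[str], np.ndarray]:
        """Boolean symmetric neighbor matrix (zero diagonal) and its node order."""
        names = self.names
        idx = {n: i for i, n in enumerate(names)}
        m = np.zeros((len(names), len(names)), dtype=bool)
        for n, nbrs in self.neighbor_sets(channel).items():
            i = idx[n]
            for b in nbrs:
                m[i, idx[b]] = True
        return names, m

    def total_weight(self, channel: Channel | str = Channel.ALL) -> int:
        channel = Channel(channel)
        w = 0
        if channel in (Channel.ALL, Channel.CHEMICAL_ONLY):
            w += sum(self.chem.values())
        if channel in (Channel.ALL, Channel.GAP_ONLY):
            w += sum(self.gap.values())
        return w

    def degree_sequences(self) -> pd.DataFrame:
        """Chemical in/out degree and gap degree per neuron."""
        rows = {n: [0, 0, 0] for n in self.neurons}
        for (p, q) in self.chem:
            rows[p][1] += 1
            rows[q][0] += 1
        for key in self.gap:
            for n in key:
                rows[n][2] += 1
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=["chem_in", "chem_out", "gap"]
        )

    def edge_records(self) -> Iterator[tuple[str, str, str, int]]:
        """Canonical (pre, post, kind, weight) records; gap pairs name-sorted."""
        for (p, q), w in sorted(self.chem.items()):
            yield p, q, "chemical", w
        for key, w in sorted(self.gap.items(), key=lambda kv: tuple(sorted(kv[0]))):
            a, b = sorted(key)
            yield a, b, "gap", w

    def summary(self) -> dict:
        return {
            "n_neurons": len(self.neurons),
            "n_chemical_edges": len(self.chem),
            "n_gap_edges": len(self.gap),
            "total_chemical_weight": sum(self.chem.values()),
            "total_gap_weight": sum(self.gap.values()),
        }


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

#: wormatlas "neuronal wiring" type codes: sends, receives (mirror of a send),
#: electrical junction, neuromuscular junction (target is muscle, not neuron).
_WA_SEND = {"S", "Sp"}
_WA_RECV = {"R", "Rp"}
_WA_GAP = {"EJ"}
_WA_SKIP = {"NMJ"}


class EdgeListError(ValueError):
    pass


def load_edge_list(path, dialect: str = "generic_csv") -> Connectome:
    """Load a connectome from a file in one of the supported dialects.

    ``generic_csv``
        Header ``pre,post,kind,weight`` with kind in {chemical, gap}.
        Parallel records are summed; reciprocal gap records for the same
        unordered pair must carry equal weights and collapse to one edge.
    ``adjacency_matrix``
        Square numeric CSV with a shared neuron-name header row and index
        column; entry (i, j) > 0 is a chemical edge i -> j of that weight.
        Gap junctions cannot be represented in this dialect.
    ``wormatlas``
        The "neuronal wiring" spreadsheet layout (Neuron 1, Neuron 2, Type,
        Nbr).  Send (S/Sp) rows give directed chemical edges pre -> post;
        receive (R/Rp) rows are the mirror records of the same synapses and
        are deduplicated against them; EJ rows give gap junctions (also
        listed from both sides, deduplicated); NMJ rows are muscle targets
        and are excluded from the neuron graph.
    """
    if dialect == "generic_csv":
        return _load_generic_csv(path)
    if dialect == "adjacency_matrix":
        return _load_adjacency(path)
    if dialect == "wormatlas":
        return _load_wormatlas(path)
    raise EdgeListError(f"unknown dialect {dialect!r}")


def _load_generic_csv(path) -> Connectome:
    c = Connectome()
    gap_pending: dict[frozenset, list[int]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"pre", "post", "kind", "weight"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise EdgeListError(f"generic_csv requires header {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                pre, post = row["pre"].strip(), row["post"].strip()
                kind = row["kind"].strip()
                weight = int(row["weight"])
                if kind == "gap":
                    # collect per unordered pair; reciprocal records must match
                    gap_pending.setdefault(frozenset((pre, post)), []).append(weight)
                    c.add_neuron(pre)
                    c.add_neuron(post)
                    if pre == post:
                        raise ValueError("self-edge")
                else:
                    c.add_edge(pre, post, kind, weight)
            except (KeyError, ValueError) as err:
                raise EdgeListError(f"{path}: malformed row at line {lineno}: {err}") from err
    for key, weights in gap_pending.items():
        if len(weights) == 1:
            c.add_edge(*sorted(key), "gap", weights[0])
        elif len(weights) == 2 and weights[0] == weights[1]:
            c.add_edge(*sorted(key), "gap", weights[0])
        else:
            a, b = sorted(key)
            raise EdgeListError(
                f"{path}: inconsistent reciprocal gap records for {a}-{b}: {weights}"
            )
    return c


def _load_adjacency(path) -> Connectome:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise EdgeListError("adjacency_matrix requires identical row and column names")
    c = Connectome()
    for n in df.index:
        c.add_neuron(str(n))
    arr = df.to_numpy()
    for i, pre in enumerate(df.index):
        for j, post in enumerate(df.columns):
            w = arr[i, j]
            if w > 0 and i != j:
                c.add_edge(str(pre), str(post), "chemical", int(w))
    return c


def _load_wormatlas(path) -> Connectome:
    send: dict[tuple[str, str], int] = {}
    recv: dict[tuple[str, str], int] = {}
    gap: dict[frozenset, int] = {}
    skipped_nmj = 0
    with open(path, newline="", encoding="utf-8") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.reader(fh, delimiter=delim)
        header = next(reader)
        if len(header) < 4:
            raise EdgeListError("wormatlas layout requires 4 columns "
                                "(Neuron 1, Neuron 2, Type, Nbr)")
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            try:
                n1, n2, code, nbr = (row[0].strip(), row[1].strip(),
                                     row[2].strip(), int(row[3]))
            except (IndexError, ValueError) as err:
                raise EdgeListError(f"{path}: malformed row at line {lineno}: {err}") from err
            if code in _WA_SKIP:
                skipped_nmj += 1
                continue
            if code in _WA_SEND:
                send[(n1, n2)] = send.get((n1, n2), 0) + nbr
            elif code in _WA_RECV:
                # N1 receives from N2: the mirror record of a send N2 -> N1
                recv[(n2, n1)] = recv.get((n2, n1), 0) + nbr
            elif code in _WA_GAP:
                key = frozenset((n1, n2))
                gap[key] = max(gap.get(key, 0), nbr)
            else:
                logger.warning("%s line %d: unknown type code %r, skipped",
                               path, lineno, code)
    c = Connectome()
    for pair in sorted(set(send) | set(recv)):
        ws, wr = send.get(pair, 0), recv.get(pair, 0)
        if ws and wr and ws != wr:
            logger.warning("wormatlas send/receive weight mismatch for %s: %d vs %d "
                           "(keeping max)", pair, ws, wr)
        c.add_edge(pair[0], pair[1], "chemical", max(ws, wr))
    for key, w in gap.items():
        a, b = sorted(key)
        c.add_edge(a, b, "gap", w)
    if skipped_nmj:
        logger.info("wormatlas: excluded %d NMJ (neuromuscular) rows", skipped_nmj)
    logger.info("wormatlas: loaded %s", c.summary())
    return c


def write_edge_list(c: Connectome, path) -> None:
    """Write the connectome in the generic_csv dialect (round-trip safe)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["pre", "post", "kind", "weight"])
        for rec in c.edge_records():
            w.writerow(rec)


def load_layer_table(c: Connectome, path) -> int:
    """Attach layers from a two-column CSV ``neuron,layer``.

    Neurons present in the table but absent from the edge list are retained
    as isolated nodes so catalogue counts stay stable.  Returns the number
    of isolated neurons added.
    """
    added = 0
    df = pd.read_csv(path)
    cols = [c0.strip().lower() for c0 in df.columns]
    df.columns = cols
    for _, row in df.iterrows():
        name, layer = str(row["neuron"]).strip(), str(row["layer"]).strip().lower()
        if layer not in LAYERS:
            raise EdgeListError(f"{path}: unknown layer {layer!r} for {name}")
        if name not in c:
            added += 1
            logger.info("layer table: neuron %s absent from edges, kept isolated", name)
        c.add_neuron(name, layer=layer)
    return added


def load_position_table(c: Connectome, path) -> None:
    """Attach 1-D anterior-posterior soma positions from CSV ``neuron,position``."""
    df = pd.read_csv(path)
    df.columns = [c0.strip().lower() for c0 in df.columns]
    for _, row in df.iterrows():
        c.add_neuron(str(row["neuron"]).strip(), soma_position=float(row["position"]))


def write_layer_table(c: Connectome, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["neuron", "layer"])
        for n in c.neurons.values():
            w.writerow([n.name, n.layer])


def write_position_table(c: Connectome, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["neuron", "position"])
        for n in c.neurons.values():
            if n.soma_position is not None:
                w.writerow([n.name, repr(float(n.soma_position))])
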