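"""The 21-type triad taxonomy and common-neighbor-set extraction.

A *triad* is a pair of neurons (X, Y) plus one common neighbor Z, with role
identity preserved: X and Y are the pair, Z the shared neighbor.  The X-Y
dyad is forward (X->Y), reciprocal, or unconnected; each role-to-Z dyad is
one of X->Z, Z->X, or bidirectional (Z must be a neighbor, so "none" is
excluded).  With X and Y distinguishable only when the X-Y link is
unidirectional, this gives 9 + 6 + 6 = 21 canonical types.

Ids follow a lexicographic ordering of the Z-dyad states (out < in < both),
which places the field's named circuits at their conventional positions:
#1 multi-output FFL, #2 multi-inter FFL, #5 multi-input FFL, #10 mutually
regulating, #13 mutually regulated, #15 fully bidirectional.  Downstream
statistics key on the canonical dyad triple, not the id.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, product

from .connectome import Channel, Connectome, DyadState


class XYState(enum.Enum):
    FORWARD = "forward"
    RECIPROCAL = "reciprocal"
    NONE = "none"


class ZDyad(enum.IntEnum):
    """State of a role neuron's dyad with Z, from the role neuron's side."""

    OUT = 0   # role -> Z
    IN = 1    # Z -> role
    BOTH = 2  # bidirectional


_NAMES = {
    1: "multi_output_FFL",
    2: "multi_inter_FFL",
    5: "multi_input_FFL",
    10: "mutually_regulating",
    13: "mutually_regulated",
    15: "fully_bidirectional",
}


@dataclass(frozen=True)
class TriadType:
    id: int
    xy: XYState
    xz: ZDyad
    yz: ZDyad
    name: str | None = None

    @property
    def key(self) -> tuple:
        """Canonical dyad triple — the stable identity of the type."""
        return (self.xy.value, self.xz.name, self.yz.name)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        label = f" {self.name}" if self.name else ""
        return f"<Triad #{self.id}{label}: xy={self.xy.value} xz={self.xz.name} yz={self.yz.name}>"


@lru_cache(maxsize=1)
def enumerate_types() -> tuple[TriadType, ...]:
    """All 21 triad types in id order."""
    types: list[TriadType] = []
    i = 1
    for xz, yz in product(ZDyad, ZDyad):          # X, Y distinguishable
        types.append(TriadType(i, XYState.FORWARD, xz, yz, _NAMES.get(i)))
        i += 1
    for xy in (XYState.RECIPROCAL, XYState.NONE):  # X<->Y swap symmetric
        for xz, yz in product(ZDyad, ZDyad):
            if xz <= yz:
                types.append(TriadType(i, xy, xz, yz, _NAMES.get(i)))
                i += 1
    assert len(types) == 21
    return tuple(types)


@lru_cache(maxsize=1)
def _lookup() -> dict[tuple, TriadType]:
    return {t.key: t for t in enumerate_types()}


def type_by_id(tid: int) -> TriadType:
    for t in enumerate_types():
        if t.id == tid:
            return t
    raise KeyError(f"no triad type #{tid}")


def _zdyad(state: DyadState) -> ZDyad:
    """Role-to-Z DyadState (role as first argument) to a ZDyad."""
    if state is DyadState.FORWARD:
        return ZDyad.OUT
    if state is DyadState.BACKWARD:
        return ZDyad.IN
    if state is DyadState.RECIPROCAL:
        return ZDyad.BOTH
    raise ValueError("Z must be a common neighbor: dyad with Z cannot be 'none'")


def classify_triad(xy: DyadState | XYState, xz: DyadState | ZDyad,
                   yz: DyadState | ZDyad) -> TriadType:
    """Map a dyad-state triple to its canonical triad type.

    ``xy`` may be a pair DyadState (FORWARD meaning X->Y; BACKWARD is
    rejected — relabel the roles first) or an XYState.  ``xz``/``yz``
    accept either the role-first DyadState or a ZDyad.  When the X-Y dyad
    is reciprocal or absent, X and Y are interchangeable and (xz, yz) is
    canonicalized by sorting.
    """
    if isinstance(xy, DyadState):
        if xy is DyadState.BACKWARD:
            raise ValueError("xy=backward: swap X and Y before classifying")
        xy = XYState(xy.value)
    a = _zdyad(xz) if isinstance(xz, DyadState) else ZDyad(xz)
    b = _zdyad(yz) if isinstance(yz, DyadState) else ZDyad(yz)
    if xy is not XYState.FORWARD and a > b:
        a, b = b, a
    return _lookup()[(xy.value, a.name, b.name)]


@dataclass
class CommonNeighborSet:
    """A pair {X, Y} with all of its common neighbors, each classified."""

    x: str
    y: str
    connected: bool
    xy: XYState
    members: list[tuple[str, TriadType]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.members)

    def type_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for _, t in self.members:
            counts[t.id] = counts.get(t.id, 0) + 1
        return counts


def extract_sets(c: Connectome, min_neighbors: int = 5,
                 connected_only: bool = True,
                 channel: Channel | str = Channel.ALL) -> list[CommonNeighborSet]:
    """All common-neighbor sets with at least ``min_neighbors`` members.

    One set per unordered neuron pair; each common neighbor Z is classified
    by :func:`classify_triad`.  For a unidirectionally connected pair the X
    role goes to the presynaptic neuron; otherwise roles are interchangeable
    and X is the lexicographically smaller name.
    """
    if min_neighbors < 1:
        raise ValueError("min_neighbors must be >= 1")
    channel = Channel(channel)
    nbrs = c.neighbor_sets(channel)
    out: list[CommonNeighborSet] = []
    names = sorted(c.neurons)
    for a, b in combinations(names, 2):
        common = (nbrs[a] & nbrs[b]) - {a, b}
        if len(common) < min_neighbors:
            continue
        state = c.dyad_state(a, b, channel)
        if connected_only and state is DyadState.NONE:
            continue
        if state is DyadState.BACKWARD:
            x, y = b, a
            xy = XYState.FORWARD
        else:
            x, y = a, b
            xy = XYState(state.value) if state is not DyadState.NONE else XYState.NONE
        cns = CommonNeighborSet(x, y, state is not DyadState.NONE, xy)
        for z in sorted(common):
            cns.members.append(
                (z, classify_triad(xy, c.dyad_state(x, z, channel),
                                   c.dyad_state(y, z, channel)))
            )
        out.append(cns)
    return out
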