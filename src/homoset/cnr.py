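"""Common-neighbor-rule statistics and spatial-distance controls.

The common neighbor rule (CNR): the more common neighbors a pair of neurons
shares, the more likely the pair is to be connected.  ``cnr_curve`` bins all
unordered pairs by common-neighbor count and fits a line to the connected
fraction per bin.  ``distance_analysis`` checks that the rule is not a
by-product of spatial proximity along the 1-D anterior-posterior axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import Channel, Connectome, DyadState


def count_common(c: Connectome, x: str, y: str,
                 channel: Channel | str = Channel.ALL) -> int:
    """Number of neurons linked (either direction, either channel) to both."""
    if x == y:
        raise ValueError("count_common requires two distinct neurons")
    return len((c.neighbors(x, channel) & c.neighbors(y, channel)) - {x, y})


@dataclass
class CNRCurve:
    bins: pd.DataFrame          # columns: n_common, n_pairs, n_connected, fraction
    slope: float | None
    intercept: float | None
    r_squared: float | None
    bins_used: list[int]        # n_common values included in the fit
    fit_feasible: bool

    def to_dict(self) -> dict:
        return {
            "bins": self.bins.to_dict(orient="records"),
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "bins_used": self.bins_used,
            "fit_feasible": self.fit_feasible,
        }


def _pair_statistics(c: Connectome, channel: Channel | str = Channel.ALL
                     ) -> tuple[np.ndarray, np.ndarray]:
    """(common-neighbor count, connected flag) for every unordered pair.

    Uses the boolean symmetric adjacency: with a zero diagonal, (B @ B)[i, j]
    counts exactly the k != i, j adjacent to both.
    """
    _, adj = c.undirected_adjacency(channel)
    counts = (adj.astype(np.int32) @ adj.astype(np.int32))
    iu = np.triu_indices(len(adj), k=1)
    return counts[iu], adj[iu]


def cnr_curve(c: Connectome, min_pairs_per_bin: int = 5,
              weighted_fit: bool = False,
              channel: Channel | str = Channel.ALL) -> CNRCurve:
    """Connection probability vs number of common neighbors, with linear fit.

    Every unordered pair is binned by its common-neighbor count; a pair is
    connected iff its dyad state is not none.  The least-squares line is
    fitted over bins holding at least ``min_pairs_per_bin`` pairs (optionally
    weighting bins by pair count).  With fewer than two eligible bins the
    fit is flagged infeasible.
    """
    if len(c.neurons) < 3:
        raise ValueError("cnr_curve requires at least 3 neurons")
    common, connected = _pair_statistics(c, channel)
    df = (pd.DataFrame({"n_common": common, "connected": connected})
          .groupby("n_common")
          .agg(n_pairs=("connected", "size"), n_connected=("connected", "sum"))
          .reset_index())
    df["fraction"] = df["n_connected"] / df["n_pairs"]
    eligible = df[df["n_pairs"] >= min_pairs_per_bin]
    if len(eligible) < 2:
        return CNRCurve(df, None, None, None, [], False)
    x = eligible["n_common"].to_numpy(dtype=float)
    y = eligible["fraction"].to_numpy(dtype=float)
    if weighted_fit:
        w = eligible["n_pairs"].to_numpy(dtype=float)
        coef = np.polyfit(x, y, 1, w=np.sqrt(w))
        slope, intercept = float(coef[0]), float(coef[1])
        yhat = slope * x + intercept
        ybar = np.average(y, weights=w)
        ss_res = float(np.sum(w * (y - yhat) ** 2))
        ss_tot = float(np.sum(w * (y - ybar) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        res = stats.linregress(x, y)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue) ** 2
    return CNRCurve(df, slope, intercept, r2,
                    eligible["n_common"].astype(int).tolist(), True)


@dataclass
class DistanceResult:
    r: float | None
    p: float
    m: int
    mode: str               # cn_vs_distance | connectivity_vs_distance
    pair_scope: str         # all_pairs | connected_pairs
    tail: str = "negative"  # the tested alternative
    degenerate: bool = False

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def distance_analysis(c: Connectome, mode: str = "cn_vs_distance",
                      pair_scope: str = "all_pairs",
                      channel: Channel | str = Channel.ALL) -> DistanceResult:
    """Correlate pair statistics with inter-somatic distance.

    ``cn_vs_distance`` correlates the common-neighbor count with
    ``|pos_x - pos_y|`` over the chosen pair scope; ``connectivity_vs_distance``
    correlates a 0/1 connected indicator with distance over all pairs.  The
    one-tailed p for a negative correlation uses t = r*sqrt((m-2)/(1-r^2))
    with m-2 degrees of freedom.
    """
    if mode not in ("cn_vs_distance", "connectivity_vs_distance"):
        raise ValueError(f"unknown mode {mode!r}")
    if pair_scope not in ("all_pairs", "connected_pairs"):
        raise ValueError(f"unknown pair_scope {pair_scope!r}")
    names = c.names
    pos = np.array([np.nan if c.neurons[n].soma_position is None
                    else c.neurons[n].soma_position for n in names])
    if np.isnan(pos).any():
        missing = [n for n, p0 in zip(names, pos) if np.isnan(p0)]
        raise ValueError(f"missing soma positions for {len(missing)} neurons "
                         f"(e.g. {missing[:3]})")
    common, connected = _pair_statistics(c, channel)
    iu = np.triu_indices(len(names), k=1)
    dist = np.abs(pos[iu[0]] - pos[iu[1]])
    if mode == "connectivity_vs_distance":
        stat = connected.astype(float)
        scope = "all_pairs"
    else:
        stat = common.astype(float)
        scope = pair_scope
        if pair_scope == "connected_pairs":
            mask = connected
            stat, dist = stat[mask], dist[mask]
    m = len(stat)
    if m < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.std(stat) == 0 or np.std(dist) == 0:
        return DistanceResult(None, 1.0, m, mode, scope, degenerate=True)
    r = float(np.corrcoef(stat, dist)[0, 1])
    t = r * np.sqrt((m - 2) / (1.0 - r * r))
    p = float(stats.t.cdf(t, df=m - 2))   # lower tail: negative correlation
    return DistanceResult(r, p, m, mode, scope)
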