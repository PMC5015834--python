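"""Homogeneity scoring of common-neighbor sets.

A set is *homogeneous* when one triad type dominates it beyond chance: the
upper-tail hypergeometric probability of drawing at least k members of the
dominant type (given that type's abundance across all sets analyzed) is at
or below alpha, AND at least half the members are of that type.  The null
for the network-level comparison permutes the member triad labels across
all sets, conserving every set's size and the global type composition.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .connectome import Connectome
from .triads import CommonNeighborSet, TriadType, type_by_id

logger = logging.getLogger(__name__)


def hgt_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P[H >= k], H ~ HG(N, K, n).

    N population size, K successes in the population, n draws, k observed
    successes.  Computed by log-space summation of the exact pmf over the
    upper tail, which keeps full relative accuracy even deep in the tail
    (a plain 1 - cdf would not).
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent hypergeometric arguments "
                         f"k={k}, n={n}, K={K}, N={N}")
    if k <= 0:
        return 1.0
    support = np.arange(k, min(n, K) + 1)
    logp = stats.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


@dataclass
class HomogeneityResult:
    set: CommonNeighborSet
    dominant_type: TriadType
    k: int
    n: int
    K: int
    N: int
    p_hgt: float
    majority: bool
    homogeneous: bool

    def to_dict(self) -> dict:
        return {
            "x": self.set.x, "y": self.set.y, "connected": self.set.connected,
            "dominant_type": self.dominant_type.id,
            "dominant_key": self.dominant_type.key,
            "k": self.k, "n": self.n, "K": self.K, "N": self.N,
            "p_hgt": self.p_hgt, "majority": self.majority,
            "homogeneous": self.homogeneous,
        }


def assess_homogeneity(sets: list[CommonNeighborSet], alpha: float = 0.05,
                       majority_fraction: float = 0.5) -> list[HomogeneityResult]:
    """Score every set against the pooled triad-type abundances.

    The population for the test is pooled over the provided sets: K_j is the
    total count of type j across all members, N the total member count.  The
    dominant type of a set is its most frequent member type; ties break by
    smaller hypergeometric p, then lower canonical type order.
    """
    if not sets:
        raise ValueError("assess_homogeneity needs at least one set")
    K_by_type: dict[int, int] = {}
    N = 0
    for s in sets:
        for tid, cnt in s.type_counts().items():
            K_by_type[tid] = K_by_type.get(tid, 0) + cnt
        N += s.n
    out: list[HomogeneityResult] = []
    for s in sets:
        counts = s.type_counts()
        k_max = max(counts.values())
        candidates = sorted(tid for tid, cnt in counts.items() if cnt == k_max)
        best = min(candidates,
                   key=lambda tid: (hgt_pvalue(k_max, s.n, K_by_type[tid], N), tid))
        p = hgt_pvalue(k_max, s.n, K_by_type[best], N)
        majority = k_max >= majority_fraction * s.n
        out.append(HomogeneityResult(
            s, type_by_id(best), k_max, s.n, K_by_type[best], N, p,
            majority, bool(p <= alpha and majority)))
    return out


def shuffle_sets(sets: list[CommonNeighborSet],
                 seed: int | None = None) -> list[CommonNeighborSet]:
    """Permute member triad labels uniformly across all member slots.

    Every set keeps its size and its member (Z) names; the global multiset
    of triad labels is conserved exactly.  Shuffled sets are a statistical
    null construct: a member's label need not be consistent with the set's
    own X-Y dyad state.
    """
    if len(sets) < 2:
        return [copy.copy(s) for s in sets]
    rng = np.random.default_rng(seed)
    labels = [t for s in sets for (_, t) in s.members]
    perm = rng.permutation(len(labels))
    shuffled = [labels[i] for i in perm]
    out: list[CommonNeighborSet] = []
    pos = 0
    for s in sets:
        ns = CommonNeighborSet(s.x, s.y, s.connected, s.xy)
        ns.members = [(z, shuffled[pos + i]) for i, (z, _) in enumerate(s.members)]
        pos += s.n
        out.append(ns)
    return out


@dataclass
class NullComparison:
    scope: str                      # overall | per_type
    R: int
    seed: int | None
    n_real_homogeneous: int
    null_counts: list[int] = field(repr=False, default_factory=list)
    z: float = float("nan")
    p: float = float("nan")
    degenerate: bool = False
    per_type: dict[int, dict] = field(default_factory=dict)
    n_types_tested: int = 0

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "null_counts"}
        d["null_mean"] = float(np.mean(self.null_counts)) if self.null_counts else None
        d["null_std"] = (float(np.std(self.null_counts, ddof=1))
                         if len(self.null_counts) > 1 else None)
        d["per_type"] = {int(k): v for k, v in self.per_type.items()}
        return d


def _z_and_p(real: float, nulls: np.ndarray, R: int) -> tuple[float, float, bool]:
    mean = float(np.mean(nulls))
    sd = float(np.std(nulls, ddof=1)) if len(nulls) > 1 else 0.0
    if sd == 0.0:
        if real == mean:
            return 0.0, 1.0, True
        # degenerate null: report p as the resolution bound of the ensemble
        return float(np.sign(real - mean)) * float("inf"), 1.0 / (R + 1), True
    z = (real - mean) / sd
    return z, float(2 * stats.norm.sf(abs(z))), False


def enrichment_tests(sets: list[CommonNeighborSet], R: int = 100,
                     seed: int | None = None, alpha: float = 0.05,
                     majority_fraction: float = 0.5) -> NullComparison:
    """Real-vs-shuffled homogeneous-set counts, overall and per dominant type.

    Homogeneity is re-assessed on R label-shuffled replicas; per-type counts
    of homogeneous sets are compared by z-score with two-sided normal p,
    Bonferroni-corrected over the types tested (those occurring anywhere in
    the population).  A zero-variance null is flagged degenerate and its p
    reported as the bound 1/(R+1).
    """
    if R < 10:
        raise ValueError("R must be >= 10")
    real = assess_homogeneity(sets, alpha, majority_fraction)
    tested_types = sorted({t for s in sets for t in s.type_counts()})
    n_tests = len(tested_types)

    def _counts(results: list[HomogeneityResult]) -> tuple[int, dict[int, int]]:
        per = {t: 0 for t in tested_types}
        total = 0
        for r in results:
            if r.homogeneous:
                total += 1
                per[r.dominant_type.id] += 1
        return total, per

    real_total, real_per = _counts(real)
    rng = np.random.default_rng(seed)
    null_totals = np.zeros(R, dtype=int)
    null_per = {t: np.zeros(R, dtype=int) for t in tested_types}
    for r_i in range(R):
        sub = int(rng.integers(0, 2**31 - 1))
        shuffled = shuffle_sets(sets, seed=sub)
        tot, per = _counts(assess_homogeneity(shuffled, alpha, majority_fraction))
        null_totals[r_i] = tot
        for t, cnt in per.items():
            null_per[t][r_i] = cnt
    z, p, degen = _z_and_p(real_total, null_totals, R)
    out = NullComparison("overall", R, seed, real_total, null_totals.tolist(),
                         z, p, degen, n_types_tested=n_tests)
    for t in tested_types:
        zt, pt, dg = _z_and_p(real_per[t], null_per[t], R)
        p_bonf = min(1.0, pt * n_tests)
        out.per_type[t] = {
            "real": int(real_per[t]),
            "null_mean": float(np.mean(null_per[t])),
            "null_std": float(np.std(null_per[t], ddof=1)),
            "z": zt, "p": pt, "p_bonferroni": p_bonf,
            "significant": bool(p_bonf <= alpha and real_per[t] > np.mean(null_per[t])),
            "degenerate": dg,
        }
    return out


def synapse_coverage(c: Connectome, results: list[HomogeneityResult]) -> float:
    """Fraction of total synaptic weight touched by homogeneous sets.

    Counts the weight of every chemical and gap edge lying on the X-Y dyad
    or any X-Z / Y-Z member dyad of at least one homogeneous set, over the
    connectome's total weight.
    """
    total = c.total_weight()
    if total == 0:
        return 0.0
    chem_used: set[tuple[str, str]] = set()
    gap_used: set[frozenset] = set()

    def _mark(a: str, b: str) -> None:
        for pair in ((a, b), (b, a)):
            if pair in c.chem:
                chem_used.add(pair)
        key = frozenset((a, b))
        if key in c.gap:
            gap_used.add(key)

    for r in results:
        if not r.homogeneous:
            continue
        _mark(r.set.x, r.set.y)
        for z, _ in r.set.members:
            _mark(r.set.x, z)
            _mark(r.set.y, z)
    covered = sum(c.chem[e] for e in chem_used) + sum(c.gap[e] for e in gap_used)
    return covered / total


def is_bilateral_pair(a: str, b: str) -> bool:
    """True iff the two names differ only in a terminal L/R."""
    return (len(a) > 1 and len(a) == len(b) and a[:-1] == b[:-1]
            and {a[-1], b[-1]} == {"L", "R"})


def bilateral_ratio(results: list[HomogeneityResult]) -> tuple[float, float]:
    """(symmetric:asymmetric ratio among homogeneous sets, same among all).

    A pair is bilaterally symmetric iff the X and Y names differ only in a
    terminal L/R (the worm's left-right anatomical mirror pairs).
    """
    def _ratio(rs: list[HomogeneityResult]) -> float:
        sym = sum(1 for r in rs if is_bilateral_pair(r.set.x, r.set.y))
        asym = len(rs) - sym
        if asym == 0:
            return float("inf") if sym else 0.0
        return sym / asym

    return (_ratio([r for r in results if r.homogeneous]), _ratio(list(results)))
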