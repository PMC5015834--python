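"""Graded-potential dynamics of the headline circuit types.

C. elegans neurons are predominantly non-spiking and show graded responses,
so signal flow is modelled with Michaelis–Menten-type rate equations: each
unit's activity A_i obeys

    dA_i/dt = sum_chem sign * beta * A_pre / (K + A_pre)
            + sum_gap  g * (A_j - A_i)
            + s_i(t) - alpha * A_i

with beta the maximal synaptic drive, K the half-saturation constant,
g the (symmetric, diffusive) gap-junction coupling, alpha the activity
decay rate and s_i(t) a piecewise-constant external stimulus.  Integration
is fixed-step classical Runge–Kutta (RK4) for a reproducible test surface,
with step-halving as the convergence check.

Two circuits are built here: the *mutually regulating* configuration
(X<->Y chemical, both driving all Z's — a candidate amplifier /
short-term-memory device) and the *mutually regulated* configuration
(X-Y gap-coupled, both driven by all Z's — a candidate synchronizer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ChemLink:
    pre: str
    post: str
    beta: float = 1.0
    K: float = 1.0
    sign: int = 1

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.K <= 0:
            raise ValueError("beta and K must be positive")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")


@dataclass(frozen=True)
class GapLink:
    a: str
    b: str
    g: float = 1.0

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise ValueError("gap coupling g must be positive")


@dataclass(frozen=True)
class Pulse:
    """Rectangular stimulus pulse on [t_on, t_off) of the given amplitude."""
    t_on: float
    t_off: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("stimulus amplitudes must be >= 0")
        if self.t_off <= self.t_on:
            raise ValueError("pulse must have positive duration")


@dataclass
class CircuitSpec:
    nodes: list[str]
    chem: list[ChemLink] = field(default_factory=list)
    gap: list[GapLink] = field(default_factory=list)
    alpha: dict[str, float] = field(default_factory=dict)   # decay per node
    stimuli: dict[str, list[Pulse]] = field(default_factory=dict)

    def decay(self, node: str) -> float:
        return self.alpha.get(node, 1.0)


def build_circuit(set_type: str, connected: bool = True, n_z: int = 2,
                  alpha: float = 1.0, beta: float = 1.0, K: float = 1.0,
                  g: float = 1.0,
                  chem_overrides: dict[tuple[str, str], dict] | None = None,
                  stimuli: dict[str, list[Pulse]] | None = None) -> CircuitSpec:
    """Build a mutually regulating or mutually regulated model circuit.

    ``mutually_regulating``: chemical X<->Y (present iff connected) plus
    chemical X->Z_i and Y->Z_i.  Default stimulus: one brief pulse
    (amplitude 1, duration 1) to X.

    ``mutually_regulated``: gap junction X-Y (present iff connected) plus
    chemical Z_i->X and Z_i->Y.  Default stimulus: unsynchronized pulses to
    Z_1 and Z_2 (second pulse offset by half the pulse width).

    ``chem_overrides`` patches individual links, e.g.
    ``{("Z1", "X"): {"beta": 2.0, "K": 10.0}}``.
    """
    if n_z < 1:
        raise ValueError("n_z must be >= 1")
    zs = [f"Z{i + 1}" for i in range(n_z)]
    nodes = ["X", "Y", *zs]
    overrides = chem_overrides or {}

    def link(pre: str, post: str) -> ChemLink:
        o = overrides.get((pre, post), {})
        return ChemLink(pre, post, beta=o.get("beta", beta),
                        K=o.get("K", K), sign=o.get("sign", 1))

    spec = CircuitSpec(nodes, alpha={n: alpha for n in nodes})
    if set_type in ("mutually_regulating", "mr10", "10"):
        if connected:
            spec.chem += [link("X", "Y"), link("Y", "X")]
        for z in zs:
            spec.chem += [link("X", z), link("Y", z)]
        default_stim = {"X": [Pulse(1.0, 2.0, 1.0)]}
    elif set_type in ("mutually_regulated", "mr13", "13"):
        if connected:
            spec.gap.append(GapLink("X", "Y", g=g))
        for z in zs:
            spec.chem += [link(z, "X"), link(z, "Y")]
        default_stim = {"Z1": [Pulse(1.0, 2.0, 1.0)]}
        if n_z >= 2:
            default_stim["Z2"] = [Pulse(1.5, 2.5, 1.0)]
    else:
        raise ValueError(f"unknown set_type {set_type!r}")
    spec.stimuli = stimuli if stimuli is not None else default_stim
    return spec


@dataclass
class SimulationResult:
    t: np.ndarray
    activity: dict[str, np.ndarray]
    dt: float
    step_halving_error: float | None = None

    def __getitem__(self, node: str) -> np.ndarray:
        return self.activity[node]


def _rhs(spec: CircuitSpec, idx: dict[str, int], t: float,
         a: np.ndarray) -> np.ndarray:
    da = np.zeros_like(a)
    for n, i in idx.items():
        da[i] = -spec.decay(n) * a[i]
        for pulse in spec.stimuli.get(n, ()):
            if pulse.t_on <= t < pulse.t_off:
                da[i] += pulse.amplitude
    for ln in spec.chem:
        pre = a[idx[ln.pre]]
        da[idx[ln.post]] += ln.sign * ln.beta * pre / (ln.K + pre)
    for gl in spec.gap:
        i, j = idx[gl.a], idx[gl.b]
        flow = gl.g * (a[j] - a[i])
        da[i] += flow
        da[j] -= flow
    return da


def simulate(spec: CircuitSpec, t_end: float = 20.0, dt: float = 0.01,
             check_convergence: bool = False,
             convergence_tol: float = 1e-3) -> SimulationResult:
    """Integrate the circuit from a zero initial state with fixed-step RK4.

    With ``check_convergence`` the integration is repeated at dt/2 and the
    maximum trajectory discrepancy recorded; exceeding ``convergence_tol``
    raises.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")

    def _run(step: float) -> tuple[np.ndarray, np.ndarray]:
        idx = {n: i for i, n in enumerate(spec.nodes)}
        n_steps = int(round(t_end / step))
        t = np.linspace(0.0, n_steps * step, n_steps + 1)
        traj = np.zeros((n_steps + 1, len(spec.nodes)))
        a = np.zeros(len(spec.nodes))
        for s in range(n_steps):
            t0 = t[s]
            k1 = _rhs(spec, idx, t0, a)
            k2 = _rhs(spec, idx, t0 + step / 2, a + step / 2 * k1)
            k3 = _rhs(spec, idx, t0 + step / 2, a + step / 2 * k2)
            k4 = _rhs(spec, idx, t0 + step, a + step * k3)
            a = a + step / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            traj[s + 1] = a
        return t, traj

    t, traj = _run(dt)
    err = None
    if check_convergence:
        _, traj_half = _run(dt / 2)
        err = float(np.max(np.abs(traj - traj_half[::2])))
        if err > convergence_tol:
            raise RuntimeError(f"step-halving discrepancy {err:.2e} exceeds "
                               f"tolerance {convergence_tol:.2e}")
    return SimulationResult(
        t, {n: traj[:, i] for i, n in enumerate(spec.nodes)}, dt, err)


def amplification_metrics(result: SimulationResult, node: str,
                          threshold: float) -> tuple[float, float]:
    """(peak activity, total time spent above threshold) for one node."""
    a = result[node]
    peak = float(np.max(a))
    time_above = float(np.sum(a > threshold) * result.dt)
    return peak, time_above


def coordination_metric(result: SimulationResult, a: str, b: str) -> float:
    """Maximal instantaneous activity difference between two nodes."""
    return float(np.max(np.abs(result[a] - result[b])))
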