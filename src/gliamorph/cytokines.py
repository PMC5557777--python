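"""Two-compartment cytokine network dynamics with Hill kinetics.

The microglial compartment tracks six cytokines (TNFa, IL-1b, IL-6, TGFb,
IL-10, CCL5).  Each species x follows

    dCx/dt = (1 + kx * LPS/(LPS + K_LPS))
             * prod_i Ci^n/(Ci^n + Kix^n)        (activators)
             * prod_j Kjx^n/(Cj^n + Kjx^n)       (inhibitors)
             - gamma_x * Cx - gamma_ss_x * C_ss_x,

where the LPS multiplier applies only to LPS-responsive species (all but
TGFb) during the stimulus window.  The concentration-independent degradation
constant gamma_ss_x is derived so that dCx/dt = 0 at the common resting level
C_ss = 0.1 with no stimulus; networks therefore hold their steady state
exactly until perturbed.

The CNS-environment compartment is a linear delay cascade converting
microglial IL-10 into environmental TGFb:

    tau dA1/dt = kA * M_IL10 - gA * A1,
    tau dAi/dt = kA * A(i-1) - gA * Ai,   i = 2..n,

whose output A_n feeds inhibition edges back onto microglial IL-1b and IL-6.
Knockouts remove a node and its incident edges and re-derive the steady-state
degradation constants of the remaining species.

Default topology: LPS drives TNFa, IL-1b, IL-6, IL-10 and CCL5; TNFa
activates IL-1b, IL-6, IL-10 and CCL5; IL-10 inhibits TNFa, IL-1b and IL-6;
microglial TGFb inhibits TNFa; microglial IL-10 drives the CNS cascade whose
TGFb output inhibits IL-1b and IL-6.  Parameter values are the package's own
defaults chosen so the qualitative behavior (knockout amplifies the TNFa
response but enhances its adaptive recovery at low doses) is reproduced; they
are not literature estimates.  Time is in hours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "Edge",
    "CascadeSpec",
    "StimulusSpec",
    "CytokineNetwork",
    "Trajectory",
    "default_network",
    "derive_steady_degradation",
    "rhs",
    "simulate",
    "knockout",
    "trajectory_adaptation",
    "dose_response",
]

MICROGLIAL_SPECIES = ("TNFa", "IL1b", "IL6", "TGFb", "IL10", "CCL5")
CASCADE_OUTPUT = "A_TGF"  # symbolic source name for the cascade's last stage


@dataclass(frozen=True)
class Edge:
    """One regulatory interaction: ``source`` modulates ``target`` production."""

    source: str
    target: str
    sign: str  # "activate" | "inhibit"
    K: float
    n: float

    def __post_init__(self):
        if self.sign not in ("activate", "inhibit"):
            raise ValueError(f"edge sign must be activate/inhibit, got {self.sign!r}")
        if self.K <= 0 or self.n <= 0:
            raise ValueError("Hill parameters K and n must be positive")


@dataclass(frozen=True)
class CascadeSpec:
    """Linear first-order delay chain from microglial IL-10 to CNS TGFb."""

    n_stages: int = 3
    tau: float = 6.0      # h
    k_A: float = 0.5      # 1/h
    gamma_A: float = 0.5  # 1/h
    source: str = "IL10"

    def __post_init__(self):
        if self.n_stages < 1:
            raise ValueError("cascade needs at least one stage")
        if min(self.tau, self.k_A, self.gamma_A) <= 0:
            raise ValueError("cascade rate constants must be positive")

    def steady_state(self, source_level: float) -> np.ndarray:
        """Stage levels at which all cascade derivatives vanish."""
        ratio = self.k_A / self.gamma_A
        return source_level * ratio ** np.arange(1, self.n_stages + 1)


@dataclass(frozen=True)
class StimulusSpec:
    """Square-pulse LPS stimulus (arbitrary concentration units)."""

    magnitude: float = 1.0
    onset: float = 0.0     # h
    duration: float = 16.0  # h

    def __post_init__(self):
        if self.magnitude < 0:
            raise ValueError("LPS magnitude must be non-negative")
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")

    @property
    def offset(self) -> float:
        return self.onset + self.duration

    def level(self, t: float) -> float:
        return self.magnitude if self.onset <= t < self.offset else 0.0


_DEFAULT_K_ACT = 0.25
_DEFAULT_K_INH = 0.6
_DEFAULT_N = 1.5
# IL-10 is parameterized as a slow integrator of the inflammatory response:
# weak basal drive (large half-saturation on its TNFa input), weak direct LPS
# gain, slow turnover, and a soft inhibition constant on TNFa.  Its long tail
# after a transient stimulus is what impedes TNFa recovery in the wild type.
_K_ACT_TNF_IL10 = 3.0
_K_INH_IL10_TNF = 2.0


def _default_edges() -> tuple[Edge, ...]:
    act = lambda s, t, K=_DEFAULT_K_ACT: Edge(s, t, "activate", K, _DEFAULT_N)
    inh = lambda s, t, K=_DEFAULT_K_INH: Edge(s, t, "inhibit", K, _DEFAULT_N)
    return (
        act("TNFa", "IL1b"),
        act("TNFa", "IL6"),
        act("TNFa", "IL10", _K_ACT_TNF_IL10),
        act("TNFa", "CCL5"),
        inh("IL10", "TNFa", _K_INH_IL10_TNF),
        inh("IL10", "IL1b"),
        inh("IL10", "IL6"),
        inh("TGFb", "TNFa"),
        inh(CASCADE_OUTPUT, "IL1b"),
        inh(CASCADE_OUTPUT, "IL6"),
    )


@dataclass(frozen=True)
class CytokineNetwork:
    """Node/edge parameterization of the two-compartment model."""

    species: tuple[str, ...] = MICROGLIAL_SPECIES
    edges: tuple[Edge, ...] = field(default_factory=_default_edges)
    k_lps: dict = field(
        default_factory=lambda: {s: (0.5 if s == "IL10" else 6.0) for s in MICROGLIAL_SPECIES}
    )
    K_LPS: float = 1.0
    lps_responsive: tuple[str, ...] = tuple(s for s in MICROGLIAL_SPECIES if s != "TGFb")
    gamma: dict = field(
        default_factory=lambda: {s: (0.02 if s == "IL10" else 1.0) for s in MICROGLIAL_SPECIES}
    )
    C_ss: float = 0.1
    cascade: Optional[CascadeSpec] = field(default_factory=CascadeSpec)

    def __post_init__(self):
        if self.C_ss <= 0 or self.K_LPS <= 0:
            raise ValueError("C_ss and K_LPS must be positive")
        for s in self.species:
            if self.gamma.get(s, 0) <= 0:
                raise ValueError(f"gamma missing or non-positive for {s}")
            if self.k_lps.get(s, 0) <= 0:
                raise ValueError(f"k_lps missing or non-positive for {s}")
        known = set(self.species) | {CASCADE_OUTPUT}
        for e in self.edges:
            if e.source not in known or e.target not in self.species:
                raise ValueError(f"edge references unknown species: {e}")
        if "TGFb" in self.species and "TGFb" in self.lps_responsive:
            raise ValueError("TGFb is not LPS-responsive")

    # -- steady-state helpers ------------------------------------------------

    def steady_source_level(self, source: str) -> float:
        """Resting level of an edge source (cascade output included)."""
        if source == CASCADE_OUTPUT:
            if self.cascade is None:
                return 0.0
            src_level = self.C_ss if self.cascade.source in self.species else 0.0
            return float(self.cascade.steady_state(src_level)[-1])
        return self.C_ss

    def production_at_steady_state(self, target: str) -> float:
        """Eq.-3 production product at rest (LPS = 0, all regulators at rest)."""
        prod = 1.0
        for e in self.edges:
            if e.target != target:
                continue
            c = self.steady_source_level(e.source)
            cn, kn = c ** e.n, e.K ** e.n
            prod *= cn / (cn + kn) if e.sign == "activate" else kn / (cn + kn)
        return prod


def derive_steady_degradation(network: CytokineNetwork) -> dict[str, float]:
    """Concentration-independent degradation rates pinning the resting state.

    gamma_ss_x = P_ss_x / C_ss - gamma_x, with P_ss_x the unstimulated
    production term; plugging these back makes dCx/dt vanish at C = C_ss.
    """
    out = {}
    for s in network.species:
        p_ss = network.production_at_steady_state(s)
        g_ss = p_ss / network.C_ss - network.gamma[s]
        if g_ss < 0:
            raise ValueError(
                f"steady-state degradation negative for {s} "
                f"(production {p_ss:.4g} too weak for gamma={network.gamma[s]})"
            )
        out[s] = g_ss
    return out


def _hill(c: float, K: float, n: float, sign: str) -> float:
    cn = c ** n if c > 0 else 0.0
    kn = K ** n
    return cn / (cn + kn) if sign == "activate" else kn / (cn + kn)


def rhs(
    t: float,
    state: np.ndarray,
    network: CytokineNetwork,
    gamma_ss: dict[str, float],
    lps: float,
) -> np.ndarray:
    """Derivative vector for the stacked [microglial..., cascade...] state."""
    ns = len(network.species)
    conc = dict(zip(network.species, np.maximum(state[:ns], 0.0)))
    casc = np.maximum(state[ns:], 0.0)
    a_out = casc[-1] if casc.size else 0.0

    dy = np.empty_like(state)
    for i, s in enumerate(network.species):
        prod = 1.0
        for e in network.edges:
            if e.target != s:
                continue
            c = a_out if e.source == CASCADE_OUTPUT else conc.get(e.source, 0.0)
            prod *= _hill(c, e.K, e.n, e.sign)
        if lps > 0 and s in network.lps_responsive:
            prod *= 1.0 + network.k_lps[s] * lps / (lps + network.K_LPS)
        dy[i] = prod - network.gamma[s] * conc[s] - gamma_ss[s] * network.C_ss

    if casc.size:
        cas = network.cascade
        src = conc.get(cas.source, 0.0)
        dy[ns] = (cas.k_A * src - cas.gamma_A * casc[0]) / cas.tau
        for i in range(1, casc.size):
            dy[ns + i] = (cas.k_A * casc[i - 1] - cas.gamma_A * casc[i]) / cas.tau
    return dy


@dataclass
class Trajectory:
    """Simulated concentration time courses for both compartments."""

    times: np.ndarray              # hours
    data: pd.DataFrame             # time-indexed, one column per state variable
    network: CytokineNetwork
    stimulus: StimulusSpec

    def species(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()


def _state_names(network: CytokineNetwork) -> list[str]:
    names = list(network.species)
    if network.cascade is not None:
        names += [f"{CASCADE_OUTPUT}{i + 1}" for i in range(network.cascade.n_stages)]
    return names


def initial_state(network: CytokineNetwork) -> np.ndarray:
    ns = len(network.species)
    y0 = np.full(ns, network.C_ss)
    if network.cascade is not None:
        src = network.C_ss if network.cascade.source in network.species else 0.0
        y0 = np.concatenate([y0, network.cascade.steady_state(src)])
    return y0


def simulate(
    network: CytokineNetwork,
    stimulus: StimulusSpec,
    t_end: float = 720.0,
    report_dt: float = 0.5,
    rtol: float = 1e-9,
    atol: float = 1e-11,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the network through a square LPS pulse.

    The integration is split at the stimulus on/off times so the solver never
    steps across the discontinuity, and results are reported on a uniform
    grid.  Concentrations are floored at zero in the reported trajectory.
    """
    if t_end <= stimulus.offset:
        raise ValueError("t_end must exceed the stimulus end")
    gamma_ss = derive_steady_degradation(network)
    y0 = initial_state(network)
    grid = np.arange(0.0, t_end + report_dt / 2, report_dt)

    breakpoints = [0.0]
    for b in (stimulus.onset, stimulus.offset):
        if 0.0 < b < t_end:
            breakpoints.append(b)
    breakpoints.append(t_end)

    times_out, states_out = [], []
    y = y0
    for a, b in zip(breakpoints, breakpoints[1:]):
        lps = stimulus.level((a + b) / 2.0) if stimulus.magnitude > 0 else 0.0
        t_eval = grid[(grid >= a) & (grid <= b)]
        if t_eval.size == 0 or t_eval[0] > a:
            t_eval = np.concatenate([[a], t_eval])
        if t_eval[-1] < b:
            t_eval = np.concatenate([t_eval, [b]])
        sol = solve_ivp(
            rhs, (a, b), y, t_eval=t_eval, args=(network, gamma_ss, lps),
            method=method, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed on [{a}, {b}]: {sol.message}")
        y = sol.y[:, -1]
        times_out.append(sol.t)
        states_out.append(sol.y)

    t_all = np.concatenate(times_out)
    y_all = np.concatenate(states_out, axis=1)
    keep = np.isin(t_all, grid)
    t_all, y_all = t_all[keep], y_all[:, keep]
    t_all, uniq = np.unique(t_all, return_index=True)
    y_all = y_all[:, uniq]
    data = pd.DataFrame(
        np.maximum(y_all.T, 0.0), index=pd.Index(t_all, name="time_h"),
        columns=_state_names(network),
    )
    return Trajectory(times=t_all, data=data, network=network, stimulus=stimulus)


def knockout(network: CytokineNetwork, species: str) -> CytokineNetwork:
    """Remove a node and its incident edges; steady state is re-derived downstream."""
    if species not in network.species:
        raise KeyError(f"unknown species: {species!r}")
    new_species = tuple(s for s in network.species if s != species)
    new_edges = tuple(
        e for e in network.edges if e.source != species and e.target != species
    )
    return replace(
        network,
        species=new_species,
        edges=new_edges,
        k_lps={s: v for s, v in network.k_lps.items() if s != species},
        gamma={s: v for s, v in network.gamma.items() if s != species},
        lps_responsive=tuple(s for s in network.lps_responsive if s != species),
    )


def trajectory_adaptation(trajectory: Trajectory, species: str = "TNFa") -> float:
    """Recovery index of a simulated curve: A = 1 - |dev_final| / |dev_peak|.

    Deviations are measured from the initial (baseline) level; the peak is the
    largest absolute excursion after t = 0.  A residual offset on either side
    of baseline counts as incomplete recovery.  Returns NaN (with a warning)
    when the curve never leaves baseline.
    """
    c = trajectory.species(species)
    c0 = c[0]
    dev = c - c0
    if dev[1:].size == 0 or np.max(np.abs(dev[1:])) < 1e-12:
        warnings.warn(f"no excursion for {species}; adaptation undefined")
        return float("nan")
    peak = np.max(np.abs(dev[1:]))
    return float(1.0 - abs(dev[-1]) / peak)


def peak_response(trajectory: Trajectory, species: str = "TNFa") -> float:
    return float(trajectory.species(species).max())


def default_network() -> CytokineNetwork:
    return CytokineNetwork()


def dose_response(
    network: CytokineNetwork,
    doses: Sequence[float],
    variants: Sequence[str] = ("wt", "ko"),
    ko_species: str = "IL10",
    t_end: float = 120.0,
    duration: float = 16.0,
    species: str = "TNFa",
    report_dt: float = 0.25,
) -> pd.DataFrame:
    """Peak response and adaptation index per LPS dose for WT and knockout."""
    doses = np.asarray(list(doses), dtype=float)
    if np.any(doses <= 0) or np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be positive and strictly increasing")
    nets = {}
    for v in variants:
        if v == "wt":
            nets[v] = network
        elif v == "ko":
            nets[v] = knockout(network, ko_species)
        else:
            raise ValueError(f"unknown variant: {v!r}")
    rows = []
    for v, net in nets.items():
        for dose in doses:
            traj = simulate(
                net, StimulusSpec(magnitude=float(dose), duration=duration),
                t_end=t_end, report_dt=report_dt, rtol=1e-8, atol=1e-10,
            )
            rows.append(
                {
                    "variant": v,
                    "dose": float(dose),
                    "peak": peak_response(traj, species),
                    "adaptation": trajectory_adaptation(traj, species),
                }
            )
    return pd.DataFrame(rows)
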