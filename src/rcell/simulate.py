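"""Deterministic integration, steady-state detection and optimality scans.

Steady states are found by integrating the stiff ODE system (LSODA) over a
72-h horizon by default and declaring convergence once the squared-and-summed
*relative* change of every variable over a trailing 12-h window drops below
1e-6.  Heavy-burden sweeps may need the horizon extended (up to 480 h).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import fastss
from .circuits import EMPTY_CIRCUIT, CircuitSpec, circuit_rhs
from .host import derived_rates, native_k
from .params import (
    HOST_STATE_NAMES,
    ChloramphenicolParams,
    DerivedRates,
    HostParams,
    HostState,
)

__all__ = [
    "Trajectory",
    "SteadyState",
    "NoBurdenReference",
    "default_initial_state",
    "integrate",
    "steady_state",
    "no_burden_reference",
    "constant_T_optimal_growth",
    "multi_start_steady_states",
]


@dataclass
class Trajectory:
    """Time-stamped record of a (possibly stochastic) simulation."""

    times: np.ndarray                 # (n_t,), hours, strictly increasing
    states: np.ndarray                # (n_t, n_var)
    names: list[str]                  # variable names, host first
    params: HostParams
    spec: CircuitSpec
    cm: ChloramphenicolParams | None = None
    seed: int | None = None

    @property
    def sigma(self) -> float:
        return self.params.sigma

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.names.index(name)]

    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def derived_at(self, i: int) -> DerivedRates:
        return _derived_from_vector(self.states[i], self.params, self.spec, self.cm)

    def derived_final(self) -> DerivedRates:
        return self.derived_at(len(self.times) - 1)


@dataclass
class SteadyState:
    """A converged-state summary with convergence metadata."""

    x: np.ndarray                     # full state vector
    names: list[str]
    derived: DerivedRates
    converged: bool
    horizon_used: float               # h
    residual: float                   # sum of squared relative 12-h changes
    params: HostParams
    spec: CircuitSpec
    cm: ChloramphenicolParams | None = None

    def __getitem__(self, name: str) -> float:
        return float(self.x[self.names.index(name)])

    @property
    def host(self) -> HostState:
        with_cm = "B_cm" in self.names
        return HostState.from_array(self.x, with_cm=with_cm)

    @property
    def lam(self) -> float:
        return self.derived.lam

    def circuit_values(self) -> dict[str, float]:
        n_host = 7 if "B_cm" in self.names else 6
        return dict(zip(self.names[n_host:], self.x[n_host:]))

    def modeled_protein_mass(self) -> float:
        """n_a*p_a + n_r*(R + B_cm) + sum(n_x*p_x), in nM-aa."""
        mass = self.params.n_a * self["p_a"] + self.params.n_r * self["R"]
        if "B_cm" in self.names:
            mass += self.params.n_r * self["B_cm"]
        for g in self.spec.genes:
            mass += g.n * self[f"p_{g.name}"]
        return mass


@dataclass
class NoBurdenReference:
    """Host-only steady-state anchors used by all analytical burden formulas."""

    sigma: float
    eps_NB: float
    F_r_NB: float
    lambda_NB: float
    k_NB: dict[str, float] = field(default_factory=dict)
    D_NB: float = 0.0
    state: SteadyState | None = None


def _names(spec: CircuitSpec, cm: ChloramphenicolParams | None) -> list[str]:
    host = list(HOST_STATE_NAMES) + (["B_cm"] if cm is not None else [])
    return host + spec.species_names()


def _split(x: np.ndarray, spec: CircuitSpec, cm) -> tuple[HostState, np.ndarray]:
    n_host = 7 if cm is not None else 6
    host = HostState.from_array(x[:n_host], with_cm=cm is not None)
    return host, x[n_host:]


def _derived_from_vector(x, params, spec, cm) -> DerivedRates:
    host, circ = _split(np.maximum(x, 0.0), spec, cm)
    tox = 1.0
    for g, i in zip(spec.genes, range(0, 2 * len(spec.genes), 2)):
        if g.toxicity_K is not None:
            tox += circ[i + 1] / g.toxicity_K
    if tox != 1.0:
        params = params.replace(eps_max=params.eps_max / tox)
    eps = params.eps_max * host.t_c / (host.t_c + params.K_eps) if host.t_c > 0 else 0.0
    extra = {g.name: (m, g.k(eps, cm))
             for g, m in zip(spec.genes, circ[0:2 * len(spec.genes):2])}
    return derived_rates(host, params, extra_mrnas=extra, cm=cm)


def build_rhs(
    params: HostParams,
    spec: CircuitSpec,
    cm: ChloramphenicolParams | None = None,
    fixed_T: float | None = None,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Right-hand side of the combined host+circuit system as f(t, x)."""

    def f(t: float, x: np.ndarray) -> np.ndarray:
        host, circ = _split(np.maximum(x, 0.0), spec, cm)
        dhost, dcirc = circuit_rhs(host, circ, params, spec, cm=cm, t=t,
                                   fixed_T=fixed_T)
        return np.concatenate([dhost, dcirc])

    return f


def default_initial_state(
    params: HostParams,
    spec: CircuitSpec = EMPTY_CIRCUIT,
    cm: ChloramphenicolParams | None = None,
) -> np.ndarray:
    """Generic positive initial condition; steady states do not depend on it."""
    host = [100.0, 100.0, params.M / (4 * params.n_a), params.M / (4 * params.n_r),
            80.0, 80.0]
    if cm is not None:
        host.append(0.0)
    return np.array(host + [0.0] * spec.n_species)


def integrate(
    params: HostParams,
    spec: CircuitSpec = EMPTY_CIRCUIT,
    t_span: float | tuple[float, float] = 72.0,
    init: np.ndarray | None = None,
    cm: ChloramphenicolParams | None = None,
    fixed_T: float | None = None,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-6,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the combined ODE system over ``t_span`` hours.

    Integration is split at gene onset times so step inputs (disturbance
    induction) are resolved exactly.
    """
    t0, t1 = (0.0, float(t_span)) if np.isscalar(t_span) else map(float, t_span)
    if t1 <= t0:
        raise ValueError("t_span must be positive")
    x0 = default_initial_state(params, spec, cm) if init is None else np.asarray(init, float)
    breaks = sorted({g.onset_time for g in spec.genes if t0 < g.onset_time < t1})
    edges = [t0] + breaks + [t1]
    f = build_rhs(params, spec, cm, fixed_T)
    if t_eval is None:
        t_eval = np.linspace(t0, t1, max(int(t1 - t0) + 1, 50))
    times_out, states_out = [], []
    x = x0
    for a, b in zip(edges[:-1], edges[1:]):
        te = t_eval[(t_eval >= a) & (t_eval <= b)]
        if len(te) == 0 or te[0] > a:
            te = np.concatenate([[a], te])
        if te[-1] < b:
            te = np.concatenate([te, [b]])
        sol = solve_ivp(f, (a, b), x, method=method, t_eval=te,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(
                f"ODE solver failed at t={sol.t[-1] if len(sol.t) else a:.3f} h: "
                f"{sol.message}; last state {sol.y[:, -1] if sol.y.size else x}"
            )
        times_out.append(sol.t)
        states_out.append(sol.y.T)
        x = sol.y[:, -1]
    times = np.concatenate(times_out)
    states = np.vstack(states_out)
    keep = np.concatenate([[True], np.diff(times) > 0])
    return Trajectory(times=times[keep], states=np.maximum(states[keep], 0.0),
                      names=_names(spec, cm), params=params, spec=spec, cm=cm)


def _window_residual(states: np.ndarray, i_now: int, i_then: int) -> float:
    now, then = states[i_now], states[i_then]
    scale = np.maximum(np.abs(now), 1e-6)
    return float(np.sum(((now - then) / scale) ** 2))


def steady_state(
    params: HostParams,
    spec: CircuitSpec = EMPTY_CIRCUIT,
    cm: ChloramphenicolParams | None = None,
    horizon: float = 72.0,
    window: float = 12.0,
    tol: float = 1e-6,
    init: np.ndarray | None = None,
    fixed_T: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-6,
    method: str = "LSODA",
) -> SteadyState:
    """Integrate up to ``horizon`` h and report the trailing-window residual.

    The residual is evaluated on a 1-h cadence against the state ``window``
    hours earlier; convergence is declared at the first time it falls below
    ``tol``.  Non-convergence yields ``converged=False``, never an exception.
    """
    if horizon < window:
        raise ValueError("horizon must be at least one window long")
    t_eval = np.arange(0.0, horizon + 0.5, 1.0)
    traj = integrate(params, spec, (0.0, horizon), init=init, cm=cm,
                     fixed_T=fixed_T, t_eval=t_eval, rtol=rtol, atol=atol,
                     method=method)
    # snap to the hourly grid (integrate() may insert onset-time points)
    idx = np.searchsorted(traj.times, t_eval)
    idx = np.clip(idx, 0, len(traj.times) - 1)
    states = traj.states[idx]
    w = int(window)
    converged, horizon_used, residual = False, horizon, np.inf
    for i in range(w, len(t_eval)):
        residual = _window_residual(states, i, i - w)
        if residual < tol:
            converged, horizon_used = True, float(t_eval[i])
            break
    x_final = states[i] if converged else traj.final_state()
    d = _derived_from_vector(x_final, params, spec, cm)
    return SteadyState(x=x_final, names=traj.names, derived=d,
                       converged=converged, horizon_used=horizon_used,
                       residual=residual, params=params, spec=spec, cm=cm)


def fast_steady_state(
    params: HostParams,
    spec: CircuitSpec = EMPTY_CIRCUIT,
    cm: ChloramphenicolParams | None = None,
    sigma: float | None = None,
    fixed_T: float | None = None,
) -> SteadyState:
    """Algebraic steady state (host + constitutive genes); see `rcell.fastss`."""
    sol = fastss.solve_host_steady_state(
        params, cm=cm, spec=spec if spec.genes else None,
        sigma=sigma, fixed_T=-1.0 if fixed_T is None else fixed_T,
    )
    p = params if sigma is None else params.replace(sigma=sigma)
    host = [sol["m_a"], sol["m_r"], sol["p_a"], sol["R"], sol["t_c"], sol["t_u"]]
    if cm is not None:
        host.append(sol["B_cm"])
    circ = []
    for g in spec.genes:
        circ += [sol["genes"][g.name]["m"], sol["genes"][g.name]["p"]]
    x = np.array(host + circ)
    d = _derived_from_vector(x, p, spec, cm)
    if fixed_T is not None:
        # regulation frozen at F_r(fixed_T); report the frozen values
        d.F_r = fixed_T / (fixed_T + p.tau)
        d.psi = p.psi_max * d.F_r
    return SteadyState(x=x, names=_names(spec, cm), derived=d, converged=True,
                       horizon_used=0.0, residual=0.0, params=p, spec=spec, cm=cm)


def no_burden_reference(
    params: HostParams,
    sigma: float | None = None,
    genes: Sequence = (),
    method: str = "fast",
) -> NoBurdenReference:
    """Steady-state anchors of the bare host at nutrient quality ``sigma``.

    ``genes`` may list GeneSpec objects whose no-burden apparent dissociation
    constants k^NB (evaluated at eps^NB) should be included.
    """
    sig = params.sigma if sigma is None else sigma
    if not 0.0 < sig <= 1.0:
        raise ValueError(f"sigma must lie in (0, 1], got {sig}")
    p = params.replace(sigma=sig)
    if method == "fast":
        ss = fast_steady_state(p)
    else:
        ss = steady_state(p)
        if not ss.converged:
            raise RuntimeError(f"no-burden steady state did not converge at sigma={sig}")
    eps_NB = ss.derived.eps
    k_NB = dict(native_k(eps_NB, p))
    for g in genes:
        k_NB[g.name] = g.k(eps_NB)
    return NoBurdenReference(sigma=sig, eps_NB=eps_NB, F_r_NB=ss.derived.F_r,
                            lambda_NB=ss.derived.lam, k_NB=k_NB,
                            D_NB=ss.derived.D, state=ss)


def constant_T_optimal_growth(
    params: HostParams,
    sigma: float | None = None,
    T_grid: np.ndarray | None = None,
    refine: bool = True,
    method: str = "fast",
) -> tuple[float, float]:
    """Max steady-state growth over simulations with frozen ppGpp level.

    For each fixed T the regulation functions F_r and psi are frozen at
    F_r(T) while everything else evolves freely; returns (lambda_opt, T_opt)
    over the grid, refined by golden-section search around the grid optimum.
    """
    p = params if sigma is None else params.replace(sigma=sigma)
    if T_grid is None:
        T_grid = np.geomspace(0.01 * p.tau, 100.0 * p.tau, 25)
    T_grid = np.asarray(T_grid, float)

    def lam_at(T0: float) -> float:
        if method == "fast":
            return fast_steady_state(p, fixed_T=T0).derived.lam
        return steady_state(p, fixed_T=T0).derived.lam

    lams = np.array([lam_at(T0) for T0 in T_grid])
    i = int(np.argmax(lams))
    lam_opt, T_opt = float(lams[i]), float(T_grid[i])
    if refine and len(T_grid) >= 3:
        lo = T_grid[max(i - 1, 0)]
        hi = T_grid[min(i + 1, len(T_grid) - 1)]
        # golden-section on log10(T)
        a, b = np.log10(lo), np.log10(hi)
        gr = (np.sqrt(5.0) - 1.0) / 2.0
        c, dpt = b - gr * (b - a), a + gr * (b - a)
        fc, fd = lam_at(10 ** c), lam_at(10 ** dpt)
        for _ in range(40):
            if b - a < 1e-5:
                break
            if fc > fd:
                b, dpt, fd = dpt, c, fc
                c = b - gr * (b - a)
                fc = lam_at(10 ** c)
            else:
                a, c, fc = c, dpt, fd
                dpt = a + gr * (b - a)
                fd = lam_at(10 ** dpt)
        T_ref = 10 ** ((a + b) / 2)
        lam_ref = lam_at(T_ref)
        if lam_ref > lam_opt:
            lam_opt, T_opt = lam_ref, T_ref
    return lam_opt, T_opt


def multi_start_steady_states(
    params: HostParams,
    spec: CircuitSpec = EMPTY_CIRCUIT,
    starts: Sequence[np.ndarray] | None = None,
    cm: ChloramphenicolParams | None = None,
    horizon: float = 72.0,
    distinct_rtol: float = 0.01,
    **kwargs,
) -> list[SteadyState]:
    """Converged states from multiple initial conditions, clustered.

    Two states are distinct if any shared variable differs by more than
    ``distinct_rtol`` relative; one representative per cluster is returned.
    This replaces formal bifurcation continuation for bistability detection.
    """
    if starts is None or len(starts) < 2:
        raise ValueError("need at least two starting states")
    found: list[SteadyState] = []
    for x0 in starts:
        ss = steady_state(params, spec, cm=cm, horizon=horizon,
                          init=np.asarray(x0, float), **kwargs)
        if not ss.converged:
            continue
        is_new = True
        for other in found:
            scale = np.maximum(np.abs(other.x), 1e-6)
            if np.all(np.abs(ss.x - other.x) / scale <= distinct_rtol):
                is_new = False
                break
        if is_new:
            found.append(ss)
    return found
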