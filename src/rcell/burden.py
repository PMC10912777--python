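"""Closed-form burden calculus and controller design relations.

All formulas are anchored to the no-burden (NB) reference: the steady state
of the bare host at the same nutrient quality.  Under the standing
approximations — elongation rate, ribosomal regulation and the apparent
dissociation constants barely move under burden, and all mRNAs decay at a
comparable rate — a synthetic gene's entire demand on the ribosome pool
collapses into one growth-independent number, the translational burden

    xi_x = F_x * c_x * alpha_x / k_x^NB ,

and steady-state mass fractions, growth rates, production optima and the
antithetic-controller setpoints become algebraic functions of xi.

Conventions: ``predict_phi_X`` returns the heterologous share of the
*modeled* (non-housekeeping) proteome, which is what n_x*p_x/M measures in
this model; the linear growth-rate law ``lambda_ratio_from_phi`` takes the
share of the *total* proteome, (1-phi_q) times the former.  With that
pairing the three relations are mutually consistent as an exact identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .circuits import CircuitSpec, GeneSpec
from .params import HostParams
from .simulate import NoBurdenReference

__all__ = [
    "BurdenSummary",
    "ControllerDesign",
    "translational_burden",
    "total_burden",
    "native_burden_sum",
    "predict_phi_X",
    "predict_lambda",
    "lambda_ratio_from_phi",
    "optimal_burden",
    "population_production_rate",
    "production_rate_curve",
    "controller_setpoints",
    "operation_range",
]


@dataclass
class BurdenSummary:
    """Per-gene and total burden with predicted/simulated observables."""

    xi_per_gene: dict[str, float]
    xi: float
    phi_X_pred: float
    lambda_pred: float
    lambda_NB: float
    phi_X_sim: float | None = None
    lambda_sim: float | None = None


@dataclass
class ControllerDesign:
    """Antithetic-controller design parameters and derived setpoints.

    ``u`` is the actuator:annihilator maximum production ratio; ideal
    annihilation pins the sensor protein at K_sens*(1-u)/u.  ``zeta`` is the
    lumped sensor transcription parameter; by default it is taken as
    c_sens*alpha_sens/(1-phi_q), which makes the D setpoint formula exact
    for the reconstructed sensor ODE (it can be overridden from config).
    """

    u: float
    K_sens: float
    kappa: float
    chi: float
    c_sens: float = 10.0
    alpha_sens: float = 60.0
    n_sens: float = 300.0
    beta_sens: float = 6.0
    k_plus_sens: float = 60.0
    k_minus_sens: float = 60.0
    zeta: float | None = None
    # outputs, filled by controller_setpoints
    D_setpoint: float | None = None
    lambda_setpoint: float | None = None
    p_sens_setpoint: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.u < 1.0:
            raise ValueError(f"u must lie in (0, 1), got {self.u}")


def _k_NB(ref: NoBurdenReference, name: str) -> float:
    try:
        return ref.k_NB[name]
    except KeyError:
        raise KeyError(
            f"no-burden dissociation constant for gene {name!r} missing from "
            "reference; pass the gene to no_burden_reference(genes=...)"
        ) from None


def translational_burden(gene: GeneSpec, ref: NoBurdenReference,
                         F_bar: float = 1.0) -> float:
    """Burden xi = F*c*alpha/k^NB of one gene (dimensionless)."""
    if gene.name in ref.k_NB:
        k = ref.k_NB[gene.name]
    else:
        k = gene.k(ref.eps_NB)
    return F_bar * gene.c * gene.alpha / k


def total_burden(spec: CircuitSpec, ref: NoBurdenReference,
                 F_bars: dict[str, float] | None = None) -> float:
    """Total burden of a circuit: sum of per-gene xi (sRNAs contribute none)."""
    F_bars = F_bars or {}
    return sum(
        translational_burden(g, ref, F_bars.get(g.name, 1.0))
        for g in spec.genes
    )


def native_burden_sum(params: HostParams, ref: NoBurdenReference) -> float:
    """S = sum over native classes of F^NB*c*alpha/k^NB (F_a = 1)."""
    return (params.c_a * params.alpha_a / _k_NB(ref, "a")
            + ref.F_r_NB * params.c_r * params.alpha_r / _k_NB(ref, "r"))


def predict_phi_X(xi: float, params: HostParams, ref: NoBurdenReference) -> float:
    """Heterologous share of the modeled proteome: xi/(xi + S)."""
    if xi < 0:
        raise ValueError("xi must be >= 0")
    S = native_burden_sum(params, ref)
    return xi / (xi + S)


def predict_lambda(xi: float, params: HostParams, ref: NoBurdenReference) -> float:
    """Growth rate under burden xi.

    lambda(xi) = eps^NB*(1-phi_q)/n_r * (F_r^NB c_r alpha_r / k_r^NB) / (xi + S),
    a Hill-repression function of xi that equals lambda^NB at xi = 0.
    """
    if xi < 0:
        raise ValueError("xi must be >= 0")
    S = native_burden_sum(params, ref)
    s_r = ref.F_r_NB * params.c_r * params.alpha_r / _k_NB(ref, "r")
    return ref.eps_NB * (1.0 - params.phi_q) / params.n_r * s_r / (xi + S)


def lambda_ratio_from_phi(phi_X: float, phi_q: float) -> float:
    """Linear growth law: lambda/lambda^NB = 1 - phi_X/(1-phi_q).

    ``phi_X`` is the heterologous mass fraction of the *total* proteome and
    can therefore not exceed the non-housekeeping share 1-phi_q.
    """
    if not 0.0 <= phi_X <= 1.0 - phi_q:
        raise ValueError(f"phi_X must lie in [0, {1 - phi_q}], got {phi_X}")
    return 1.0 - phi_X / (1.0 - phi_q)


def optimal_burden(delta: float, params: HostParams, ref: NoBurdenReference) -> float:
    """Burden maximizing population-level protein production.

    xi_max = (1 - delta/lambda^NB)/(1 + delta/lambda^NB) * S for a population
    growing at lambda(xi) and dying at constant rate delta.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if delta >= ref.lambda_NB:
        raise ValueError(
            f"delta={delta} >= lambda_NB={ref.lambda_NB:.4f}: population cannot grow"
        )
    d = delta / ref.lambda_NB
    return (1.0 - d) / (1.0 + d) * native_burden_sum(params, ref)


def population_production_rate(
    phi_X: float, lam: float, delta: float, params: HostParams
) -> float:
    """Net per-cell production rate of the protein of interest (nM-aa/h).

    For a population in balanced growth (dN/dt = (lam - delta)N) whose cells
    each hold phi_X*M of the protein, the population-level accumulation rate
    per cell is mu = phi_X*M*(lam - delta); phi_X here is the modeled-proteome
    share n_poi*p_poi/M.
    """
    return phi_X * params.M * (lam - delta)


def production_rate_curve(
    c_values: Sequence[float],
    delta: float,
    params: HostParams,
    ref: NoBurdenReference,
    gene_template: GeneSpec | None = None,
    method: str = "fast",
) -> dict:
    """Population production rate mu over a DNA-concentration sweep.

    For each gene dose c, the constitutive gene-of-interest circuit is
    solved to steady state, its burden xi = c*alpha/k^NB recorded, and
    mu = n_poi*p_poi*(lam - delta) evaluated.  Returns the curve plus the
    burden at the numerical maximum (quadratic interpolation through the
    three points bracketing the grid maximum).
    """
    from .circuits import build_constitutive_gene
    from .simulate import fast_steady_state, steady_state

    if gene_template is None:
        gene_template = build_constitutive_gene().genes[0]
    xis, mus, lams = [], [], []
    for c in c_values:
        from dataclasses import replace as _dc_replace
        gene = _dc_replace(gene_template, c=float(c))
        spec = CircuitSpec(genes=[gene], name="poi_sweep")
        if method == "fast":
            ss = fast_steady_state(params, spec)
        else:
            ss = steady_state(params, spec, horizon=480.0)
        lam = ss.derived.lam
        p_poi = ss[f"p_{gene.name}"]
        xis.append(translational_burden(gene, ref))
        lams.append(lam)
        mus.append(gene.n * p_poi * (lam - delta))
    xis = np.asarray(xis)
    mus = np.asarray(mus)
    i = int(np.argmax(mus))
    if 0 < i < len(xis) - 1:
        # quadratic interpolation in log-xi around the discrete maximum
        x = np.log(xis[i - 1:i + 2])
        y = mus[i - 1:i + 2]
        denom = (x[0] - x[1]) * (x[0] - x[2]) * (x[1] - x[2])
        a = (x[2] * (y[1] - y[0]) + x[1] * (y[0] - y[2]) + x[0] * (y[2] - y[1])) / denom
        b = (x[2] ** 2 * (y[0] - y[1]) + x[1] ** 2 * (y[2] - y[0]) + x[0] ** 2 * (y[1] - y[2])) / denom
        xi_argmax = float(np.exp(-b / (2 * a))) if a < 0 else float(xis[i])
    else:
        xi_argmax = float(xis[i])
    return {"xi": xis, "mu": mus, "lam": np.asarray(lams), "xi_argmax": xi_argmax}


def controller_setpoints(
    design: ControllerDesign,
    params: HostParams,
    ref: NoBurdenReference,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> ControllerDesign:
    """Analytical setpoints of the antithetic controller (ideal annihilation).

    The sensor protein is pinned at p_sens = K_sens*(1-u)/u; feeding this
    through the steady-state translation-share identity yields the growth
    setpoint (solved jointly by fixed-point iteration because lambda enters
    the mRNA decay factors on both sides) and the resource-competition
    denominator setpoint D.
    """
    u = design.u
    p_set = design.K_sens * (1.0 - u) / u
    k_s_NB = (design.k_minus_sens + ref.eps_NB / design.n_sens) / design.k_plus_sens
    k_r_NB = _k_NB(ref, "r")
    lam = ref.lambda_NB
    for _ in range(max_iter):
        # sensor transcript share fixed by the sensor-protein setpoint
        w_s = design.c_sens * design.alpha_sens * lam / ((lam + design.beta_sens) * k_s_NB)
        w_sum = w_s * params.M * u / (design.n_sens * design.K_sens * (1.0 - u))
        w_r = ref.F_r_NB * params.c_r * params.alpha_r * lam / ((lam + params.beta_r) * k_r_NB)
        lam_new = (ref.eps_NB * (1.0 - params.phi_q) / params.n_r) * w_r / (lam * w_sum) * lam
        # contraction step
        lam_next = 0.5 * (lam + lam_new)
        if abs(lam_next - lam) < tol * max(lam, 1e-12):
            lam = lam_next
            break
        lam = lam_next
    else:
        raise RuntimeError("controller setpoint iteration did not converge")
    if not np.isfinite(lam) or lam <= 0:
        raise RuntimeError("controller setpoint diverged (u too extreme)")
    w_s = design.c_sens * design.alpha_sens * lam / ((lam + design.beta_sens) * k_s_NB)
    zeta = design.zeta if design.zeta is not None else (
        design.c_sens * design.alpha_sens / (1.0 - params.phi_q)
    )
    D = 1.0 + (lam * zeta / ((lam + design.beta_sens) * k_s_NB)) / (
        (design.n_sens / params.M) * design.K_sens * (1.0 - u) / u
    )
    design.D_setpoint = D
    design.lambda_setpoint = lam
    design.p_sens_setpoint = p_set
    return design


def operation_range(
    design: ControllerDesign,
    disturbing_genes: Sequence[GeneSpec],
    params: HostParams,
    ref: NoBurdenReference,
    F_bars: dict[str, float] | None = None,
) -> tuple[float, float, bool]:
    """Disturbance magnitudes the controller can absorb.

    The controller keeps total transcript demand Sum(w) at its setpoint by
    shedding actuator/amplifier transcripts; a disturbance is mitigable while
    its own transcript demand (lhs) does not exceed the controller's shed
    headroom (rhs).  Returns (lhs, rhs, mitigable).
    """
    F_bars = F_bars or {}
    design = controller_setpoints(design, params, ref)
    lam = design.lambda_setpoint
    lhs = 0.0
    for g in disturbing_genes:
        k = ref.k_NB.get(g.name, g.k(ref.eps_NB))
        F = F_bars.get(g.name, 1.0)
        lhs += F * g.c * g.alpha * lam / (k * (lam + g.beta))
    k_s_NB = (design.k_minus_sens + ref.eps_NB / design.n_sens) / design.k_plus_sens
    w_s = design.c_sens * design.alpha_sens * lam / ((lam + design.beta_sens) * k_s_NB)
    w_total_setpoint = w_s * params.M * design.u / (
        design.n_sens * design.K_sens * (1.0 - design.u)
    )
    w_native_and_sensor = (
        params.c_a * params.alpha_a * lam / (_k_NB(ref, "a") * (lam + params.beta_a))
        + ref.F_r_NB * params.c_r * params.alpha_r * lam / (_k_NB(ref, "r") * (lam + params.beta_r))
        + w_s
    )
    rhs = w_total_setpoint - w_native_and_sensor
    return lhs, rhs, lhs <= rhs
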