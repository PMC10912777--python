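"""Rate laws and right-hand sides of the coarse-grained host-cell ODEs.

The host is described by six concentrations: metabolic and ribosomal mRNA
(m_a, m_r), metabolic protein (p_a), ribosomes (R) and charged/uncharged
tRNA (t_c, t_u).  Growth rate is not a free parameter: the finite-proteome
trade-off fixes it as lam = eps*B/M, the total protein synthesis flux per
unit protein mass.  Ribosomal and tRNA transcription are co-repressed by
ppGpp, whose level is tracked through its reciprocal proxy T = t_c/t_u
(flux-parity regulation).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .params import (
    T_CAP,
    ChloramphenicolParams,
    DerivedRates,
    HostParams,
    HostState,
    InvalidParameterError,
)

__all__ = [
    "apparent_dissociation_constants",
    "derived_rates",
    "host_rhs",
    "chloramphenicol_rhs",
]


def _k_single(eps: float, k_minus: float, k_plus: float, n: float,
              cm: ChloramphenicolParams | None = None) -> float:
    """Apparent mRNA-ribosome dissociation constant k = (k- + eps/n [+ k_cm*h])/k+.

    The eps/n term is the rate at which a ribosome completes translation and
    slides off the transcript; with chloramphenicol present, ribosome
    inactivation adds a further channel by which a translating ribosome is
    removed from the mRNA.
    """
    if k_plus <= 0:
        raise InvalidParameterError(f"k_plus must be > 0, got {k_plus}")
    extra = cm.k_cm * cm.h_cm if cm is not None else 0.0
    return (k_minus + eps / n + extra) / k_plus


def apparent_dissociation_constants(
    eps: float,
    genes: Mapping[str, tuple[float, float, float]] | Sequence[tuple[str, float, float, float]],
    cm: ChloramphenicolParams | None = None,
) -> dict[str, float]:
    """Apparent mRNA-ribosome dissociation constants k_i for a set of genes.

    Parameters
    ----------
    eps
        Current translation elongation rate (aa/h), >= 0.
    genes
        Mapping of gene name to ``(k_minus, k_plus, n)`` or a sequence of
        ``(name, k_minus, k_plus, n)`` tuples.
    cm
        Optional chloramphenicol parameters; when active, the inactivation
        term k_cm*h_cm is added to each gene's numerator.
    """
    if eps < 0:
        raise ValueError(f"eps must be >= 0, got {eps}")
    if isinstance(genes, Mapping):
        items = [(name, *kin) for name, kin in genes.items()]
    else:
        items = list(genes)
    return {
        name: _k_single(eps, k_minus, k_plus, n, cm)
        for name, k_minus, k_plus, n in items
    }


def native_k(eps: float, params: HostParams,
             cm: ChloramphenicolParams | None = None) -> dict[str, float]:
    """k_a and k_r at elongation rate ``eps``."""
    return apparent_dissociation_constants(
        eps,
        {"a": params.gene_kinetics("a"), "r": params.gene_kinetics("r")},
        cm,
    )


def tRNA_ratio(t_c: float, t_u: float) -> float:
    """Charged:uncharged tRNA ratio T, capped as t_u -> 0 so F_r -> 1 smoothly."""
    if t_u <= 0.0:
        return T_CAP if t_c > 0.0 else 0.0
    return min(t_c / t_u, T_CAP)


def derived_rates(
    state: HostState,
    params: HostParams,
    extra_mrnas: Mapping[str, tuple[float, float]] | None = None,
    cm: ChloramphenicolParams | None = None,
) -> DerivedRates:
    """All instantaneous quantities following from a host state.

    ``extra_mrnas`` maps circuit gene names to ``(m_x, k_x)`` pairs; their
    transcripts enter the shared resource-competition denominator D and the
    translating-ribosome pool B alongside the native classes.
    """
    x = state.as_array()
    if np.any(x < 0):
        raise ValueError("negative host state component")
    eps = params.eps_max * state.t_c / (state.t_c + params.K_eps) if state.t_c > 0 else 0.0
    nu = params.nu_max * params.sigma * state.t_u / (state.t_u + params.K_nu) if state.t_u > 0 else 0.0
    T = tRNA_ratio(state.t_c, state.t_u)
    F_r = T / (T + params.tau)
    psi = params.psi_max * F_r
    k = native_k(eps, params, cm)
    w = state.m_a / k["a"] + state.m_r / k["r"]
    w_total = w
    if extra_mrnas:
        for name, (m_x, k_x) in extra_mrnas.items():
            k[name] = k_x
            w_total += m_x / k_x
    D = 1.0 + w_total / (1.0 - params.phi_q)
    B = w_total / D * state.R
    lam = eps * B / params.M
    return DerivedRates(eps=eps, nu=nu, T=T, F_r=F_r, psi=psi, D=D, B=B, lam=lam, k=k)


def host_rhs(state: HostState, params: HostParams) -> np.ndarray:
    """Time derivatives of the six host variables (nM/h).

    Metabolic transcription is constitutive (F_a = 1 in every medium);
    ribosomal transcription carries the ppGpp regulation F_r(T).
    """
    d = derived_rates(state, params)
    lam, eps = d.lam, d.eps
    dm_a = params.c_a * params.alpha_a * lam - (params.beta_a + lam) * state.m_a
    dm_r = d.F_r * params.c_r * params.alpha_r * lam - (params.beta_r + lam) * state.m_r
    dp_a = eps / params.n_a * (state.m_a / d.k["a"]) / d.D * state.R - lam * state.p_a
    dR = eps / params.n_r * (state.m_r / d.k["r"]) / d.D * state.R - lam * state.R
    dt_c = d.nu * state.p_a - eps * d.B - lam * state.t_c
    dt_u = d.psi * lam - d.nu * state.p_a + eps * d.B - lam * state.t_u
    return np.array([dm_a, dm_r, dp_a, dR, dt_c, dt_u])


def chloramphenicol_rhs(
    state: HostState, params: HostParams, cm: ChloramphenicolParams
) -> np.ndarray:
    """Host derivatives under chloramphenicol, plus dB_cm/dt as 7th component.

    The apparent dissociation constants gain the inactivation term, operational
    ribosomes R lose an inactivation flux k_cm*h_cm*B, and inactivated
    ribosomes B_cm accumulate and dilute.  The experimentally visible ribosome
    content is n_r*(R + B_cm)/M.
    """
    d = derived_rates(state, params, cm=cm)
    lam, eps = d.lam, d.eps
    inact = cm.k_cm * cm.h_cm * d.B
    dm_a = params.c_a * params.alpha_a * lam - (params.beta_a + lam) * state.m_a
    dm_r = d.F_r * params.c_r * params.alpha_r * lam - (params.beta_r + lam) * state.m_r
    dp_a = eps / params.n_a * (state.m_a / d.k["a"]) / d.D * state.R - lam * state.p_a
    dR = eps / params.n_r * (state.m_r / d.k["r"]) / d.D * state.R - lam * state.R - inact
    dt_c = d.nu * state.p_a - eps * d.B - lam * state.t_c
    dt_u = d.psi * lam - d.nu * state.p_a + eps * d.B - lam * state.t_u
    dB_cm = inact - lam * state.B_cm
    return np.array([dm_a, dm_r, dp_a, dR, dt_c, dt_u, dB_cm])
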