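"""Declarative heterologous gene circuits on top of the host cell.

Each synthetic gene adds an mRNA/protein ODE pair that mirrors the native
classes: transcription scales with growth (unless driven by orthogonal
machinery such as T7 RNAP), and translation is discounted by the shared
resource-competition denominator D, which sums m_j/k_j over native *and*
circuit transcripts.  Small RNAs are transcribed but never translated, so
they exert no ribosomal burden; annihilation pairs remove one molecule of
each partner (the duplex is assumed rapidly degraded and is not tracked).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .host import native_k, _k_single, derived_rates, tRNA_ratio
from .params import ChloramphenicolParams, HostParams, HostState

__all__ = [
    "RegulationSpec",
    "GeneSpec",
    "RNASpec",
    "CircuitSpec",
    "CircuitConfigError",
    "circuit_rhs",
    "build_constitutive_gene",
    "build_winner_takes_all",
    "build_t7_self_activator",
    "build_aif_controller",
    "build_inducible_module",
    "build_disturbance_gene",
]


class CircuitConfigError(ValueError):
    """A circuit definition references unknown species or invalid values."""


REGULATION_KINDS = (
    "constitutive",
    "hill_activation",
    "hill_repression",
    "inducible_self_activation",
)


@dataclass
class RegulationSpec:
    """Transcription regulation function F mapping into [0, 1].

    ``baseline`` is the leaky floor F_min; the regulated part spans the
    remaining 1-baseline.  When ``inducer_K`` is set, the regulator protein
    is allosterically modulated: only the inducer-bound fraction
    p* = p*f/(f + inducer_K) acts as the transcription factor.
    """

    kind: str = "constitutive"
    regulator: str | None = None   # species name, e.g. "p_sens"
    K: float = 100.0               # half-saturation (nM)
    hill: float = 2.0              # cooperativity
    baseline: float = 0.0          # leaky fraction F_min in [0, 1]
    inducer_K: float = 0.0         # inducer binding constant (nM); 0 = no inducer step
    inducer_level: float = 0.0     # inducer concentration f (nM)

    def __post_init__(self) -> None:
        if self.kind not in REGULATION_KINDS:
            raise CircuitConfigError(f"unknown regulation kind {self.kind!r}")
        if not 0.0 <= self.baseline <= 1.0:
            raise CircuitConfigError("baseline must lie in [0, 1]")
        if self.kind != "constitutive" and self.regulator is None:
            raise CircuitConfigError(f"{self.kind} regulation requires a regulator")

    def evaluate(self, species: dict[str, float]) -> float:
        if self.kind == "constitutive":
            return 1.0
        try:
            p = species[self.regulator]
        except KeyError:
            raise CircuitConfigError(
                f"regulator species {self.regulator!r} is not defined"
            ) from None
        if self.inducer_K > 0.0:
            p = p * self.inducer_level / (self.inducer_level + self.inducer_K)
        p = max(p, 0.0)
        if self.kind in ("hill_activation", "inducible_self_activation"):
            act = p ** self.hill / (self.K ** self.hill + p ** self.hill)
        else:  # hill_repression
            act = self.K ** self.hill / (self.K ** self.hill + p ** self.hill)
        return self.baseline + (1.0 - self.baseline) * act


@dataclass
class GeneSpec:
    """A heterologous protein-coding gene."""

    name: str
    c: float = 1.0                 # DNA concentration (nM)
    alpha: float = 1000.0          # promoter strength (dimensionless)
    n: float = 300.0               # protein length (aa)
    beta: float = 6.0              # mRNA degradation rate (1/h)
    k_plus: float = 60.0           # ribosome-RBS association (1/(nM h))
    k_minus: float = 60.0          # dissociation (1/h)
    regulation: RegulationSpec = field(default_factory=RegulationSpec)
    protein_degradation: float = 0.0      # active degradation (1/h)
    growth_coupled_transcription: bool = True
    toxicity_K: float | None = None       # growth penalty: lam /= 1 + p/K_tox
    onset_time: float = 0.0               # transcription switched on at this time (h)

    def __post_init__(self) -> None:
        for attr in ("alpha", "n", "k_plus"):
            if getattr(self, attr) <= 0:
                raise CircuitConfigError(f"gene {self.name}: {attr} must be > 0")
        if self.c < 0:
            raise CircuitConfigError(f"gene {self.name}: c must be >= 0")
        if self.beta < 0 or self.protein_degradation < 0:
            raise CircuitConfigError(f"gene {self.name}: rates must be >= 0")

    def k(self, eps: float, cm: ChloramphenicolParams | None = None) -> float:
        """Apparent mRNA-ribosome dissociation constant at elongation rate eps."""
        return _k_single(eps, self.k_minus, self.k_plus, self.n, cm)


@dataclass
class RNASpec:
    """A non-translated small RNA: transcribed, degraded, diluted; no burden."""

    name: str
    transcription_rate: float = 1000.0    # max rate per unit growth rate (nM)
    regulation: RegulationSpec = field(default_factory=RegulationSpec)
    beta: float = 6.0                     # degradation rate (1/h)

    def __post_init__(self) -> None:
        if self.transcription_rate < 0 or self.beta < 0:
            raise CircuitConfigError(f"sRNA {self.name}: rates must be >= 0")


@dataclass
class CircuitSpec:
    """A set of synthetic genes, sRNAs and annihilation reactions."""

    genes: list[GeneSpec] = field(default_factory=list)
    rnas: list[RNASpec] = field(default_factory=list)
    annihilations: list[tuple[str, str, float]] = field(default_factory=list)
    name: str = "circuit"

    def __post_init__(self) -> None:
        names = [g.name for g in self.genes] + [r.name for r in self.rnas]
        if len(set(names)) != len(names):
            raise CircuitConfigError("species names must be unique")
        declared = set(self.species_names())
        for a, b, theta in self.annihilations:
            for s in (a, b):
                if s not in declared:
                    raise CircuitConfigError(
                        f"annihilation references undeclared species {s!r}"
                    )
            if theta < 0:
                raise CircuitConfigError("annihilation rate must be >= 0")

    # ---- species bookkeeping -------------------------------------------
    def species_names(self) -> list[str]:
        out: list[str] = []
        for g in self.genes:
            out += [f"m_{g.name}", f"p_{g.name}"]
        out += [r.name for r in self.rnas]
        return out

    @property
    def n_species(self) -> int:
        return 2 * len(self.genes) + len(self.rnas)

    def species_index(self, name: str) -> int:
        return self.species_names().index(name)

    def is_empty(self) -> bool:
        return not self.genes and not self.rnas

    def merged(self, other: "CircuitSpec", name: str | None = None) -> "CircuitSpec":
        return CircuitSpec(
            genes=list(self.genes) + list(other.genes),
            rnas=list(self.rnas) + list(other.rnas),
            annihilations=list(self.annihilations) + list(other.annihilations),
            name=name or f"{self.name}+{other.name}",
        )


EMPTY_CIRCUIT = CircuitSpec(name="none")


def _species_dict(spec: CircuitSpec, circ: np.ndarray) -> dict[str, float]:
    return dict(zip(spec.species_names(), circ))


def circuit_rhs(
    host: HostState,
    circ: np.ndarray,
    params: HostParams,
    spec: CircuitSpec,
    cm: ChloramphenicolParams | None = None,
    t: float = 0.0,
    fixed_T: float | None = None,
):
    """Joint right-hand side of the host + circuit ODE system.

    Returns ``(dhost, dcirc)`` where ``dhost`` has 7 components when the
    chloramphenicol extension is active (B_cm last) and 6 otherwise.

    The elongation-rate-dependent circuit k_x are recomputed at every call,
    and all translation terms share a single resource-competition
    denominator D spanning native and synthetic transcripts.
    """
    circ = np.asarray(circ, dtype=float)
    gene_ms = circ[0:2 * len(spec.genes):2] if spec.genes else np.empty(0)
    # toxicity (e.g. T7 RNAP) poisons translation: the maximum elongation
    # rate is scaled down, which slows growth while preserving the
    # finite-proteome constraint lam = eps*B/M exactly.
    tox = 1.0
    for g, i in zip(spec.genes, range(0, 2 * len(spec.genes), 2)):
        if g.toxicity_K is not None:
            tox += max(circ[i + 1], 0.0) / g.toxicity_K
    if tox != 1.0:
        params = params.replace(eps_max=params.eps_max / tox)
    # apparent dissociation constants at the current elongation rate
    t_c = host.t_c
    eps = params.eps_max * t_c / (t_c + params.K_eps) if t_c > 0 else 0.0
    extra = {
        f"{g.name}": (m, g.k(eps, cm))
        for g, m in zip(spec.genes, gene_ms)
    }
    d = derived_rates(host, params, extra_mrnas=extra, cm=cm)
    if fixed_T is not None:
        F_r = fixed_T / (fixed_T + params.tau)
        psi = params.psi_max * F_r
    else:
        F_r, psi = d.F_r, d.psi
    lam = d.lam
    nu = d.nu
    species = _species_dict(spec, circ)
    inact = cm.k_cm * cm.h_cm * d.B if cm is not None else 0.0

    dm_a = params.c_a * params.alpha_a * lam - (params.beta_a + lam) * host.m_a
    dm_r = F_r * params.c_r * params.alpha_r * lam - (params.beta_r + lam) * host.m_r
    dp_a = d.eps / params.n_a * (host.m_a / d.k["a"]) / d.D * host.R - lam * host.p_a
    dR = (d.eps / params.n_r * (host.m_r / d.k["r"]) / d.D * host.R
          - lam * host.R - inact)
    dt_c = nu * host.p_a - d.eps * d.B - lam * host.t_c
    dt_u = psi * lam - nu * host.p_a + d.eps * d.B - lam * host.t_u
    if cm is not None:
        dB_cm = inact - lam * host.B_cm
        dhost = np.array([dm_a, dm_r, dp_a, dR, dt_c, dt_u, dB_cm])
    else:
        dhost = np.array([dm_a, dm_r, dp_a, dR, dt_c, dt_u])

    dcirc = np.zeros(spec.n_species)
    i = 0
    for g in spec.genes:
        m_x, p_x = circ[i], circ[i + 1]
        F = g.regulation.evaluate(species) if t >= g.onset_time else 0.0
        txn = F * g.c * g.alpha * (lam if g.growth_coupled_transcription else 1.0)
        k_x = extra[g.name][1]
        dcirc[i] = txn - (g.beta + lam) * m_x
        dcirc[i + 1] = (d.eps / g.n * (m_x / k_x) / d.D * host.R
                        - (lam + g.protein_degradation) * p_x)
        i += 2
    for r in spec.rnas:
        x = circ[i]
        F = r.regulation.evaluate(species)
        dcirc[i] = r.transcription_rate * F * lam - (r.beta + lam) * x
        i += 1
    names = spec.species_names()
    for a, b, theta in spec.annihilations:
        flux = theta * species[a] * species[b]
        dcirc[names.index(a)] -= flux
        dcirc[names.index(b)] -= flux
    return dhost, dcirc


# ---------------------------------------------------------------------------
# circuit builders
# ---------------------------------------------------------------------------

def build_constitutive_gene(
    c: float = 10.0,
    alpha: float = 1000.0,
    n: float = 300.0,
    rbs_kinetics: tuple[float, float] = (60.0, 60.0),
    name: str = "x",
    beta: float = 6.0,
) -> CircuitSpec:
    """One unregulated synthetic gene (F = 1 everywhere)."""
    k_plus, k_minus = rbs_kinetics
    gene = GeneSpec(name=name, c=c, alpha=alpha, n=n, beta=beta,
                    k_plus=k_plus, k_minus=k_minus)
    return CircuitSpec(genes=[gene], name="constitutive")


def build_winner_takes_all(
    inducer1: float,
    inducer2: float,
    c: float = 10.0,
    alpha: float = 1.0e4,
    n: float = 300.0,
    K: float = 6.0e4,
    hill: float = 2.0,
    baseline: float = 0.03,
    inducer_K: float = 100.0,
    k_plus: float = 60.0,
    k_minus: float = 60.0,
) -> CircuitSpec:
    """Two co-hosted self-activating switches competing for ribosomes.

    Each switch protein, once bound by its inducer, cooperatively activates
    its own transcription; the inducer level sets the timescale of the climb
    toward the high-expression state, so unequal inducers let the faster
    switch monopolize ribosomes.
    """
    if inducer1 < 0 or inducer2 < 0:
        raise CircuitConfigError("inducer concentrations must be >= 0")
    genes = []
    for label, f in (("s1", inducer1), ("s2", inducer2)):
        reg = RegulationSpec(
            kind="inducible_self_activation", regulator=f"p_{label}",
            K=K, hill=hill, baseline=baseline,
            inducer_K=inducer_K, inducer_level=f,
        )
        genes.append(GeneSpec(name=label, c=c, alpha=alpha, n=n,
                              k_plus=k_plus, k_minus=k_minus, regulation=reg))
    return CircuitSpec(genes=genes, name="winner_takes_all")


def build_t7_self_activator(
    c: float = 10.0,
    alpha: float = 3000.0,
    n: float = 883.0,
    K: float = 3.0e5,
    baseline: float = 0.02,
    toxicity_K: float | None = 3.0e4,
    protein_degradation: float = 0.15,
    k_plus: float = 60.0,
    k_minus: float = 60.0,
) -> CircuitSpec:
    """Heterologous T7 RNAP transcribing its own gene (non-cooperative).

    Transcription is carried out by the heterologous polymerase, so it does
    not scale with host growth rate; bistability emerges only through the
    growth-mediated feedback (burden and toxicity slow growth, which depletes
    the growth-coupled native transcript pool and raises the T7 share), not
    through cooperativity (Hill coefficient 1).  A modest active-degradation
    rate keeps the high-expression state at a finite, non-zero growth rate.
    """
    reg = RegulationSpec(kind="hill_activation", regulator="p_t7",
                         K=K, hill=1.0, baseline=baseline)
    gene = GeneSpec(name="t7", c=c, alpha=alpha, n=n,
                    k_plus=k_plus, k_minus=k_minus, regulation=reg,
                    growth_coupled_transcription=False, toxicity_K=toxicity_K,
                    protein_degradation=protein_degradation)
    return CircuitSpec(genes=[gene], name="t7_self_activator")


def build_aif_controller(
    kappa: float = 1.0e4,
    u: float = 0.4,
    chi: float = 3.0e5,
    K_sens: float = 3722.0,
    theta: float = 500.0,
    c_sens: float = 10.0,
    alpha_sens: float = 60.0,
    n_sens: float = 300.0,
    K_amp: float = 1000.0,
    c_act: float = 1.0,
    n_act: float = 300.0,
    beta: float = 6.0,
) -> CircuitSpec:
    """RNA-based antithetic integral feedback controller of ribosome availability.

    The constitutive sensor protein p_sens reads out translational resource
    availability.  The annihilator sRNA is transcribed at kappa*F_anti with
    F_anti = K_sens/(K_sens + p_sens) (activated when p_sens falls), the
    actuator mRNA at the constant fraction u*kappa, and the two annihilate at
    rate theta.  The actuator protein activates a non-annihilated amplifier
    mRNA (gain chi) that carries the bulk of the ribosome-sequestering
    control action.  Ideal annihilation forces F_anti(p_sens) = u, i.e. a
    sensor setpoint K_sens*(1-u)/u.
    """
    if not 0.0 < u < 1.0:
        raise CircuitConfigError(f"u must lie in (0, 1), got {u}")
    for nm, v in (("kappa", kappa), ("chi", chi), ("K_sens", K_sens), ("theta", theta)):
        if v <= 0:
            raise CircuitConfigError(f"{nm} must be > 0")
    sens = GeneSpec(name="sens", c=c_sens, alpha=alpha_sens, n=n_sens, beta=beta)
    act = GeneSpec(name="act", c=c_act, alpha=u * kappa, n=n_act, beta=beta)
    amp = GeneSpec(
        name="amp", c=1.0, alpha=chi, beta=beta,
        regulation=RegulationSpec(kind="hill_activation", regulator="p_act",
                                  K=K_amp, hill=1.0),
    )
    anti = RNASpec(
        name="anti", transcription_rate=kappa, beta=beta,
        regulation=RegulationSpec(kind="hill_repression", regulator="p_sens",
                                  K=K_sens, hill=1.0),
    )
    return CircuitSpec(
        genes=[sens, act, amp],
        rnas=[anti],
        annihilations=[("m_act", "anti", theta)],
        name="aif_controller",
    )


def build_disturbance_gene(
    c: float = 100.0,
    alpha: float = 1000.0,
    n: float = 300.0,
    onset_time: float = 0.0,
    name: str = "dist",
    beta: float = 6.0,
) -> CircuitSpec:
    """Constitutive burden gene whose transcription starts at ``onset_time``."""
    gene = GeneSpec(name=name, c=c, alpha=alpha, n=n, beta=beta,
                    onset_time=onset_time)
    return CircuitSpec(genes=[gene], name="disturbance")


def build_inducible_module(
    inducer: float = 100.0,
    c_ta: float = 10.0,
    alpha_ta: float = 100.0,
    n_ta: float = 300.0,
    c_x: float = 10.0,
    alpha_x: float = 500.0,
    n_x: float = 300.0,
    K: float = 300.0,
    hill: float = 2.0,
    baseline: float = 0.0,
    inducer_K: float = 100.0,
) -> CircuitSpec:
    """Inducible two-gene module: activator ta drives output gene x."""
    if inducer < 0:
        raise CircuitConfigError("inducer must be >= 0")
    ta = GeneSpec(name="ta", c=c_ta, alpha=alpha_ta, n=n_ta)
    reg = RegulationSpec(kind="hill_activation", regulator="p_ta",
                         K=K, hill=hill, baseline=baseline,
                         inducer_K=inducer_K, inducer_level=inducer)
    x = GeneSpec(name="x", c=c_x, alpha=alpha_x, n=n_x, regulation=reg)
    return CircuitSpec(genes=[ta, x], name="inducible_module")
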