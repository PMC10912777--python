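"""Host-cell parameters, state containers and derived-rate records.

Units convention used throughout the package: concentrations in nM, time in
hours, protein lengths in amino-acid residues (aa), total protein mass
density ``M`` in nM-aa.  With an E. coli volume of ~1 um^3, 1 nM corresponds
to roughly one molecule per cell, so native gene DNA concentrations default
to 1 nM (one chromosomal copy).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "HostParams",
    "HostState",
    "DerivedRates",
    "ChloramphenicolParams",
    "default_host_params",
    "load_host_params",
    "InvalidParameterError",
]


class InvalidParameterError(ValueError):
    """A parameter value violates its physical domain."""


HOST_STATE_NAMES = ("m_a", "m_r", "p_a", "R", "t_c", "t_u")

#: Cap applied to the charged:uncharged tRNA ratio T when t_u -> 0, so that
#: F_r(T) -> 1 smoothly instead of dividing by zero.
T_CAP = 1e12


@dataclass
class HostParams:
    """Parameters of the six-variable coarse-grained host cell.

    The cell's proteome is split into three classes: metabolic (``a``),
    ribosomal (``r``) and housekeeping (``q``).  Housekeeping expression is
    not modeled explicitly; its fixed mass share ``phi_q`` enters translation
    through the 1/(1-phi_q) factor of the resource-competition denominator.
    """

    M: float = 1.19e9            # total modeled protein mass density (nM-aa)
    phi_q: float = 0.59          # housekeeping protein mass fraction (-)
    eps_max: float = 7.2e4       # max translation elongation rate (aa/h)
    K_eps: float = 5000.0        # elongation half-saturation (nM charged tRNA)
    nu_max: float = 6000.0       # max per-enzyme aminoacylation rate (1/h)
    K_nu: float = 5000.0         # aminoacylation half-saturation (nM)
    psi_max: float = 1.0e5       # max tRNA transcription per unit growth (nM)
    tau: float = 1.0             # ppGpp-regulation half-saturation (-)
    sigma: float = 0.5           # medium nutrient quality (-), 0..1
    # metabolic gene class (lumped)
    c_a: float = 1.0             # gene DNA concentration (nM)
    alpha_a: float = 1.0e5       # promoter strength (-)
    beta_a: float = 6.0          # mRNA degradation rate (1/h)
    n_a: float = 300.0           # protein length (aa)
    k_plus_a: float = 60.0       # ribosome-RBS association (1/(nM h))
    k_minus_a: float = 60.0      # ribosome-RBS dissociation (1/h)
    # ribosomal gene class (lumped)
    c_r: float = 1.0
    alpha_r: float = 1.0e5
    beta_r: float = 6.0
    n_r: float = 7459.0
    k_plus_r: float = 60.0
    k_minus_r: float = 60.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.phi_q < 1.0:
            raise InvalidParameterError(f"phi_q must lie in (0, 1), got {self.phi_q}")
        if not 0.0 <= self.sigma <= 1.0:
            raise InvalidParameterError(f"sigma must lie in [0, 1], got {self.sigma}")
        positive = (
            "M", "eps_max", "K_eps", "nu_max", "K_nu", "psi_max", "tau",
            "c_a", "alpha_a", "n_a", "k_plus_a",
            "c_r", "alpha_r", "n_r", "k_plus_r",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        for name in ("beta_a", "beta_r", "k_minus_a", "k_minus_r"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")

    def replace(self, **kwargs) -> "HostParams":
        d = asdict(self)
        d.update(kwargs)
        return HostParams(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    # per-gene-class kinetic tuples used by the rate laws
    def gene_kinetics(self, which: str) -> tuple[float, float, float]:
        """Return (k_minus, k_plus, n) for native gene class 'a' or 'r'."""
        if which not in ("a", "r"):
            raise KeyError(which)
        return (
            getattr(self, f"k_minus_{which}"),
            getattr(self, f"k_plus_{which}"),
            getattr(self, f"n_{which}"),
        )


@dataclass
class ChloramphenicolParams:
    """Translation-inhibiting antibiotic action.

    Chloramphenicol at internal concentration ``h_cm`` binds and disables
    translating ribosomes at rate ``k_cm * h_cm``; disabled ribosomes are
    tracked as a separate pool B_cm that is only removed by dilution.
    ``h_cm = 0`` recovers the unextended model exactly.
    """

    h_cm: float = 0.0   # internal chloramphenicol concentration (uM)
    k_cm: float = 0.30  # ribosome-chloramphenicol binding rate (1/(uM h))

    def __post_init__(self) -> None:
        if self.h_cm < 0:
            raise InvalidParameterError(f"h_cm must be >= 0, got {self.h_cm}")
        if self.k_cm < 0:
            raise InvalidParameterError(f"k_cm must be >= 0, got {self.k_cm}")

    @property
    def active(self) -> bool:
        return self.h_cm > 0


@dataclass
class HostState:
    """Concentrations of the six host variables (all nM; B_cm optional)."""

    m_a: float
    m_r: float
    p_a: float
    R: float
    t_c: float
    t_u: float
    B_cm: float = 0.0

    def as_array(self, with_cm: bool = False) -> np.ndarray:
        base = [self.m_a, self.m_r, self.p_a, self.R, self.t_c, self.t_u]
        if with_cm:
            base.append(self.B_cm)
        return np.asarray(base, dtype=float)

    @classmethod
    def from_array(cls, x, with_cm: bool = False) -> "HostState":
        x = np.asarray(x, dtype=float)
        if with_cm:
            return cls(*x[:6], B_cm=float(x[6]))
        return cls(*x[:6])

    def validate(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"state component {f.name} is negative")


@dataclass
class DerivedRates:
    """Instantaneous rates and regulatory quantities computed from a state."""

    eps: float       # translation elongation rate (aa/h)
    nu: float        # per-enzyme tRNA aminoacylation rate (1/h)
    T: float         # charged:uncharged tRNA ratio (reciprocal ppGpp proxy)
    F_r: float       # ribosomal transcription regulation (0..1)
    psi: float       # tRNA synthesis rate per unit growth rate (nM)
    D: float         # resource competition denominator (>= 1)
    B: float         # translating-ribosome concentration (nM)
    lam: float       # growth rate (1/h)
    k: dict[str, float] = field(default_factory=dict)  # apparent k_i per gene (nM)

    def to_dict(self) -> dict:
        d = {n: getattr(self, n) for n in ("eps", "nu", "T", "F_r", "psi", "D", "B", "lam")}
        d.update({f"k_{g}": v for g, v in self.k.items()})
        return d


def default_host_params() -> HostParams:
    """Host parameters shipped with the package (E. coli parameterization)."""
    path = resources.files("rcell").joinpath("data/host_default.yaml")
    with path.open("r") as fh:
        doc = yaml.safe_load(fh)
    return _params_from_doc(doc)


def load_host_params(path: str | Path) -> HostParams:
    """Load host parameters from a YAML file (one flat ``host`` block)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _params_from_doc(doc)


def _params_from_doc(doc: Mapping) -> HostParams:
    block = doc.get("host", doc)
    known = {f.name for f in fields(HostParams)}
    unknown = set(block) - known
    if unknown:
        raise InvalidParameterError(
            f"unknown host parameter key(s): {', '.join(sorted(unknown))}"
        )
    # YAML 1.1 reads exponent forms like 1.19e9 as strings; coerce
    return HostParams(**{k: float(v) for k, v in block.items()})
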