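"""Fitting host parameters to growth-law data with adaptive multi-chain MCMC.

The observables are steady-state growth rate and ribosomal mass fraction of
cells grown in media of different nutrient quality sigma, with and without
the translation inhibitor chloramphenicol.  RNA:protein mass ratios are
converted to ribosomal mass fractions with the factor 0.4558, and records
with growth rate <= 0.3 1/h are excluded from the likelihood (the model does
not describe the stress physiology of near-stasis cells).  Media nutrient
qualities are fixed at six points log-spaced on [0.08, 0.5], matched to
media by rank.

The sampler is a DREAM-style scheme: several chains run in parallel and
propose differential-evolution jumps built from the difference of two other
randomly chosen chains, with per-dimension crossover adapted during burn-in
and occasional full-size (gamma = 1) jumps for mode swapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ChloramphenicolParams, HostParams
from .fastss import solve_host_steady_state

__all__ = [
    "RNA_PROTEIN_TO_PHI_R",
    "LAMBDA_FILTER",
    "FitConfig",
    "GrowthLawDataset",
    "synthesize_growth_law_data",
    "log_likelihood",
    "dream_sample",
    "DreamResult",
]

RNA_PROTEIN_TO_PHI_R = 0.4558   # RNA:protein mass ratio -> ribosomal mass fraction
LAMBDA_FILTER = 0.3             # records at or below this growth rate are dropped

FREE_PARAM_NAMES = ("nu_max", "k_cm", "K", "alpha_ratio")


@dataclass
class FitConfig:
    """Free parameters, priors, bounds and sampler settings.

    Priors are normal with sd = mean/4; admissible intervals span
    [mean/50, 50*mean].  ``K`` is the shared Michaelis constant
    K_eps = K_nu (flux parity makes them equal); ``alpha_ratio`` is
    alpha_r:alpha_a with alpha_a held fixed.
    """

    free_params: tuple[str, ...] = FREE_PARAM_NAMES
    prior_means: dict[str, float] = field(default_factory=dict)
    n_chains: int = 10
    n_steps: int = 20000
    burn_in_fraction: float = 0.2
    seed: int = 0
    sigma_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.08, 0.5, 6)
    )
    cm_grid: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0)
    likelihood_horizon: float = 48.0   # h, used by the integration fallback
    error_scale_fraction: float = 0.05  # sd as a fraction of each observable's range

    def __post_init__(self) -> None:
        if self.n_chains < 3:
            raise ValueError("differential-evolution proposals need >= 3 chains")
        for name in self.free_params:
            if name not in FREE_PARAM_NAMES:
                raise ValueError(f"unknown free parameter {name!r}")

    def resolved_prior_means(self, params: HostParams) -> np.ndarray:
        defaults = {
            "nu_max": params.nu_max,
            "k_cm": ChloramphenicolParams().k_cm,
            "K": params.K_eps,
            "alpha_ratio": 1.0,   # order-of-magnitude prior: equal promoters
        }
        defaults.update(self.prior_means)
        means = np.array([defaults[n] for n in self.free_params])
        if np.any(means <= 0):
            raise ValueError("prior means must be positive")
        return means


@dataclass
class GrowthLawDataset:
    """Growth-law records: one row per (medium, chloramphenicol) condition."""

    table: pd.DataFrame   # columns: medium, sigma, cm_uM, lambda_per_h, rna_protein_ratio

    REQUIRED = ("medium", "cm_uM", "lambda_per_h", "rna_protein_ratio")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"dataset missing column(s): {sorted(missing)}")
        if (self.table["lambda_per_h"] <= 0).any():
            raise ValueError("growth rates must be positive")

    def with_sigma(self, sigma_grid: np.ndarray) -> pd.DataFrame:
        """Attach nutrient qualities, matching media to the grid by rank.

        Media are ranked by their drug-free growth rate; the slowest medium
        gets the smallest sigma.  If the table already carries a ``sigma``
        column it is used as-is.
        """
        t = self.table.copy()
        if "sigma" in t.columns:
            return t
        order = (
            t[t.cm_uM == 0].groupby("medium")["lambda_per_h"].mean().sort_values()
        )
        if len(order) != len(sigma_grid):
            raise ValueError(
                f"{len(order)} media in dataset but {len(sigma_grid)} grid points"
            )
        t["sigma"] = t["medium"].map(dict(zip(order.index, np.sort(sigma_grid))))
        return t

    def filtered(self, sigma_grid: np.ndarray) -> pd.DataFrame:
        """Records entering the likelihood: lambda > 0.3 only, with phi_r."""
        t = self.with_sigma(sigma_grid)
        t = t[t["lambda_per_h"] > LAMBDA_FILTER].copy()
        t["phi_r"] = t["rna_protein_ratio"] * RNA_PROTEIN_TO_PHI_R
        return t


def _apply_theta(params: HostParams, names, theta) -> tuple[HostParams, float]:
    """Host parameters and k_cm with the free parameters substituted."""
    kw = {}
    k_cm = ChloramphenicolParams().k_cm
    for name, value in zip(names, theta):
        if name == "nu_max":
            kw["nu_max"] = value
        elif name == "K":
            kw["K_eps"] = value
            kw["K_nu"] = value
        elif name == "alpha_ratio":
            kw["alpha_r"] = params.alpha_a * value
        elif name == "k_cm":
            k_cm = value
    return (params.replace(**kw) if kw else params), k_cm


def _model_observables(params: HostParams, k_cm: float, sigma: float, h_cm: float):
    """(lambda, phi_r) at one condition; phi_r counts inactivated ribosomes."""
    cm = ChloramphenicolParams(h_cm=h_cm, k_cm=k_cm) if h_cm > 0 else None
    sol = solve_host_steady_state(params, cm=cm, sigma=sigma)
    phi_r = params.n_r * (sol["R"] + sol["B_cm"]) / params.M
    return sol["lam"], phi_r


def synthesize_growth_law_data(
    theta_true: dict[str, float] | None = None,
    noise_cv: float = 0.02,
    seed: int = 0,
    params: HostParams | None = None,
    config: FitConfig | None = None,
) -> GrowthLawDataset:
    """Generate a synthetic growth-law dataset from the model itself.

    The model is evaluated on the 6-point sigma grid crossed with
    chloramphenicol levels {0, 2, 4, 8} uM; ribosomal mass fractions are
    converted back to RNA:protein ratios via 1/0.4558 and both observables
    are multiplied by lognormal noise with coefficient of variation
    ``noise_cv``.  Conditions where the model predicts growth collapse are
    skipped (real datasets lack such cultures too).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if params is None:
        from .params import default_host_params
        params = default_host_params()
    config = config or FitConfig()
    theta_true = theta_true or {}
    names = tuple(theta_true)
    p, k_cm = _apply_theta(params, names, [theta_true[n] for n in names])
    rng = np.random.default_rng(seed)
    sd = np.sqrt(np.log1p(noise_cv ** 2))
    rows = []
    for i, sigma in enumerate(np.sort(config.sigma_grid)):
        for h in config.cm_grid:
            try:
                lam, phi_r = _model_observables(p, k_cm, float(sigma), float(h))
            except RuntimeError:
                continue
            ratio = phi_r / RNA_PROTEIN_TO_PHI_R
            if noise_cv > 0:
                lam *= np.exp(rng.normal(-0.5 * sd * sd, sd))
                ratio *= np.exp(rng.normal(-0.5 * sd * sd, sd))
            rows.append({"medium": f"M{i + 1}", "sigma": float(sigma),
                         "cm_uM": float(h), "lambda_per_h": float(lam),
                         "rna_protein_ratio": float(ratio)})
    return GrowthLawDataset(pd.DataFrame(rows))


def _prepare_likelihood(data: GrowthLawDataset, config: FitConfig):
    t = data.filtered(np.sort(config.sigma_grid))
    lam_obs = t["lambda_per_h"].to_numpy()
    phi_obs = t["phi_r"].to_numpy()
    conds = list(zip(t["sigma"].to_numpy(), t["cm_uM"].to_numpy()))
    sd_lam = max(config.error_scale_fraction * np.ptp(lam_obs), 1e-3)
    sd_phi = max(config.error_scale_fraction * np.ptp(phi_obs), 1e-4)
    return conds, lam_obs, phi_obs, sd_lam, sd_phi


def log_likelihood(
    theta: np.ndarray,
    data: GrowthLawDataset,
    config: FitConfig,
    params: HostParams | None = None,
    _prepared=None,
) -> float:
    """Gaussian log-likelihood of the growth-law data under parameters theta.

    Each retained record contributes independent Gaussian errors on the
    growth rate and on the ribosomal mass fraction, with per-observable
    error scales set to 5% of that observable's range in the data.  A
    condition where the model predicts growth collapse contributes a large
    negative penalty rather than raising.
    """
    if params is None:
        from .params import default_host_params
        params = default_host_params()
    means = config.resolved_prior_means(params)
    theta = np.asarray(theta, float)
    if np.any(theta < means / 50.0) or np.any(theta > means * 50.0):
        return -np.inf
    conds, lam_obs, phi_obs, sd_lam, sd_phi = (
        _prepared if _prepared is not None else _prepare_likelihood(data, config)
    )
    p, k_cm = _apply_theta(params, config.free_params, theta)
    ll = 0.0
    for (sigma, h), lo, po in zip(conds, lam_obs, phi_obs):
        try:
            lam, phi_r = _model_observables(p, k_cm, sigma, h)
        except RuntimeError:
            ll += -1e8
            continue
        ll += -0.5 * ((lam - lo) / sd_lam) ** 2 - 0.5 * ((phi_r - po) / sd_phi) ** 2
    return ll


@dataclass
class DreamResult:
    chains: np.ndarray          # (n_chains, n_kept, d)
    log_post: np.ndarray        # (n_chains, n_kept)
    mode: np.ndarray            # (d,) MAP sample
    mode_log_post: float
    r_hat: np.ndarray           # (d,) Gelman-Rubin statistic on kept samples
    acceptance_rate: float
    param_names: tuple[str, ...]

    def mode_dict(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.mode))


def _gelman_rubin(chains: np.ndarray) -> np.ndarray:
    """Potential scale reduction factor per dimension; chains (m, n, d)."""
    m, n, d = chains.shape
    means = chains.mean(axis=1)                      # (m, d)
    B = n * means.var(axis=0, ddof=1)                # between-chain
    W = chains.var(axis=1, ddof=1).mean(axis=0)      # within-chain
    var_plus = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(var_plus / W)
    return np.where(W > 0, r, 1.0)


def dream_sample(
    data: GrowthLawDataset,
    config: FitConfig,
    params: HostParams | None = None,
    log_prob=None,
) -> DreamResult:
    """DREAM-style adaptive differential-evolution MCMC.

    Proposals for chain i are x* = x_i + gamma*(x_r1 - x_r2) restricted to an
    adaptively chosen random subset of dimensions, with
    gamma = 2.38/sqrt(2*d_eff) and a 10% share of gamma = 1 jumps; crossover
    probabilities are adapted during burn-in toward the values that moved the
    chains farthest.  Positions are reflected at the prior bounds.  The
    returned mode is the best (maximum-posterior) sample seen.
    """
    if params is None:
        from .params import default_host_params
        params = default_host_params()
    rng = np.random.default_rng(config.seed)
    means = config.resolved_prior_means(params)
    sds = means / 4.0
    lo, hi = means / 50.0, means * 50.0
    d = len(means)
    m = config.n_chains

    prepared = _prepare_likelihood(data, config)

    def log_prior(x):
        return float(-0.5 * np.sum(((x - means) / sds) ** 2))

    if log_prob is None:
        def log_prob(x):
            ll = log_likelihood(x, data, config, params=params, _prepared=prepared)
            return ll + log_prior(x) if np.isfinite(ll) else -np.inf

    # initial population: prior draws clipped to bounds
    X = rng.normal(means, sds, size=(m, d))
    X = np.clip(X, lo * 1.0001, hi * 0.9999)
    lp = np.array([log_prob(x) for x in X])

    CR_pool = np.array([0.3, 0.6, 1.0])
    CR_weight = np.ones(3)
    CR_gain = np.zeros(3)
    CR_count = np.ones(3)

    n_steps = config.n_steps
    burn = int(config.burn_in_fraction * n_steps)
    kept_X = np.empty((m, n_steps - burn, d))
    kept_lp = np.empty((m, n_steps - burn))
    best_x, best_lp = X[np.argmax(lp)].copy(), float(np.max(lp))
    n_accept = 0

    for step in range(n_steps):
        for i in range(m):
            r1, r2 = rng.choice([j for j in range(m) if j != i], size=2, replace=False)
            ci = rng.choice(3, p=CR_weight / CR_weight.sum())
            mask = rng.random(d) <= CR_pool[ci]
            if not mask.any():
                mask[rng.integers(d)] = True
            d_eff = int(mask.sum())
            gamma = 1.0 if rng.random() < 0.1 else 2.38 / np.sqrt(2.0 * d_eff)
            jitter = 1e-6 * sds * rng.standard_normal(d)
            prop = X[i].copy()
            prop[mask] = (X[i] + gamma * (X[r1] - X[r2]))[mask] + jitter[mask]
            # reflect at bounds
            prop = np.where(prop < lo, 2 * lo - prop, prop)
            prop = np.where(prop > hi, 2 * hi - prop, prop)
            prop = np.clip(prop, lo, hi)
            lp_prop = log_prob(prop)
            if np.log(rng.random()) < lp_prop - lp[i]:
                move = np.sum(((prop - X[i]) / sds) ** 2)
                X[i], lp[i] = prop, lp_prop
                n_accept += 1
                if step < burn:
                    CR_gain[ci] += move
            if step < burn:
                CR_count[ci] += 1
        if step == burn - 1:
            gains = CR_gain / CR_count
            if gains.sum() > 0:
                CR_weight = 0.1 + gains / gains.sum()
        if step >= burn:
            kept_X[:, step - burn] = X
            kept_lp[:, step - burn] = lp
        j = int(np.argmax(lp))
        if lp[j] > best_lp:
            best_lp, best_x = float(lp[j]), X[j].copy()

    if not np.isfinite(kept_lp).any():
        raise RuntimeError("all chains degenerate: no finite posterior values")
    r_hat = _gelman_rubin(kept_X)
    return DreamResult(
        chains=kept_X, log_post=kept_lp, mode=best_x, mode_log_post=best_lp,
        r_hat=r_hat, acceptance_rate=n_accept / (m * n_steps),
        param_names=tuple(config.free_params),
    )
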