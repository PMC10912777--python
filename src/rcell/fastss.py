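"""Algebraic steady-state solver for the host (+ antibiotic, + constitutive genes).

At steady state the full system collapses exactly onto three unknowns
(lam, t_c, t_u): every mRNA level follows from lam, every protein level from
the translation-share identity n_j*p_j = M*w_j/Sum(w) with w_j = m_j/k_j,
and the remaining balances are

    (eps/n_r)*w_r/D = lam + q*Sum(w)/D        (operational-ribosome balance,
                                               q = k_cm*h_cm)
    nu(t_u)*p_a     = lam*(M + t_c)           (charged-tRNA balance, eps*B = lam*M)
    t_c + t_u       = psi(T)                  (total tRNA balance)

This reduction holds for any number of *constitutive, growth-coupled*
synthetic genes, so burden sweeps and the fitting likelihood can avoid long
stiff integrations.  It is validated against the integration path in the
test suite.  Regulated circuits (self-activators, the AIF controller) do not
reduce this way and always go through time integration.

A damped Newton iteration in log-space does the solving; numba compiles the
hot loop when available, with a pure-NumPy fallback otherwise.
"""

from __future__ import annotations

import numpy as np

from .circuits import CircuitSpec
from .params import ChloramphenicolParams, HostParams

__all__ = ["solve_host_steady_state", "pack_params"]

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap


_NP = 22  # number of scalar parameter slots before the per-gene block


def pack_params(
    params: HostParams,
    cm: ChloramphenicolParams | None = None,
    spec: CircuitSpec | None = None,
    fixed_T: float = -1.0,
    sigma: float | None = None,
) -> np.ndarray:
    """Flatten parameters into the array layout the numba kernel expects."""
    q = cm.k_cm * cm.h_cm if cm is not None else 0.0
    genes = list(spec.genes) if spec is not None else []
    for g in genes:
        if g.regulation.kind != "constitutive" or g.toxicity_K is not None \
                or g.protein_degradation != 0.0:
            raise ValueError(
                "algebraic steady state supports constitutive non-toxic "
                f"genes only (gene {g.name!r} is not)"
            )
    if spec is not None and spec.rnas:
        raise ValueError("algebraic steady state does not support sRNA species")
    p = np.zeros(_NP + 6 * len(genes))
    p[0] = params.M
    p[1] = params.phi_q
    p[2] = params.eps_max
    p[3] = params.K_eps
    p[4] = params.nu_max
    p[5] = params.K_nu
    p[6] = params.psi_max
    p[7] = params.tau
    p[8] = sigma if sigma is not None else params.sigma
    p[9] = params.c_a * params.alpha_a
    p[10] = params.beta_a
    p[11] = params.n_a
    p[12] = params.k_plus_a
    p[13] = params.k_minus_a
    p[14] = params.c_r * params.alpha_r
    p[15] = params.beta_r
    p[16] = params.n_r
    p[17] = params.k_plus_r
    p[18] = params.k_minus_r
    p[19] = q
    p[20] = fixed_T
    p[21] = float(len(genes))
    for i, g in enumerate(genes):
        base = _NP + 6 * i
        p[base] = g.c * g.alpha
        p[base + 1] = g.beta
        p[base + 2] = g.n
        p[base + 3] = g.k_plus
        p[base + 4] = g.k_minus
        p[base + 5] = 1.0 if g.growth_coupled_transcription else 0.0
    return p


@njit(cache=True)
def _residual(y: np.ndarray, p: np.ndarray) -> np.ndarray:
    lam = np.exp(y[0])
    t_c = np.exp(y[1])
    t_u = np.exp(y[2])
    # guard against under/overflow of the log-space iterate
    if lam < 1e-300:
        lam = 1e-300
    elif lam > 1e12:
        lam = 1e12
    if t_c < 1e-300:
        t_c = 1e-300
    elif t_c > 1e150:
        t_c = 1e150
    if t_u < 1e-300:
        t_u = 1e-300
    elif t_u > 1e150:
        t_u = 1e150
    M, phi_q, eps_max, K_eps, nu_max, K_nu, psi_max, tau, sigma = p[0:9]
    ca_aa, beta_a, n_a, kp_a, km_a = p[9:14]
    cr_ar, beta_r, n_r, kp_r, km_r = p[14:19]
    q = p[19]
    Tfix = p[20]
    ngenes = int(p[21])

    eps = eps_max / (1.0 + K_eps / t_c)     # overflow-safe Michaelis-Menten
    nu = nu_max * sigma / (1.0 + K_nu / t_u)
    T = t_c / t_u if t_c < t_u * 1e12 else 1e12
    if Tfix > 0.0:
        F_r = Tfix / (Tfix + tau)
    else:
        F_r = T / (T + tau)
    psi = psi_max * F_r
    if psi < 1e-300:
        psi = 1e-300

    k_a = (km_a + eps / n_a + q) / kp_a
    k_r = (km_r + eps / n_r + q) / kp_r
    w_a = ca_aa * lam / ((beta_a + lam) * k_a)
    w_r = F_r * cr_ar * lam / ((beta_r + lam) * k_r)
    w_sum = w_a + w_r
    for i in range(ngenes):
        base = _NP + 6 * i
        k_x = (p[base + 4] + eps / p[base + 2] + q) / p[base + 3]
        txn = p[base] * lam if p[base + 5] > 0.0 else p[base]
        w_sum += txn / ((p[base + 1] + lam) * k_x)
    D = 1.0 + w_sum / (1.0 - phi_q)
    p_a = M * w_a / (n_a * w_sum)

    r = np.empty(3)
    r[0] = (eps / n_r) * w_r / D - lam - q * w_sum / D
    r[1] = nu * p_a / (lam * M) - 1.0 - t_c / M
    r[2] = (t_c + t_u) / psi - 1.0
    return r


@njit(cache=True)
def _newton(y0: np.ndarray, p: np.ndarray, tol: float, max_iter: int):
    y = y0.copy()
    r = _residual(y, p)
    for _ in range(max_iter):
        nr = np.sqrt((r * r).sum())
        if nr < tol:
            return y, True
        # finite-difference Jacobian
        J = np.empty((3, 3))
        h = 1e-7
        for j in range(3):
            yh = y.copy()
            yh[j] += h
            rh = _residual(yh, p)
            for i in range(3):
                J[i, j] = (rh[i] - r[i]) / h
        if not np.isfinite(J).all():
            return y, False
        # guarded 3x3 solve (Cramer); np.linalg.solve raises on singular input
        det = (J[0, 0] * (J[1, 1] * J[2, 2] - J[1, 2] * J[2, 1])
               - J[0, 1] * (J[1, 0] * J[2, 2] - J[1, 2] * J[2, 0])
               + J[0, 2] * (J[1, 0] * J[2, 1] - J[1, 1] * J[2, 0]))
        if not np.isfinite(det) or abs(det) < 1e-300:
            return y, False
        b = -r
        step = np.empty(3)
        step[0] = (b[0] * (J[1, 1] * J[2, 2] - J[1, 2] * J[2, 1])
                   - J[0, 1] * (b[1] * J[2, 2] - J[1, 2] * b[2])
                   + J[0, 2] * (b[1] * J[2, 1] - J[1, 1] * b[2])) / det
        step[1] = (J[0, 0] * (b[1] * J[2, 2] - J[1, 2] * b[2])
                   - b[0] * (J[1, 0] * J[2, 2] - J[1, 2] * J[2, 0])
                   + J[0, 2] * (J[1, 0] * b[2] - b[1] * J[2, 0])) / det
        step[2] = (J[0, 0] * (J[1, 1] * b[2] - b[1] * J[2, 1])
                   - J[0, 1] * (J[1, 0] * b[2] - b[1] * J[2, 0])
                   + b[0] * (J[1, 0] * J[2, 1] - J[1, 1] * J[2, 0])) / det
        # damped line search
        t = 1.0
        ok = False
        for _ in range(40):
            y_new = y + t * step
            r_new = _residual(y_new, p)
            if np.isfinite(r_new).all() and np.sqrt((r_new * r_new).sum()) < nr:
                y, r = y_new, r_new
                ok = True
                break
            t *= 0.5
        if not ok:
            return y, False
    nr = np.sqrt((r * r).sum())
    return y, nr < tol


@njit(cache=True)
def _solve(p: np.ndarray, tol: float):
    K_eps = p[3]
    # multi-start over growth rate and tRNA ratio guesses
    lam_guesses = np.array([1.0, 0.3, 2.0, 0.05, 3.0])
    T_guesses = np.array([1.0, 0.2, 5.0])
    for li in range(lam_guesses.shape[0]):
        for ti in range(T_guesses.shape[0]):
            tc0 = K_eps
            tu0 = tc0 / T_guesses[ti]
            y0 = np.array([np.log(lam_guesses[li]), np.log(tc0), np.log(tu0)])
            y, ok = _newton(y0, p, tol, 60)
            if ok:
                return y, True
    return np.zeros(3), False


def solve_host_steady_state(
    params: HostParams,
    cm: ChloramphenicolParams | None = None,
    spec: CircuitSpec | None = None,
    sigma: float | None = None,
    fixed_T: float = -1.0,
    tol: float = 1e-12,
) -> dict:
    """Steady state of host (+cm, +constitutive genes) by root finding.

    Returns a dict with the full state (host variables, B_cm, per-gene m_x
    and p_x) plus lam, eps, nu, T, F_r, psi, D, B and convergence flag.
    Raises ``RuntimeError`` if no root is found from any starting point.
    """
    p = pack_params(params, cm, spec, fixed_T, sigma)
    y, ok = _solve(p, tol)
    if not ok:
        raise RuntimeError("algebraic steady-state solve did not converge")
    lam, t_c, t_u = np.exp(y)
    sig = sigma if sigma is not None else params.sigma
    q = p[19]
    eps = params.eps_max * t_c / (t_c + params.K_eps)
    nu = params.nu_max * sig * t_u / (t_u + params.K_nu)
    T = t_c / t_u
    F_r = (fixed_T / (fixed_T + params.tau)) if fixed_T > 0 else T / (T + params.tau)
    psi = params.psi_max * F_r
    k_a = (params.k_minus_a + eps / params.n_a + q) / params.k_plus_a
    k_r = (params.k_minus_r + eps / params.n_r + q) / params.k_plus_r
    m_a = params.c_a * params.alpha_a * lam / (params.beta_a + lam)
    m_r = F_r * params.c_r * params.alpha_r * lam / (params.beta_r + lam)
    w_a, w_r = m_a / k_a, m_r / k_r
    w_sum = w_a + w_r
    genes = list(spec.genes) if spec is not None else []
    gene_out = {}
    for g in genes:
        k_x = (g.k_minus + eps / g.n + q) / g.k_plus
        txn = g.c * g.alpha * (lam if g.growth_coupled_transcription else 1.0)
        m_x = txn / (g.beta + lam)
        gene_out[g.name] = {"m": m_x, "k": k_x, "w": m_x / k_x}
        w_sum += m_x / k_x
    D = 1.0 + w_sum / (1.0 - params.phi_q)
    R = lam * D * params.M / (eps * w_sum)
    B = w_sum / D * R
    p_a = params.M * w_a / (params.n_a * w_sum)
    for g in genes:
        gene_out[g.name]["p"] = params.M * gene_out[g.name]["w"] / (g.n * w_sum)
    B_cm = q * B / lam if q > 0 else 0.0
    return {
        "lam": lam, "t_c": t_c, "t_u": t_u, "eps": eps, "nu": nu, "T": T,
        "F_r": F_r, "psi": psi, "D": D, "B": B, "R": R, "p_a": p_a,
        "m_a": m_a, "m_r": m_r, "k_a": k_a, "k_r": k_r, "B_cm": B_cm,
        "genes": gene_out, "converged": True,
    }
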