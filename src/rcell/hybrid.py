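"""Hybrid deterministic/tau-leaping simulation of host + circuit.

The six host variables are coarse-grained averages over many molecular
species, so they are advanced deterministically (explicit Euler at the leap
step, which is far below every host timescale).  Circuit species are held as
integer molecule counts — with an E. coli volume of ~1 um^3, 1 nM
corresponds to one molecule per cell — and updated by Poisson-distributed
firings of transcription, translation, degradation, dilution and
annihilation channels in each leap.

If a leap would drive a count negative, it is re-drawn as ten sub-leaps at
dt/10 (with residual negatives clamped at zero); dilution of stochastic
species is a first-order decay channel at rate lam, as the model has no
explicit division events.
"""

from __future__ import annotations

import numpy as np

from .circuits import CircuitSpec
from .params import ChloramphenicolParams, HostParams

try:  # pragma: no cover
    from numba import njit
except Exception:  # pragma: no cover
    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap

__all__ = ["hybrid_simulate"]

# regulation kind codes
_REG_CONST, _REG_ACT, _REG_REP = 0, 1, 2


def _encode_circuit(spec: CircuitSpec):
    """Flatten a CircuitSpec into arrays the numba kernel can use."""
    names = spec.species_names()
    idx = {n: i for i, n in enumerate(names)}
    ng, nr = len(spec.genes), len(spec.rnas)
    gene_par = np.zeros((ng, 9))
    gene_reg = np.zeros((ng, 5))
    for i, g in enumerate(spec.genes):
        gene_par[i] = [g.c * g.alpha, g.beta, g.n, g.k_plus, g.k_minus,
                       1.0 if g.growth_coupled_transcription else 0.0,
                       g.protein_degradation,
                       g.toxicity_K if g.toxicity_K is not None else np.inf,
                       g.onset_time]
        gene_reg[i] = _encode_reg(g.regulation, idx)
    rna_par = np.zeros((nr, 2))
    rna_reg = np.zeros((nr, 5))
    for i, r in enumerate(spec.rnas):
        rna_par[i] = [r.transcription_rate, r.beta]
        rna_reg[i] = _encode_reg(r.regulation, idx)
    ann = np.zeros((len(spec.annihilations), 3))
    for i, (a, b, theta) in enumerate(spec.annihilations):
        ann[i] = [idx[a], idx[b], theta]
    return gene_par, gene_reg, rna_par, rna_reg, ann


def _encode_reg(reg, idx):
    if reg.kind == "constitutive":
        return [_REG_CONST, -1, 1.0, 1.0, 0.0]
    kind = _REG_REP if reg.kind == "hill_repression" else _REG_ACT
    scale = (reg.inducer_level / (reg.inducer_level + reg.inducer_K)
             if reg.inducer_K > 0 else 1.0)
    # the inducer-bound fraction enters as a rescaling of the half-saturation
    K_eff = reg.K / scale if scale > 0 else np.inf
    return [kind, idx[reg.regulator], K_eff, reg.hill, reg.baseline]


def _pack_host(params: HostParams, cm: ChloramphenicolParams | None):
    q = cm.k_cm * cm.h_cm if cm is not None else 0.0
    return np.array([
        params.M, params.phi_q, params.eps_max, params.K_eps, params.nu_max,
        params.K_nu, params.psi_max, params.tau, params.sigma,
        params.c_a * params.alpha_a, params.beta_a, params.n_a,
        params.k_plus_a, params.k_minus_a,
        params.c_r * params.alpha_r, params.beta_r, params.n_r,
        params.k_plus_r, params.k_minus_r, q,
    ])


@njit(cache=True)
def _reg_F(code, target, K, hill, baseline, counts):
    if code == _REG_CONST:
        return 1.0
    p = counts[int(target)]
    if p < 0.0:
        p = 0.0
    x = (p / K) ** hill
    act = x / (1.0 + x)
    if code == _REG_REP:
        act = 1.0 - act
    return baseline + (1.0 - baseline) * act


@njit(cache=True)
def _exp_step(x, prod, a, dt):
    if a <= 0.0:
        return x + prod * dt
    x_inf = prod / a
    return x_inf + (x - x_inf) * np.exp(-a * dt)


@njit(cache=True)
def _kernel(hp, host0, counts0, gene_par, gene_reg, rna_par, rna_reg, ann,
            t_end, dt, record_every, seed):
    np.random.seed(seed)
    n_rec = int(t_end / record_every) + 1
    ng = gene_par.shape[0]
    nr = rna_par.shape[0]
    ns = counts0.shape[0]
    rec_t = np.empty(n_rec)
    rec_host = np.empty((n_rec, 6))
    rec_counts = np.empty((n_rec, ns))
    host = host0.copy()
    counts = counts0.astype(np.float64)
    (M, phi_q, eps_max, K_eps, nu_max, K_nu, psi_max, tau, sigma,
     ca_aa, beta_a, n_a, kp_a, km_a, cr_ar, beta_r, n_r, kp_r, km_r, q) = hp

    n_steps = int(round(t_end / dt))
    rec_stride = max(int(round(record_every / dt)), 1)
    ri = 0
    new_counts = np.empty(ns)
    for step in range(n_steps + 1):
        t = step * dt
        m_a, m_r, p_a, R, t_c, t_u = host
        # toxicity poisons translation: scale the max elongation rate
        tox = 1.0
        for i in range(ng):
            if np.isfinite(gene_par[i, 7]):
                tox += counts[2 * i + 1] / gene_par[i, 7]
        eps = (eps_max / tox) * t_c / (t_c + K_eps) if t_c > 0 else 0.0
        nu = nu_max * sigma * t_u / (t_u + K_nu) if t_u > 0 else 0.0
        T = (t_c / t_u) if t_u > 0 else 1e12
        F_r = T / (T + tau)
        psi = psi_max * F_r
        k_a = (km_a + eps / n_a + q) / kp_a
        k_r = (km_r + eps / n_r + q) / kp_r
        w = m_a / k_a + m_r / k_r
        for i in range(ng):
            k_x = (gene_par[i, 4] + eps / gene_par[i, 2] + q) / gene_par[i, 3]
            w += counts[2 * i] / k_x
        D = 1.0 + w / (1.0 - phi_q)
        B = w / D * R
        lam = eps * B / M
        if step % rec_stride == 0 and ri < n_rec:
            rec_t[ri] = t
            rec_host[ri] = host
            rec_counts[ri] = counts
            ri += 1
        if step == n_steps:
            break

        # deterministic host update: exponential Euler per variable
        # (x' = prod - a*x  ->  x_new = prod/a + (x - prod/a)*exp(-a*dt));
        # unconditionally stable despite the millisecond tRNA turnover.
        host[0] = _exp_step(m_a, ca_aa * lam, beta_a + lam, dt)
        host[1] = _exp_step(m_r, F_r * cr_ar * lam, beta_r + lam, dt)
        host[2] = _exp_step(p_a, eps / n_a * (m_a / k_a) / D * R, lam, dt)
        host[3] = _exp_step(R, eps / n_r * (m_r / k_r) / D * R, lam, dt)
        a_tc = (eps * B / t_c + lam) if t_c > 0.0 else lam
        host[4] = _exp_step(t_c, nu * p_a, a_tc, dt)
        a_tu = (nu * p_a / t_u + lam) if t_u > 0.0 else lam
        host[5] = _exp_step(t_u, psi * lam + eps * B, a_tu, dt)

        # stochastic circuit update: try dt, redraw at dt/10 on negativity
        for attempt in range(2):
            sub = 1 if attempt == 0 else 10
            h = dt / sub
            for j in range(ns):
                new_counts[j] = counts[j]
            ok = True
            for _ in range(sub):
                for i in range(ng):
                    F = _reg_F(gene_reg[i, 0], gene_reg[i, 1], gene_reg[i, 2],
                               gene_reg[i, 3], gene_reg[i, 4], new_counts)
                    if t < gene_par[i, 8]:
                        F = 0.0
                    k_x = (gene_par[i, 4] + eps / gene_par[i, 2] + q) / gene_par[i, 3]
                    txn = F * gene_par[i, 0] * (lam if gene_par[i, 5] > 0 else 1.0)
                    m_x = new_counts[2 * i]
                    p_x = new_counts[2 * i + 1]
                    d_m = (np.random.poisson(txn * h)
                           - np.random.poisson((gene_par[i, 1] + lam) * m_x * h))
                    d_p = (np.random.poisson(eps / gene_par[i, 2] * (m_x / k_x) / D * R * h)
                           - np.random.poisson((lam + gene_par[i, 6]) * p_x * h))
                    new_counts[2 * i] = m_x + d_m
                    new_counts[2 * i + 1] = p_x + d_p
                for i in range(nr):
                    F = _reg_F(rna_reg[i, 0], rna_reg[i, 1], rna_reg[i, 2],
                               rna_reg[i, 3], rna_reg[i, 4], new_counts)
                    x = new_counts[2 * ng + i]
                    d_x = (np.random.poisson(rna_par[i, 0] * F * lam * h)
                           - np.random.poisson((rna_par[i, 1] + lam) * x * h))
                    new_counts[2 * ng + i] = x + d_x
                for i in range(ann.shape[0]):
                    ia, ib = int(ann[i, 0]), int(ann[i, 1])
                    a_ct, b_ct = new_counts[ia], new_counts[ib]
                    if a_ct > 0 and b_ct > 0:
                        fired = np.random.poisson(ann[i, 2] * a_ct * b_ct * h)
                        new_counts[ia] = a_ct - fired
                        new_counts[ib] = b_ct - fired
                neg = False
                for j in range(ns):
                    if new_counts[j] < 0.0:
                        neg = True
                if neg and attempt == 0:
                    ok = False
                    break
                if neg:  # second attempt: clamp
                    for j in range(ns):
                        if new_counts[j] < 0.0:
                            new_counts[j] = 0.0
            if ok:
                break
        for j in range(ns):
            counts[j] = new_counts[j]
    return rec_t[:ri], rec_host[:ri], rec_counts[:ri]


def hybrid_simulate(
    params: HostParams,
    spec: CircuitSpec,
    t_span: float,
    seed: int,
    dt: float = 1e-6,
    init: np.ndarray | None = None,
    cm: ChloramphenicolParams | None = None,
    record_every: float = 0.1,
):
    """Hybrid stochastic trajectory; identical seeds give identical paths.

    ``init`` is a full state vector (host then circuit, circuit entries in
    molecules = nM); by default the host starts from the generic initial
    condition with all circuit counts at zero.  Returns a
    `rcell.simulate.Trajectory` whose circuit columns are integer counts.
    """
    from .simulate import Trajectory, default_initial_state, _names

    if dt <= 0:
        raise ValueError("dt must be > 0")
    if seed is None:
        raise ValueError("hybrid simulation requires an explicit seed")
    if cm is not None:
        raise NotImplementedError(
            "hybrid mode does not track inactivated ribosomes; "
            "use deterministic integration for antibiotic scenarios"
        )
    x0 = default_initial_state(params, spec, cm=None) if init is None else np.asarray(init, float)
    host0 = x0[:6].astype(float)
    counts0 = np.round(x0[6:6 + spec.n_species])
    gene_par, gene_reg, rna_par, rna_reg, ann = _encode_circuit(spec)
    hp = _pack_host(params, cm)
    t, host, counts = _kernel(hp, host0, counts0, gene_par, gene_reg,
                              rna_par, rna_reg, ann, float(t_span), float(dt),
                              float(record_every), int(seed) & 0x7FFFFFFF)
    states = np.hstack([host, counts])
    return Trajectory(times=t, states=states, names=_names(spec, None),
                      params=params, spec=spec, cm=None, seed=seed)
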