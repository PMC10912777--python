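"""Headline scenarios at desk scale: growth laws, ppGpp optimality, burden
sweeps, the two self-activator case studies and the antithetic controller.

Each ``run_*`` function returns a dict of tidy DataFrames; `rcell.io`
serializes them.  These are also the computations behind the acceptance
script, so every quantitative claim in the README is reproducible from here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .burden import (
    native_burden_sum,
    optimal_burden,
    population_production_rate,
    predict_lambda,
    predict_phi_X,
    production_rate_curve,
    translational_burden,
    ControllerDesign,
    controller_setpoints,
    operation_range,
)
from .circuits import (
    CircuitSpec,
    build_aif_controller,
    build_constitutive_gene,
    build_disturbance_gene,
    build_inducible_module,
    build_t7_self_activator,
    build_winner_takes_all,
)
from .params import ChloramphenicolParams, default_host_params
from .simulate import (
    constant_T_optimal_growth,
    default_initial_state,
    fast_steady_state,
    integrate,
    multi_start_steady_states,
    no_burden_reference,
    steady_state,
)

__all__ = [n for n in dir() if n.startswith("run_")]

# default controller/disturbance working points (sigma = 0.5 unless varied)
AIF_KW = dict()                       # builder defaults are the design point
DIST_KW = dict(c=30.0, alpha=1000.0)  # in-range disturbance (see run_aif_range)


def _ss(params, spec, fast=True, **kw):
    if fast and not spec.rnas and all(
        g.regulation.kind == "constitutive" and g.toxicity_K is None
        and g.protein_degradation == 0.0 for g in spec.genes
    ):
        return fast_steady_state(params, spec)
    return steady_state(params, spec, **kw)


def run_growth_laws(seed: int = 0, fast: bool = True) -> dict[str, pd.DataFrame]:
    """First and second bacterial growth laws from steady-state sweeps."""
    p = default_host_params()
    rows = []
    for sigma in np.linspace(0.2, 1.0, 15):
        ss = _ss(p.replace(sigma=sigma), CircuitSpec(name="none"), fast)
        rows.append({"sigma": sigma, "lambda_per_h": ss.derived.lam,
                     "phi_r": p.n_r * ss["R"] / p.M})
    first = pd.DataFrame(rows)
    rows = []
    for sigma in (0.25, 0.35, 0.5):
        for h in (0.0, 2.0, 4.0, 8.0):
            cm = ChloramphenicolParams(h_cm=h) if h > 0 else None
            ss = fast_steady_state(p.replace(sigma=sigma), cm=cm) if fast else \
                steady_state(p.replace(sigma=sigma), cm=cm)
            phi = p.n_r * (ss["R"] + (ss["B_cm"] if h > 0 else 0.0)) / p.M
            rows.append({"sigma": sigma, "h_cm_uM": h,
                         "lambda_per_h": ss.derived.lam, "phi_r": phi})
    second = pd.DataFrame(rows)
    lam, phi = first["lambda_per_h"], first["phi_r"]
    r2 = float(np.corrcoef(lam, phi)[0, 1] ** 2)
    summary = pd.DataFrame([{"first_law_r_squared": r2}])
    return {"first_law": first, "second_law": second, "summary": summary}


def run_optimality(seed: int = 0, fast: bool = True,
                   n_sigma: int = 20) -> dict[str, pd.DataFrame]:
    """Regulated growth vs the constant-ppGpp optimum across nutrient qualities."""
    p = default_host_params()
    rows = []
    for sigma in np.linspace(0.05, 1.0, n_sigma):
        lam_reg = _ss(p.replace(sigma=sigma), CircuitSpec(name="none"), fast).derived.lam
        method = "fast" if fast else "integrate"
        lam_opt, T_opt = constant_T_optimal_growth(p, sigma=sigma, method=method)
        rows.append({"sigma": sigma, "lambda_regulated": lam_reg,
                     "lambda_optimal": lam_opt, "T_optimal": T_opt,
                     "ratio": lam_reg / lam_opt})
    df = pd.DataFrame(rows)
    summary = pd.DataFrame([{"min_ratio": df["ratio"].min(),
                             "max_deficit_percent": 100 * (1 - df["ratio"].min())}])
    return {"optimality": df, "summary": summary}


def run_burden_sweep(seed: int = 0, fast: bool = True, n_c: int = 25,
                     delta: float = 0.25) -> dict[str, pd.DataFrame]:
    """Constitutive-gene dose sweep: burden, mass fraction, growth, production."""
    from dataclasses import replace as dc_replace

    p = default_host_params()
    gene0 = build_constitutive_gene().genes[0]
    ref = no_burden_reference(p, genes=[gene0],
                              method="fast" if fast else "integrate")
    rows = []
    for c in np.geomspace(1.0, 1100.0, n_c):
        gene = dc_replace(gene0, c=float(c))
        spec = CircuitSpec(genes=[gene], name="sweep")
        ss = _ss(p, spec, fast, horizon=480.0)
        xi = translational_burden(gene, ref)
        lam = ss.derived.lam
        phi_sim = gene.n * ss[f"p_{gene.name}"] / p.M
        rows.append({
            "c_nM": c, "xi": xi,
            "phi_X_sim": phi_sim, "phi_X_pred": predict_phi_X(xi, p, ref),
            "lambda_sim": lam, "lambda_pred": predict_lambda(xi, p, ref),
            "lambda_ratio_sim": lam / ref.lambda_NB,
            "mu_per_cell": population_production_rate(phi_sim, lam, delta, p),
        })
    df = pd.DataFrame(rows)
    xi_max = optimal_burden(delta, p, ref)
    curve = production_rate_curve(np.geomspace(1.0, 1100.0, 60), delta, p, ref,
                                  gene0, method="fast" if fast else "integrate")
    summary = pd.DataFrame([{
        "delta_per_h": delta,
        "xi_max_analytic": xi_max,
        "xi_max_numeric": curve["xi_argmax"],
        "rel_difference": xi_max / curve["xi_argmax"] - 1.0,
        "native_burden_sum": native_burden_sum(p, ref),
        "lambda_NB": ref.lambda_NB,
    }])
    return {"sweep": df, "summary": summary}


# ---------------------------------------------------------------------------
# winner-takes-all
# ---------------------------------------------------------------------------

def _wta_outcome(params, f1, f2, k_plus=60.0):
    """Pre-equilibrate with no inducer, then step both inducers in."""
    spec0 = build_winner_takes_all(0.0, 0.0, k_plus=k_plus)
    base = steady_state(params, spec0, horizon=72.0)
    spec = build_winner_takes_all(f1, f2, k_plus=k_plus)
    ss = steady_state(params, spec, horizon=72.0, init=base.x)
    K = spec.genes[0].regulation.K
    iK = spec.genes[0].regulation.inducer_K
    act1 = ss["p_s1"] * f1 / (f1 + iK) > K if f1 > 0 else False
    act2 = ss["p_s2"] * f2 / (f2 + iK) > K if f2 > 0 else False
    return ss, act1, act2


def run_wta(seed: int = 0, fast: bool = True) -> dict[str, pd.DataFrame]:
    """Resource-mediated mutual exclusion of two co-hosted bistable switches."""
    p = default_host_params()
    rows = []
    for f1 in (4.0, 20.0, 50.0, 100.0, 200.0, 400.0, 800.0):
        ss, a1, a2 = _wta_outcome(p, f1, 20.0)
        rows.append({"f1_nM": f1, "f2_nM": 20.0, "p_s1": ss["p_s1"],
                     "p_s2": ss["p_s2"], "switch1_high": a1, "switch2_high": a2,
                     "lambda_per_h": ss.derived.lam})
    curve = pd.DataFrame(rows)
    # fading of the effect as ribosome demand is reduced (weaker RBS):
    # suppression = loser's level under asymmetric induction relative to its
    # co-activated level; -> 1 means no resource coupling left
    rows = []
    for factor in (1.0, 2.0, 5.0, 10.0):
        ss_co, *_ = _wta_outcome(p, 20.0, 20.0, k_plus=60.0 / factor)
        ss_ex, *_ = _wta_outcome(p, 800.0, 20.0, k_plus=60.0 / factor)
        rows.append({"rbs_weakening": factor,
                     "p_s2_symmetric": ss_co["p_s2"],
                     "p_s2_outcompeted": ss_ex["p_s2"],
                     "suppression_ratio": ss_ex["p_s2"] / ss_co["p_s2"]})
    fading = pd.DataFrame(rows)
    return {"induction_curve": curve, "fading": fading}


def run_t7(seed: int = 0, fast: bool = True) -> dict[str, pd.DataFrame]:
    """Bistability of the non-cooperative T7 RNAP self-activator."""
    p = default_host_params()
    spec = build_t7_self_activator()
    lo = default_initial_state(p, spec)
    hi = lo.copy()
    hi[6], hi[7] = 3.0e3, 2.5e5      # m_t7, p_t7 high start
    states = multi_start_steady_states(p, spec, [lo, hi], horizon=240.0)
    rows = [{"start": name, "p_t7": ss["p_t7"], "m_t7": ss["m_t7"],
             "lambda_per_h": ss.derived.lam, "converged": ss.converged}
            for name, ss in zip(("low", "high"), states)]
    # monostable control: weak feedback, no toxicity
    spec_mono = build_t7_self_activator(toxicity_K=None, alpha=300.0)
    lo2 = default_initial_state(p, spec_mono)
    hi2 = lo2.copy()
    hi2[7] = 2.5e5
    mono = multi_start_steady_states(p, spec_mono, [lo2, hi2], horizon=240.0)
    summary = pd.DataFrame([{"n_states_bistable": len(states),
                             "n_states_weak_feedback": len(mono)}])
    return {"states": pd.DataFrame(rows), "summary": summary}


# ---------------------------------------------------------------------------
# antithetic integral feedback controller
# ---------------------------------------------------------------------------

def _aif_pair(sigma: float, dist_kw: dict | None = None, onset: float = 25.0,
              horizon: float = 100.0, aif_kw: dict | None = None):
    """Closed- and open-loop systems with an optional disturbance step."""
    p = default_host_params().replace(sigma=sigma)
    aif = build_aif_controller(**(aif_kw or AIF_KW))
    sensor_only = CircuitSpec(genes=[g for g in aif.genes if g.name == "sens"],
                              name="open_loop")
    out = {}
    for label, spec in (("closed", aif), ("open", sensor_only)):
        if dist_kw is not None:
            dist = build_disturbance_gene(onset_time=onset, **dist_kw)
            spec = spec.merged(dist, name=f"{spec.name}+dist")
        out[label] = (p, spec)
    return out


def run_aif_step(seed: int = 0, fast: bool = True, sigma: float = 0.5,
                 horizon: float = 100.0, onset: float = 25.0) -> dict[str, pd.DataFrame]:
    """Step-disturbance rejection by the RNA-based antithetic controller."""
    tables = {}
    errors = {}
    for label, (p, spec) in _aif_pair(sigma, DIST_KW, onset, horizon).items():
        base = steady_state(p, spec, horizon=200.0)   # pre-disturbance steady state
        x0 = base.x.copy()
        # restart the clock: disturbance switches on at `onset`
        traj = integrate(p, spec, t_span=horizon, init=x0,
                         t_eval=np.linspace(0.0, horizon, 201))
        i0 = np.searchsorted(traj.times, onset) - 1
        p_ref = traj["p_sens"][i0]
        lam = np.array([traj.derived_at(i).lam for i in range(len(traj.times))])
        D = np.array([traj.derived_at(i).D for i in range(len(traj.times))])
        df = pd.DataFrame({
            "t_h": traj.times,
            "p_sens_rel": traj["p_sens"] / p_ref,
            "lambda_rel": lam / lam[i0],
            "D_rel": D / D[i0],
        })
        for col in ("m_amp", "m_act", "anti"):
            if col in traj.names:
                df[col] = traj[col]
        tables[label] = df
        errors[label] = abs(df["p_sens_rel"].iloc[-1] - 1.0)
    tables["summary"] = pd.DataFrame([{
        "sigma": sigma,
        "adaptation_error_closed": errors["closed"],
        "adaptation_error_open": errors["open"],
        "error_ratio": errors["closed"] / errors["open"],
    }])
    return tables


def closed_loop_growth(sigma: float, horizon: float = 96.0) -> float:
    """Undisturbed closed-loop steady-state growth rate at nutrient quality sigma."""
    p = default_host_params().replace(sigma=sigma)
    return steady_state(p, build_aif_controller(), horizon=horizon).derived.lam


def run_aif_range(seed: int = 0, fast: bool = True, sigma: float = 0.5,
                  n_c: int = 11) -> dict[str, pd.DataFrame]:
    """Operation range: disturbance magnitudes the controller can absorb."""
    p = default_host_params().replace(sigma=sigma)
    aif = build_aif_controller()
    sens = next(g for g in aif.genes if g.name == "sens")
    design = ControllerDesign(
        u=0.4, K_sens=aif.rnas[0].regulation.K,
        kappa=aif.rnas[0].transcription_rate,
        chi=next(g.alpha for g in aif.genes if g.name == "amp"),
        c_sens=sens.c, alpha_sens=sens.alpha, n_sens=sens.n, beta_sens=sens.beta,
    )
    ref = no_burden_reference(p)
    dist0 = build_disturbance_gene(**DIST_KW).genes[0]
    from dataclasses import replace as dc_replace

    rows = []
    base = {}
    for label, (pp, spec) in _aif_pair(sigma, None).items():
        base[label] = steady_state(pp, spec, horizon=200.0)
    for c_dist in np.geomspace(3.0, 700.0, n_c):
        dist = dc_replace(dist0, c=float(c_dist), onset_time=0.0)
        lhs, rhs, ok = operation_range(design, [dist], p, ref)
        row = {"c_dist_nM": c_dist, "eq_lhs": lhs, "eq_rhs": rhs,
               "within_range": ok}
        for label, (pp, spec) in _aif_pair(sigma, None).items():
            full = spec.merged(CircuitSpec(genes=[dist], name="d"), name="x")
            ss = steady_state(pp, full, horizon=200.0)
            row[f"p_sens_rel_{label}"] = ss["p_sens"] / base[label]["p_sens"]
        rows.append(row)
    df = pd.DataFrame(rows)
    inside = df[df.within_range]
    outside = df[~df.within_range]
    summary = pd.DataFrame([{
        "sigma": sigma,
        "boundary_c_dist_nM": float(outside["c_dist_nM"].min()) if len(outside) else np.nan,
        "max_inrange_error_closed": float((1 - inside["p_sens_rel_closed"]).abs().max()) if len(inside) else np.nan,
        "max_inrange_error_open": float((1 - inside["p_sens_rel_open"]).abs().max()) if len(inside) else np.nan,
    }])
    return {"range": df, "summary": summary}


def run_induction(seed: int = 0, fast: bool = True, sigma: float = 0.5,
                  n_f: int = 7) -> dict[str, pd.DataFrame]:
    """Robustness of an inducible module's induction curve under disturbance."""
    p = default_host_params().replace(sigma=sigma)
    fs = np.geomspace(5.0, 2000.0, n_f)
    rows = []
    for loop, (pp, spec0) in _aif_pair(sigma, None).items():
        for disturbed in (False, True):
            for f in fs:
                spec = spec0.merged(build_inducible_module(inducer=float(f)), name="m")
                if disturbed:
                    spec = spec.merged(build_disturbance_gene(**DIST_KW), name="md")
                ss = steady_state(pp, spec, horizon=200.0)
                rows.append({"loop": loop, "disturbed": disturbed, "f_nM": f,
                             "p_x": ss["p_x"], "lambda_per_h": ss.derived.lam})
    df = pd.DataFrame(rows)
    piv = df.pivot_table(index="f_nM", columns=["loop", "disturbed"], values="p_x")
    shift_closed = np.abs(piv[("closed", True)] / piv[("closed", False)] - 1.0)
    shift_open = np.abs(piv[("open", True)] / piv[("open", False)] - 1.0)
    summary = pd.DataFrame({
        "f_nM": piv.index,
        "rel_shift_closed": shift_closed.values,
        "rel_shift_open": shift_open.values,
    })
    return {"curves": df, "shifts": summary}


# ---------------------------------------------------------------------------
# plotting (convenience only)
# ---------------------------------------------------------------------------

def plot_tables(tag: str, tables: dict[str, pd.DataFrame], out_dir) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    if tag == "growth_laws":
        t = tables["first_law"]
        ax.plot(t["lambda_per_h"], t["phi_r"], "o-", label="nutrient sweep")
        for sig, grp in tables["second_law"].groupby("sigma"):
            ax.plot(grp["lambda_per_h"], grp["phi_r"], "s--",
                    label=f"cm sweep, sigma={sig}")
        ax.set_xlabel("growth rate (1/h)")
        ax.set_ylabel("ribosomal mass fraction")
        ax.legend(fontsize=7)
    elif tag == "optimality":
        t = tables["optimality"]
        ax.plot(t["sigma"], t["ratio"], "o-")
        ax.axhline(1.0, color="k", lw=0.5)
        ax.set_xlabel("nutrient quality sigma")
        ax.set_ylabel("lambda_regulated / lambda_optimal")
    elif tag == "burden_sweep":
        t = tables["sweep"]
        ax.semilogx(t["xi"], t["lambda_sim"], "o", label="simulated")
        ax.semilogx(t["xi"], t["lambda_pred"], "-", label="analytic")
        ax.set_xlabel("translational burden xi")
        ax.set_ylabel("growth rate (1/h)")
        ax.legend()
    elif tag == "wta":
        t = tables["induction_curve"]
        ax.semilogx(t["f1_nM"], t["p_s1"], "o-", label="switch 1")
        ax.semilogx(t["f1_nM"], t["p_s2"], "s-", label="switch 2")
        ax.set_xlabel("inducer 1 (nM), inducer 2 = 20 nM")
        ax.set_ylabel("switch protein (nM)")
        ax.legend()
    elif tag == "t7":
        t = tables["states"]
        ax.bar(t["start"], t["p_t7"])
        ax.set_ylabel("T7 RNAP (nM)")
    elif tag == "aif_step":
        for label in ("closed", "open"):
            t = tables[label]
            ax.plot(t["t_h"], t["p_sens_rel"], label=label)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("p_sens (relative)")
        ax.legend()
    elif tag == "aif_range":
        t = tables["range"]
        ax.semilogx(t["c_dist_nM"], t["p_sens_rel_closed"], "o-", label="closed")
        ax.semilogx(t["c_dist_nM"], t["p_sens_rel_open"], "s-", label="open")
        ax.set_xlabel("disturbing gene DNA (nM)")
        ax.set_ylabel("steady-state p_sens (relative)")
        ax.legend()
    elif tag == "induction":
        t = tables["curves"]
        for (loop, dist), grp in t.groupby(["loop", "disturbed"]):
            ax.semilogx(grp["f_nM"], grp["p_x"],
                        "o-" if loop == "closed" else "s--",
                        label=f"{loop}{'+dist' if dist else ''}")
        ax.set_xlabel("inducer (nM)")
        ax.set_ylabel("output protein (nM)")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(f"{out_dir}/{tag}.png", dpi=120)
    plt.close(fig)
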