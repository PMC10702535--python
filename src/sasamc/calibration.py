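"""Two-stage model parametrization.

Stage 1 fixes the microscopic surface tension γ of the attractive ring
beads against a salt-free osmotic-coefficient curve (canonical MC at
several caffeine concentrations).  Stage 2 fixes the salt-specific TFE
coefficient ε_TFE against excess-chemical-potential differences Δμ^ex
between salt solution and water at fixed caffeine molar activity
(grand-canonical MC); within this model Δμ^ex is linear in ε_TFE·c_s,
which enables a direct slope-matching shortcut.

Reference curves are user-supplied (concentration, value, stderr)
tables; the published best-fit parameters are shipped as named defaults
in :mod:`sasamc.constants`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constants as c
from .cg_model import build_caffeine_template
from .mc_engine import Engine, MoveParams, RunProtocol, SystemState
from .observables import (DensityAccumulator, PressureAccumulator,
                          WidomAccumulator, delta_mu_ex_gc)
from .sasa_potential import PairTable, SaltField

__all__ = [
    "SimOptions",
    "simulate_osmotic_coefficients",
    "simulate_gc_density",
    "calibrate_gamma",
    "calibrate_tfe",
]


@dataclass
class SimOptions:
    """Problem sizes for calibration simulations (kept small enough for
    interactive use; increase for production accuracy)."""

    n_molecules: int = 100
    equilibration: int = 2000
    production: int = 10000
    sample_stride: int = 10
    seed: int = 1
    temperature: float = c.T_DEFAULT
    delta_v: float = 5.0


def _box_for(n, conc_molar):
    rho = c.molar_to_number_density(conc_molar)
    return (n / rho) ** (1.0 / 3.0)


def simulate_osmotic_coefficients(gamma, concentrations, opts: SimOptions,
                                  wca_epsilon=c.WCA_EPSILON_DEFAULT):
    """Canonical MC osmotic coefficients φ(c) for a given surface
    tension (virtual-volume pressure route)."""
    template = build_caffeine_template(surface_tension=gamma,
                                       wca_epsilon=wca_epsilon)
    table = PairTable(template)
    engine = Engine(table)
    out = []
    for i, conc in enumerate(np.atleast_1d(concentrations)):
        L = _box_for(opts.n_molecules, conc)
        rng = np.random.default_rng(opts.seed + 17 * i)
        state = SystemState.random(template, L, opts.n_molecules, rng=rng,
                                   temperature=opts.temperature)
        press = PressureAccumulator(engine, delta_v=opts.delta_v,
                                    stride=opts.sample_stride)
        engine.run(state, MoveParams.canonical_default(),
                   RunProtocol(opts.equilibration, opts.production,
                               seed=opts.seed + 17 * i,
                               sample_stride=opts.sample_stride),
                   observers=[press])
        res = press.result(state)
        out.append(dict(concentration=conc, phi=res["phi"],
                        p_ex=res["p_ex"], p_ex_stderr=res["p_ex_stderr"],
                        p_id=res["p_id"]))
    return pd.DataFrame(out)


def simulate_gc_density(tfe_times_cs, activity, opts: SimOptions,
                        gamma=c.GAMMA_CALIBRATED, box_length=80.0):
    """Grand-canonical mean caffeine density (M) at fixed molar activity
    for a given product ε_TFE·c_s (the only salt quantity entering the
    Hamiltonian; passed as c_s = 1 M with ε_TFE = the product)."""
    template = build_caffeine_template(surface_tension=gamma,
                                       tfe=tfe_times_cs)
    table = PairTable(template)
    engine = Engine(table)
    salt = SaltField(c_s=1.0 if tfe_times_cs != 0.0 else 0.0)
    if tfe_times_cs == 0.0:
        salt = SaltField(c_s=0.0)
    rng = np.random.default_rng(opts.seed)
    n0 = max(int(c.molar_to_number_density(activity) * box_length**3), 1)
    state = SystemState.random(template, box_length, n0, rng=rng,
                               temperature=opts.temperature, salt=salt,
                               ensemble="grand_canonical", activity=activity,
                               capacity=max(20 * n0, 512))
    dens = DensityAccumulator(stride=opts.sample_stride)
    engine.run(state, MoveParams.grand_canonical_default(),
               RunProtocol(opts.equilibration, opts.production,
                           seed=opts.seed, sample_stride=opts.sample_stride),
               observers=[dens])
    return dens.result()


def _golden_minimize(fn, lo, hi, n_grid=5, n_refine=8):
    """Deterministic grid scan followed by golden-section refinement."""
    xs = np.linspace(lo, hi, n_grid)
    ys = [fn(x) for x in xs]
    k = int(np.argmin(ys))
    if k == 0 or k == n_grid - 1:
        raise ValueError(
            f"scan range [{lo}, {hi}] does not bracket the minimum")
    a, b = xs[k - 1], xs[k + 1]
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    x1 = b - invphi * (b - a)
    x2 = a + invphi * (b - a)
    f1, f2 = fn(x1), fn(x2)
    for _ in range(n_refine):
        if f1 <= f2:
            b, x2, f2 = x2, x1, f1
            x1 = b - invphi * (b - a)
            f1 = fn(x1)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + invphi * (b - a)
            f2 = fn(x2)
    return 0.5 * (a + b)


def calibrate_gamma(target: pd.DataFrame, opts: SimOptions,
                    gamma_bounds=(0.02, 0.12), n_grid: int = 5,
                    n_refine: int = 6, wca_epsilon=c.WCA_EPSILON_DEFAULT):
    """Fit γ to a reference osmotic-coefficient curve.

    ``target`` columns: concentration (M), phi, optional stderr.
    Returns (gamma, diagnostics DataFrame of the best simulation).
    Deterministic: every objective evaluation reuses the same seeds.
    """
    conc = target["concentration"].to_numpy()
    phi_ref = target["phi"].to_numpy()
    w = (1.0 / target["stderr"] ** 2
         if "stderr" in target and (target["stderr"] > 0).all()
         else np.ones_like(phi_ref))

    cache = {}

    def objective(gamma):
        sim = simulate_osmotic_coefficients(gamma, conc, opts,
                                            wca_epsilon=wca_epsilon)
        cache[gamma] = sim
        return float(np.sum(w * (sim["phi"].to_numpy() - phi_ref) ** 2))

    gamma_best = _golden_minimize(objective, *gamma_bounds,
                                  n_grid=n_grid, n_refine=n_refine)
    diag = cache.get(gamma_best,
                     simulate_osmotic_coefficients(gamma_best, conc, opts,
                                                   wca_epsilon=wca_epsilon))
    return gamma_best, diag


def calibrate_tfe(target: pd.DataFrame, activity: float, opts: SimOptions,
                  gamma=c.GAMMA_CALIBRATED, box_length=80.0,
                  probe_tfe_cs: float = 0.005, method: str = "slope"):
    """Fit a salt's ε_TFE to a Δμ^ex(c_s) reference curve at fixed
    caffeine molar activity.

    ``target`` columns: c_s (M), delta_mu_ex (kT), optional stderr.
    The default ``slope`` method exploits the model's exact linearity of
    Δμ^ex in ε_TFE·c_s: one reference simulation at ``probe_tfe_cs``
    fixes the response slope and the least-squares ε_TFE follows in
    closed form.  ``method='scan'`` minimizes the weighted SSE by a
    deterministic grid + golden-section search instead.

    Returns (epsilon_tfe, diagnostics dict).
    """
    cs = target["c_s"].to_numpy(dtype=float)
    dmu_ref = target["delta_mu_ex"].to_numpy(dtype=float)
    w = (1.0 / target["stderr"] ** 2
         if "stderr" in target and (target["stderr"] > 0).all()
         else np.ones_like(dmu_ref))

    rho_w = simulate_gc_density(0.0, activity, opts, gamma=gamma,
                                box_length=box_length)

    def dmu_at(tfe_cs_products):
        out = []
        for p in tfe_cs_products:
            if p == 0.0:
                out.append(0.0)
                continue
            rho_s = simulate_gc_density(p, activity, opts, gamma=gamma,
                                        box_length=box_length)
            out.append(delta_mu_ex_gc(rho_w["density_molar"],
                                      rho_s["density_molar"]))
        return np.asarray(out)

    if method == "slope":
        slope = dmu_at([probe_tfe_cs])[0] / probe_tfe_cs
        # least squares for dmu = slope * eps * cs
        x = slope * cs
        eps = float(np.sum(w * x * dmu_ref) / np.sum(w * x * x))
        pred = eps * x
    elif method == "scan":
        scale = max(np.max(np.abs(dmu_ref)) / max(np.max(cs), 1e-9), 1e-4)

        def objective(eps):
            pred = dmu_at(eps * cs)
            return float(np.sum(w * (pred - dmu_ref) ** 2))

        eps = _golden_minimize(objective, -3.0 * scale, 3.0 * scale,
                               n_grid=7, n_refine=5)
        pred = dmu_at(eps * cs)
    else:
        raise ValueError(f"unknown method {method!r}")

    flags = []
    if np.unique(np.sign(dmu_ref[dmu_ref != 0])).size > 1:
        flags.append("target changes sign: inconsistent with a single "
                     "epsilon_TFE; best fit returned")
    return eps, {"predicted": pred, "reference": dmu_ref, "c_s": cs,
                 "rho_water_molar": rho_w["density_molar"], "flags": flags}
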