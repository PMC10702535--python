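"""Ternary solution thermodynamics: activity models and Kirkwood-Buff
inversion.

Components are labelled 1 = water, 2 = solute (caffeine), 3 = salt.
The solute activity coefficient is modelled as

    ln γ₂ = A₂·m₂ + B₂·m₂² + (C₁ + C₂·m₂)·m₃

so the salting-out constant k_s = ∂ln γ₂/∂m₃ = C₁ + C₂·m₂ is linear in
the solute molality.  The binary salt activity is ln γ₃± = A₃·m₃ +
B₃·m₃², and thermodynamic consistency (the Maxwell relation
∂ln γ₂/∂m₃ = ν₃·∂ln γ₃±/∂m₂) fixes the caffeine cross-term in the full
salt activity.  The water activity follows exactly from Gibbs-Duhem,

    ln a₁ = −M₁·[m₂ + ν₃·m₃ + m₂·g₂ + m₃·g₃ − g]

with g the excess Gibbs energy per kg of water (in RT units) whose
molality gradients are (ln γ₂, ν₃·ln γ₃).  The osmolality is
Osm = −ln a₁/M₁, and the residual osmolality of this model is exactly
(C₁ + C₂·m₂)·m₂·m₃.

KB inversion converts the analytic activity derivatives plus
infinite-dilution partial molar volumes and the water compressibility
into the six KB integrals G_ij via the grand-canonical fluctuation
matrix B_ij = ρ_i·δ_ij + ρ_i·ρ_j·G_ij; the forward map is its exact
inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants as c

__all__ = [
    "ActivityModel",
    "SolutionComposition",
    "KBMatrix",
    "ln_gamma2",
    "ln_gamma3",
    "ln_a1",
    "osmolality",
    "ks_model",
    "activity_derivative_matrix",
    "kb_invert",
    "kb_forward",
    "fit_activity_model",
    "ks_from_gamma23",
    "WATER_KAPPA_T",
]

#: Isothermal compressibility of water, 1/Pa (310 K); used as the
#: composition-independent default.
WATER_KAPPA_T = 4.48e-10

#: Infinite-dilution partial molar volumes, cm³/mol (water, caffeine,
#: salt placeholder), 37 °C.
VBAR_DEFAULT = (18.14, 145.9, 16.62)


@dataclass(frozen=True)
class ActivityModel:
    """Coefficients of the ternary activity model (reciprocal molality
    units of the appropriate power)."""

    A2: float = 0.0
    B2: float = 0.0
    C1: float = 0.0
    C2: float = 0.0
    A3: float = 0.0
    B3: float = 0.0
    nu3: int = 2
    M1: float = c.M1_WATER

    def __post_init__(self):
        vals = (self.A2, self.B2, self.C1, self.C2, self.A3, self.B3)
        if not np.all(np.isfinite(vals)):
            raise ValueError("activity coefficients must be finite")
        if self.nu3 < 1:
            raise ValueError("nu3 must be a positive ion count")


@dataclass(frozen=True)
class SolutionComposition:
    m2: float = 0.0      # solute molality, mol/kg
    m3: float = 0.0      # salt molality, mol/kg
    T: float = c.T_VPO   # K

    def __post_init__(self):
        if self.m2 < 0 or self.m3 < 0:
            raise ValueError("molalities must be nonnegative")


@dataclass
class KBMatrix:
    """KB integrals (Å³, symmetric 3×3) with the volumetric constants
    used in the inversion and the excess coordination numbers
    N_ij = G_ij·ρ_j."""

    G: np.ndarray
    rho: np.ndarray            # number densities, 1/Å³ (component basis)
    kappa_T: float             # 1/Pa
    vbar: tuple                # cm³/mol

    @property
    def N(self) -> np.ndarray:
        return self.G * self.rho[None, :]


# -- excess Gibbs energy per kg water (RT units) and its derivatives ----

def _g_derivs(m2, m3, mod: ActivityModel):
    g = (0.5 * mod.A2 * m2**2 + mod.B2 * m2**3 / 3.0
         + mod.C1 * m2 * m3 + 0.5 * mod.C2 * m2**2 * m3
         + mod.nu3 * (0.5 * mod.A3 * m3**2 + mod.B3 * m3**3 / 3.0))
    g2 = mod.A2 * m2 + mod.B2 * m2**2 + (mod.C1 + mod.C2 * m2) * m3
    g3 = (mod.C1 * m2 + 0.5 * mod.C2 * m2**2
          + mod.nu3 * (mod.A3 * m3 + mod.B3 * m3**2))
    g22 = mod.A2 + 2.0 * mod.B2 * m2 + mod.C2 * m3
    g23 = mod.C1 + mod.C2 * m2
    g33 = mod.nu3 * (mod.A3 + 2.0 * mod.B3 * m3)
    return g, g2, g3, g22, g23, g33


def ln_gamma2(comp: SolutionComposition, model: ActivityModel) -> float:
    """Solute activity coefficient; ∂ln γ₂/∂m₃ = C₁ + C₂·m₂ by
    construction."""
    return float(_g_derivs(comp.m2, comp.m3, model)[1])


def ln_gamma3(m3, model: ActivityModel, m2: float = 0.0):
    """Mean ionic activity coefficient of the salt.

    The binary part is A₃·m₃ + B₃·m₃²; at finite solute molality the
    Maxwell-consistent cross-term (C₁·m₂ + C₂·m₂²/2)/ν₃ is added."""
    m3 = np.asarray(m3, dtype=float)
    base = model.A3 * m3 + model.B3 * m3**2
    cross = (model.C1 * m2 + 0.5 * model.C2 * m2**2) / model.nu3
    out = base + cross
    return float(out) if out.ndim == 0 else out


def ks_model(m2, model: ActivityModel):
    """Salting-out constant k_s(m₂) = C₁ + C₂·m₂ (1/molal)."""
    return model.C1 + model.C2 * np.asarray(m2, dtype=float)


def ln_a1(comp: SolutionComposition, model: ActivityModel) -> float:
    """Water activity, exactly Gibbs-Duhem-consistent with the solute
    and salt activity models.  Ideal limit: −M₁·(m₂ + ν₃·m₃)."""
    g, g2, g3, *_ = _g_derivs(comp.m2, comp.m3, model)
    F = (comp.m2 + model.nu3 * comp.m3
         + comp.m2 * g2 + comp.m3 * g3 - g)
    return -model.M1 * F


def osmolality(comp: SolutionComposition, model: ActivityModel) -> float:
    """Osm = −ln a₁ / M₁, mol/kg."""
    return -ln_a1(comp, model) / model.M1


# -- activity derivatives and KB inversion ------------------------------

def _molality_derivative_matrix(comp, model):
    """D_jk = ∂(βμ_j)/∂m_k at constant T, P for j ∈ {1,2,3},
    k ∈ {2,3}; rows satisfy Gibbs-Duhem exactly."""
    m2, m3 = comp.m2, comp.m3
    _, g2, g3, g22, g23, g33 = _g_derivs(m2, m3, model)
    D = np.zeros((3, 2))
    D[1, 0] = 1.0 / m2 + g22
    D[1, 1] = g23
    D[2, 0] = g23
    D[2, 1] = model.nu3 / m3 + g33
    D[0, 0] = -model.M1 * (1.0 + m2 * g22 + m3 * g23)
    D[0, 1] = -model.M1 * (model.nu3 + m2 * g23 + m3 * g33)
    return D


def activity_derivative_matrix(comp: SolutionComposition,
                               model: ActivityModel) -> np.ndarray:
    """Dimensionless activity-derivative matrix a_jk = ∂ln a_j/∂ln m_k
    (j ∈ {1,2,3}, k ∈ {2,3}) at constant T, P.

    The cross-Maxwell relation makes a_23/m3 = a_32/m2 symmetric in the
    underlying μ-derivatives; compositions with a vanishing molality are
    evaluated in the dilute limit (tiny floor)."""
    comp = _floored(comp)
    D = _molality_derivative_matrix(comp, model)
    m = np.array([comp.m2, comp.m3])
    # βμ_j per ln m_k; for the salt, μ3 = ν3 ln(m3 γ3) so divide by ν3
    scale = np.array([1.0, 1.0, 1.0 / model.nu3])
    return D * m[None, :] * scale[:, None]


_MOLALITY_FLOOR = 1e-8


def _floored(comp: SolutionComposition) -> SolutionComposition:
    m2 = comp.m2 if comp.m2 > 0 else _MOLALITY_FLOOR
    m3 = comp.m3 if comp.m3 > 0 else _MOLALITY_FLOOR
    if m2 is comp.m2 and m3 is comp.m3:
        return comp
    return SolutionComposition(m2=m2, m3=m3, T=comp.T)


def _volumes_and_densities(comp, model, vbar):
    """Per-kg-water particle numbers, batch volume (Å³) and number
    densities (1/Å³) in the component basis (salt = formula units)."""
    n = np.array([1.0 / model.M1, comp.m2, comp.m3])   # mol per kg water
    v_cm3 = float(np.dot(n, vbar))
    v_A3 = v_cm3 * 1e24
    N = n * c.AVOGADRO
    rho = N / v_A3
    return n, v_A3, rho


def kb_invert(comp: SolutionComposition, model: ActivityModel,
              vbar=VBAR_DEFAULT, kappa_T: float = WATER_KAPPA_T,
              cond_limit: float = 1e14) -> KBMatrix:
    """Invert the activity model into the six KB integrals G_ij (Å³).

    Builds the constant-T,V chemical-potential derivative matrix
    A_ij = βV·∂μ_i/∂N_j|_{T,V} = βV·∂μ_i/∂N_j|_{T,P} + V̄_iV̄_j/(kTκ_T),
    inverts it to the fluctuation matrix B = A⁻¹ and reads
    G_ij = (B_ij − ρ_i·δ_ij)/(ρ_i·ρ_j).  The forward map
    (:func:`kb_forward`) reproduces the input derivatives exactly.
    """
    comp = _floored(comp)
    n, v_A3, rho = _volumes_and_densities(comp, model, vbar)
    D = _molality_derivative_matrix(comp, model)
    # per-particle constant-T,P derivative matrix W_ij = βV ∂μ_i/∂N_j
    W = np.zeros((3, 3))
    W[:, 1] = v_A3 * D[:, 0] / c.AVOGADRO
    W[:, 2] = v_A3 * D[:, 1] / c.AVOGADRO
    W[:, 0] = -(v_A3 * model.M1 / c.AVOGADRO) * (
        D[:, 0] * comp.m2 + D[:, 1] * comp.m3)
    vbar_A3 = np.asarray(vbar) * 1e24 / c.AVOGADRO          # Å³/particle
    kTkappa = 1.380649e-23 * comp.T * kappa_T * 1e30        # Å³
    A = W + np.outer(vbar_A3, vbar_A3) / kTkappa
    condition = np.linalg.cond(A)
    if condition > cond_limit:
        raise np.linalg.LinAlgError(
            f"KB inversion ill-conditioned (cond = {condition:.2e})")
    B = np.linalg.inv(A)
    G = (B - np.diag(rho)) / np.outer(rho, rho)
    G = 0.5 * (G + G.T)   # symmetrize roundoff
    return KBMatrix(G=G, rho=rho, kappa_T=kappa_T, vbar=tuple(vbar))


def kb_forward(kb: KBMatrix, comp: SolutionComposition,
               model_nu3: int = 2, M1: float = c.M1_WATER):
    """Forward KB relations: from G_ij and densities back to the
    constant-T,P molality derivatives D_jk, plus the implied kTκ_T (Å³)
    and partial molar volumes (Å³/particle)."""
    comp = _floored(comp)
    rho = kb.rho
    B = np.diag(rho) + np.outer(rho, rho) * kb.G
    A = np.linalg.inv(B)
    kTkappa = 1.0 / float(rho @ A @ rho)
    vbar_A3 = kTkappa * (A @ rho)
    W = A - np.outer(vbar_A3, vbar_A3) / kTkappa
    # volume of the 1-kg-water batch: N1 = N_A/M1 particles at density rho1
    v_A3 = c.AVOGADRO / (rho[0] * M1)
    D = np.zeros((3, 2))
    D[:, 0] = W[:, 1] * c.AVOGADRO / v_A3
    D[:, 1] = W[:, 2] * c.AVOGADRO / v_A3
    return D, kTkappa, vbar_A3


def gibbs_duhem_residual(model: ActivityModel, path, n_points: int = 50,
                         h: float = 1e-6):
    """Largest pointwise Gibbs-Duhem violation along a composition path.

    At points along the piecewise-linear path [(m2, m3), ...] the
    weighted sum n₁·dβμ₁ + m₂·dβμ₂ + m₃·dβμ₃ (per kg water, per unit
    path parameter) is evaluated with central-difference chemical
    potentials; it vanishes for a thermodynamically consistent model.
    """
    path = np.asarray(path, dtype=float)

    def mu_vector(m2, m3):
        comp = SolutionComposition(m2, m3)
        return np.array([
            ln_a1(comp, model),
            np.log(max(m2, _MOLALITY_FLOOR)) + ln_gamma2(comp, model),
            model.nu3 * np.log(max(m3, _MOLALITY_FLOOR))
            + model.nu3 * ln_gamma3(m3, model, m2=m2),
        ])

    worst = 0.0
    for (m2a, m3a), (m2b, m3b) in zip(path[:-1], path[1:]):
        for t in np.linspace(h, 1.0 - h, n_points):
            m2 = m2a + (m2b - m2a) * t
            m3 = m3a + (m3b - m3a) * t
            dmu = (mu_vector(m2a + (m2b - m2a) * (t + h),
                             m3a + (m3b - m3a) * (t + h))
                   - mu_vector(m2a + (m2b - m2a) * (t - h),
                               m3a + (m3b - m3a) * (t - h))) / (2.0 * h)
            weights = np.array([1.0 / model.M1, m2, m3])
            worst = max(worst, abs(float(weights @ dmu)))
    return worst


# -- fitting ------------------------------------------------------------

@dataclass
class FittedActivityModel:
    model: ActivityModel
    stderr: dict
    covariance_binary: np.ndarray
    covariance_salt: np.ndarray
    residuals: pd.DataFrame


def _wls(X, y, w, known_variance=False):
    """Weighted least squares; returns (params, covariance).

    With ``known_variance`` the weights are true inverse variances and
    the parameter covariance is (XᵀWX)⁻¹; otherwise the residual
    variance rescales it."""
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    cov = np.linalg.inv(Xw.T @ Xw)
    if not known_variance:
        dof = max(len(y) - X.shape[1], 1)
        resid = yw - Xw @ beta
        cov = cov * (float(resid @ resid) / dof)
    return beta, cov


def fit_activity_model(grid: pd.DataFrame, nu3: int = 2,
                       A3: float = 0.0, B3: float = 0.0) -> FittedActivityModel:
    """Two-stage global fit of a μ₂^ex grid to the activity model.

    ``grid`` columns: m2, m3, ln_gamma2 (= βμ₂^ex), optional stderr.
    Stage 1 fits (A₂, B₂) on the salt-free slice; stage 2 freezes them
    and fits (C₁, C₂) on the full grid.  Weights are inverse-variance
    when ``stderr`` is present.
    """
    req = {"m2", "m3", "ln_gamma2"}
    if not req.issubset(grid.columns):
        raise ValueError(f"grid must have columns {sorted(req)}")
    g = grid.copy()
    known = "stderr" in g and np.isfinite(g["stderr"]).all() \
        and (g["stderr"] > 0).all()
    w = 1.0 / g["stderr"] ** 2 if "stderr" in g else pd.Series(1.0, index=g.index)
    w = w.fillna(w[np.isfinite(w)].median() if np.isfinite(w).any() else 1.0)

    binary = g[g["m3"] == 0.0]
    if len(binary) < 2:
        raise ValueError("need >= 2 salt-free points to fit A2, B2")
    Xb = np.column_stack([binary["m2"], binary["m2"] ** 2])
    (A2, B2), cov_b = _wls(Xb, binary["ln_gamma2"].to_numpy(),
                           w[binary.index].to_numpy(), known_variance=known)

    ternary = g[g["m3"] > 0.0]
    if len(ternary) < 2:
        raise ValueError("need >= 2 ternary points to fit C1, C2")
    resid = (ternary["ln_gamma2"]
             - A2 * ternary["m2"] - B2 * ternary["m2"] ** 2).to_numpy()
    Xs = np.column_stack([ternary["m3"], ternary["m2"] * ternary["m3"]])
    ws = w[ternary.index].to_numpy()
    (C1, C2), cov_s = _wls(Xs, resid, ws, known_variance=known)
    # propagate the frozen (A2, B2) uncertainty into (C1, C2): the
    # stage-2 response to a stage-1 error δ(A2,B2) is linear
    T = np.column_stack([ternary["m2"], ternary["m2"] ** 2])
    M = np.linalg.inv((Xs * ws[:, None]).T @ Xs)
    J = -M @ (Xs * ws[:, None]).T @ T
    cov_s = cov_s + J @ cov_b @ J.T

    model = ActivityModel(A2=A2, B2=B2, C1=C1, C2=C2, A3=A3, B3=B3, nu3=nu3)
    pred = np.array([ln_gamma2(SolutionComposition(r.m2, r.m3), model)
                     for r in g.itertuples()])
    residuals = g.assign(predicted=pred, residual=g["ln_gamma2"] - pred)
    stderr = {"A2": float(np.sqrt(cov_b[0, 0])),
              "B2": float(np.sqrt(cov_b[1, 1])),
              "C1": float(np.sqrt(cov_s[0, 0])),
              "C2": float(np.sqrt(cov_s[1, 1]))}
    return FittedActivityModel(model=model, stderr=stderr,
                               covariance_binary=cov_b,
                               covariance_salt=cov_s, residuals=residuals)


def ks_from_gamma23(gamma23: float, m3: float, model: ActivityModel) -> float:
    """Salting-out constant from the preferential binding coefficient,
    k_s = −(Γ₂₃/m₃)·(1 + ∂ln γ₃±/∂ln m₃).

    Γ₂₃ counts cosolute *ions* (the ν₃-fold formula-unit coefficient);
    the bracket corrects for salt nonideality.  A depleted cosolute
    (Γ₂₃ < 0) gives k_s > 0 (salting-out).  At m₃ = 0 the expression is
    the analytic limit of Γ₂₃ ∝ −k_s·m₃, so Γ₂₃ must vanish there.
    """
    if m3 == 0:
        if gamma23 == 0:
            return 0.0
        raise ValueError("finite Γ23 at zero salt concentration")
    nonideal = 1.0 + m3 * (model.A3 + 2.0 * model.B3 * m3)
    return -(gamma23 / m3) * nonideal
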