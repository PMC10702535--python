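"""Estimators accumulated during sampling.

RDFs and Kirkwood-Buff integrals, preferential-binding coefficients from
either KB integrals or running coordination numbers, virtual-volume
pressure and osmotic coefficient, Widom and grand-canonical excess
chemical potentials.  Correlated-sample uncertainties are estimated by
block averaging with automatic block-length doubling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from . import constants as c

__all__ = [
    "block_stderr",
    "RdfAccumulator",
    "kb_integral",
    "gamma23_from_kb",
    "gamma23_from_counts",
    "PressureAccumulator",
    "osmotic_coefficient",
    "WidomAccumulator",
    "DensityAccumulator",
    "delta_mu_ex_gc",
]


def block_stderr(samples) -> float:
    """Standard error of the mean of a correlated series.

    Block averages with doubling block length; returns the largest
    plateau estimate (conservative for short series)."""
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 2:
        return np.nan
    best = x.std(ddof=1) / np.sqrt(n)
    length = 1
    while n // (2 * length) >= 4:
        length *= 2
        nb = n // length
        blocks = x[:nb * length].reshape(nb, length).mean(axis=1)
        best = max(best, blocks.std(ddof=1) / np.sqrt(nb))
    return best


class RdfAccumulator:
    """Center-of-mass radial distribution function.

    Normalization uses the exact per-frame molecule count and volume, so
    the estimator is valid in the grand-canonical ensemble as well.
    """

    def __init__(self, bin_width: float = 0.25, r_max: float | None = None,
                 stride: int = 10):
        self.bin_width = float(bin_width)
        self.r_max = r_max
        self.stride = int(stride)
        self._hist = None
        self._norm = None
        self.frames = 0

    def sample(self, state):
        from . import _kernels as k

        L = state.box_length
        if self.r_max is None:
            self.r_max = 0.5 * L
        if self._hist is None:
            nbins = int(self.r_max / self.bin_width)
            self._hist = np.zeros(nbins)
            self._norm = np.zeros(nbins)
        n = state.n
        if n < 2:
            return
        frame = np.zeros_like(self._hist)
        k.rdf_accumulate(state.com, n, L, self.bin_width, frame)
        edges = self.bin_width * np.arange(len(frame) + 1)
        shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        # ideal pair count in each shell: N(N-1)/2 * shell/V
        ideal = 0.5 * n * (n - 1) * shell / L**3
        self._hist += frame
        self._norm += ideal
        self.frames += 1

    def result(self) -> pd.DataFrame:
        if self._hist is None or self.frames == 0:
            raise ValueError("no frames sampled")
        r = self.bin_width * (np.arange(len(self._hist)) + 0.5)
        with np.errstate(invalid="ignore", divide="ignore"):
            g = self._hist / self._norm
        return pd.DataFrame({"r": r, "g": g})


def kb_integral(r, g, plateau_window=(16.0, 20.0)):
    """Running Kirkwood-Buff integral G(R) = ∫₀^R [g(r)-1]·4πr² dr (Å³)
    and its plateau value (mean over the plateau window, Å).

    Returns (DataFrame with columns r, G, plateau_value)."""
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    if r[-1] < plateau_window[1]:
        raise ValueError(
            f"RDF range {r[-1]:.1f} Å shorter than the plateau window "
            f"{plateau_window}; use a larger box")
    integrand = (g - 1.0) * 4.0 * np.pi * r**2
    G = cumulative_trapezoid(integrand, r, initial=0.0)
    mask = (r >= plateau_window[0]) & (r <= plateau_window[1])
    plateau = float(G[mask].mean())
    return pd.DataFrame({"r": r, "G": G}), plateau


def gamma23_from_kb(G23: float, G21: float, rho3: float) -> float:
    """Preferential binding coefficient Γ₂₃ = ρ₃·(G₂₃ − G₂₁) from KB
    integrals (ρ₃ = cosolute ion number density, 1/Å³)."""
    if rho3 < 0:
        raise ValueError("density must be nonnegative")
    return rho3 * (G23 - G21)


def gamma23_from_counts(N23, N21, N3_total: float, N1_total: float,
                        r=None, plateau_window=None):
    """Γ₂₃(r) = N₂₃(r) − (N₃⁰/N₁⁰)·N₂₁(r) from running coordination
    numbers of cosolute ions and water around the solute.

    If ``r`` and ``plateau_window`` are given, also returns the plateau
    mean over that window."""
    N23 = np.asarray(N23, dtype=float)
    N21 = np.asarray(N21, dtype=float)
    if N1_total <= 0 or N3_total <= 0:
        raise ValueError("totals must be positive")
    if np.any(np.diff(N23) < -1e-9) or np.any(np.diff(N21) < -1e-9):
        raise ValueError("running coordination numbers must be nondecreasing")
    gamma = N23 - (N3_total / N1_total) * N21
    if r is None or plateau_window is None:
        return gamma
    r = np.asarray(r, dtype=float)
    mask = (r >= plateau_window[0]) & (r <= plateau_window[1])
    return gamma, float(gamma[mask].mean())


class PressureAccumulator:
    """Excess pressure from virtual volume perturbations.

    Each sample evaluates the energy change of scaling the box and the
    molecular centers of mass isotropically (rigid molecules) by
    (1 + ΔV/V)^(1/3) and accumulates (1+ΔV/V)^N·exp(−βΔU).  The
    pressure is p = (kT/ΔV)·ln⟨...⟩ and the excess part subtracts the
    ideal contribution ⟨N⟩kT/V.
    """

    def __init__(self, engine, delta_v: float = 5.0, stride: int = 10):
        self.engine = engine
        self.delta_v = float(delta_v)
        self.stride = int(stride)
        self._terms = []
        self._ns = []

    def sample(self, state):
        V = state.volume
        if self.delta_v >= V:
            raise ValueError("volume perturbation exceeds the box volume")
        scale = (1.0 + self.delta_v / V) ** (1.0 / 3.0)
        u0 = self.engine.perturbed_energy(state, 1.0)
        u1 = self.engine.perturbed_energy(state, scale)
        beta = 1.0 / c.kT(state.temperature)
        term = (1.0 + self.delta_v / V) ** state.n * np.exp(-beta * (u1 - u0))
        self._terms.append(term)
        self._ns.append(state.n)

    def result(self, state) -> dict:
        """Pressure decomposition in kJ/(mol Å³); also φ."""
        terms = np.asarray(self._terms)
        if terms.size == 0:
            raise ValueError("no pressure samples")
        kT = c.kT(state.temperature)
        V = state.volume
        p_total = kT / self.delta_v * np.log(terms.mean())
        p_id = np.mean(self._ns) * kT / V
        p_ex = p_total - p_id
        # error via block averaging on log-linearized samples
        se_terms = block_stderr(terms)
        p_err = kT / self.delta_v * se_terms / terms.mean()
        return {"p_total": p_total, "p_id": p_id, "p_ex": p_ex,
                "p_ex_stderr": p_err,
                "phi": osmotic_coefficient(p_ex, p_id)}


def osmotic_coefficient(p_ex: float, p_id: float) -> float:
    """φ = (p_id + p_ex)/p_id."""
    if p_id <= 0:
        raise ValueError("ideal pressure must be positive")
    return (p_id + p_ex) / p_id


class WidomAccumulator:
    """Excess chemical potential by Widom test-particle insertion,
    μ^ex = −ln⟨exp(−βΔU_insert)⟩ in kT (one-body transfer term
    included in ΔU_insert)."""

    def __init__(self, engine, n_insert: int = 25, stride: int = 10):
        self.engine = engine
        self.n_insert = int(n_insert)
        self.stride = int(stride)
        self._means = []

    def sample(self, state):
        s = self.engine.widom_sum(state, self.n_insert)
        self._means.append(s / self.n_insert)

    def result(self) -> dict:
        m = np.asarray(self._means)
        if m.size == 0:
            raise ValueError("no Widom samples")
        mean = m.mean()
        if mean <= 0:
            import warnings

            warnings.warn("all insertions overlapped; μ^ex is a lower bound")
            return {"mu_ex": np.inf, "mu_ex_stderr": np.nan}
        se = block_stderr(m)
        return {"mu_ex": -np.log(mean), "mu_ex_stderr": se / mean}


class DensityAccumulator:
    """Mean molecule number / molar density (grand canonical)."""

    def __init__(self, stride: int = 10):
        self.stride = int(stride)
        self._ns = []
        self._volume = None

    def sample(self, state):
        self._ns.append(state.n)
        self._volume = state.volume

    def result(self) -> dict:
        ns = np.asarray(self._ns, dtype=float)
        if ns.size == 0:
            raise ValueError("no density samples")
        rho = ns.mean() / self._volume
        se = block_stderr(ns) / self._volume
        return {"n_mean": ns.mean(),
                "density_molar": c.number_density_to_molar(rho),
                "density_molar_stderr": c.number_density_to_molar(se)}


def delta_mu_ex_gc(rho_water: float, rho_salt: float) -> float:
    """Δμ^ex = ln(ρ^wat / ρ^salt) in kT, from grand-canonical densities
    at equal solute activity in water and in the salt solution."""
    if rho_water <= 0 or rho_salt <= 0:
        raise ValueError("densities must be positive")
    return float(np.log(rho_water / rho_salt))
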