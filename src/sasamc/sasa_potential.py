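"""SASA-based implicit-solvent pair potential.

The potential energy of a configuration of rigid CG molecules is

    U = Σ_pairs u_WCA(r_ab) + Σ_pairs (γ_ab + ε_ab,TFE·c_s)·ΔA_ab(d)
        + N · c_s · Σ_i ε_i,TFE · A_i^ref

where the sums run over intermolecular bead pairs, ΔA_ab(d) is the
two-sphere exposed area relative to non-overlapping separation (zero at
and beyond contact, negative for overlap), and the last term is the
one-body cost of transferring each molecule's reference surface from
water into the cosolute solution.  Mixed-pair coefficients are
arithmetic means; WCA σ mixes by the Lorentz rule and ϵ by the
Berthelot (geometric) rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cg_model import MoleculeTemplate
from .geometry import two_sphere_area

__all__ = [
    "SaltField",
    "PairTable",
    "wca_energy",
    "sasa_pair_energy",
    "monomer_transfer_energy",
    "system_energy",
]


@dataclass(frozen=True)
class SaltField:
    """Implicit cosolute: only the product ε_TFE·c_s enters pair
    energies, so a single salt descriptor suffices."""

    c_s: float = 0.0       # molar concentration of added cosolute, M
    label: str = "none"

    def __post_init__(self):
        if self.c_s < 0:
            raise ValueError("cosolute concentration must be >= 0")


class PairTable:
    """Precomputed symmetric bead-pair coefficient tables for one
    molecule template (γ_ab, ε_ab,TFE, σ_ab, ϵ_ab, contact distances and
    non-overlap reference areas)."""

    def __init__(self, template: MoleculeTemplate):
        self.template = template
        R = template.sasa_radii
        sig = template.wca_sigmas
        eps = template.wca_epsilons
        gam = template.surface_tensions
        tfe = template.tfes

        self.contact = R[:, None] + R[None, :]
        self.area0 = 4.0 * np.pi * (R[:, None] ** 2 + R[None, :] ** 2)
        self.sigma = 0.5 * (sig[:, None] + sig[None, :])
        self.epsilon = np.sqrt(eps[:, None] * eps[None, :])
        self.gamma = 0.5 * (gam[:, None] + gam[None, :])
        self.tfe = 0.5 * (tfe[:, None] + tfe[None, :])
        self.sasa_radii = R.copy()
        #: largest bead-pair interaction range, Å
        self.cutoff = float(self.contact.max())
        off = np.linalg.norm(template.body_coords, axis=1)
        #: molecule-level COM cutoff, Å
        self.mol_cutoff = self.cutoff + 2.0 * float(off.max())
        self.u_one_coeff = float(np.sum(tfe * template.reference_areas))

    def coefficients(self, salt: SaltField) -> np.ndarray:
        """Effective area coefficients γ_ab + ε_ab,TFE·c_s."""
        return self.gamma + self.tfe * salt.c_s

    def to_frame(self):
        """Tabular dump of the pair coefficients (tidy, one pair/row)."""
        import pandas as pd

        names = self.template.names
        rows = []
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if j < i:
                    continue
                rows.append(dict(i=a, j=b, sigma=self.sigma[i, j],
                                 epsilon=self.epsilon[i, j],
                                 gamma=self.gamma[i, j], tfe=self.tfe[i, j],
                                 contact=self.contact[i, j]))
        return pd.DataFrame(rows)


def wca_energy(sigma, epsilon, rij):
    """Weeks-Chandler-Andersen potential: Lennard-Jones truncated at its
    minimum 2^(1/6)σ and shifted by ϵ so it is purely repulsive and
    continuous at the cutoff.  rij = 0 returns +inf (rejection
    sentinel)."""
    sigma = np.asarray(sigma, dtype=float)
    rij = np.asarray(rij, dtype=float)
    if np.any(sigma <= 0) or np.any(np.asarray(epsilon) <= 0):
        raise ValueError("WCA sigma and epsilon must be positive")
    with np.errstate(divide="ignore", over="ignore"):
        sr6 = (sigma / rij) ** 6
        u = np.where(rij < 2.0 ** (1.0 / 6.0) * sigma,
                     4.0 * np.asarray(epsilon) * (sr6 * sr6 - sr6) + epsilon,
                     0.0)
        u = np.where(rij == 0.0, np.inf, u)
    if u.ndim == 0:
        return float(u)
    return u


def sasa_pair_energy(Ri, Rj, coeff, d):
    """SASA pair term (γ_ij + ε_ij,TFE·c_s)·[A(d) − A(contact)], kJ/mol.

    Exactly zero at and beyond contact; negative for overlapping beads
    when the coefficient is positive (burying area is favourable)."""
    area0 = 4.0 * np.pi * (np.asarray(Ri, dtype=float) ** 2
                           + np.asarray(Rj, dtype=float) ** 2)
    return coeff * (two_sphere_area(Ri, Rj, d) - area0)


def monomer_transfer_energy(template: MoleculeTemplate,
                            salt: SaltField) -> float:
    """One-body transfer energy u₁ = c_s · Σ_i ε_i,TFE · A_i^ref, kJ/mol.

    Pose-independent; added once per molecule.  It shifts canonical
    totals by a constant and matters for insertion/deletion statistics
    in the grand-canonical ensemble and for Widom insertions.
    """
    return float(salt.c_s * np.sum(template.tfes * template.reference_areas))


def system_energy(state, table: PairTable, salt: SaltField) -> float:
    """Total potential energy (kJ/mol) of a system state: WCA + SASA
    pair terms over all intermolecular bead pairs under the molecular
    minimum-image convention, plus N times the one-body transfer term.
    Intramolecular pairs are excluded (the molecule is rigid)."""
    from . import _kernels as k

    coeff = table.coefficients(salt)
    u_pair = k.total_energy(
        state.com[:state.n], state.offsets[:state.n], state.box_length,
        table.sigma ** 2, table.epsilon, coeff, table.contact,
        table.area0, table.mol_cutoff ** 2)
    return u_pair + state.n * salt.c_s * table.u_one_coeff
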