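"""Rigid coarse-grained molecule model.

A molecule is represented by a small number of spherical beads, one per
chemical group.  For caffeine the default scheme has eight beads: the two
fused heterocyclic rings (the only attractive sites in the two-site
model), the three N-methyl carbons, the two carbonyl oxygens and the
-N=CH- imine moiety.  Every bead carries a SASA radius (group radius plus
probe radius), WCA parameters, a microscopic surface tension γ_i and a
transfer-free-energy coefficient ε_i,TFE.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import constants as c

__all__ = [
    "BeadSpec",
    "MoleculeTemplate",
    "build_caffeine_template",
    "caffeine_heavy_atoms",
    "DEFAULT_CAFFEINE_GROUPS",
    "rotation_from_axis_angle",
    "random_rotation",
    "reference_areas",
    "molecule_bead_coordinates",
]

# Reference heavy-atom geometry of caffeine (MMFF94-optimized, centered),
# shipped as a frozen fixture so template construction is reproducible.
# Columns: atom name, element, x, y, z (Å).  Naming follows the xanthine
# ring convention (N1/C2/O2/N3/C4/C5/C6/O6/N7/C8/N9, CM* = N-methyl C).
_CAFFEINE_ATOMS = """
CM7 C  3.2369 -1.0491  0.0728
N7  N  2.2205 -0.0279  0.0748
C8  C  2.4324  1.3244  0.1305
N9  N  1.2975  1.9953  0.1158
C4  C  0.3358  1.0330  0.0485
C5  C  0.8697 -0.2195  0.0218
C6  C  0.0824 -1.4006 -0.0474
O6  O  0.5738 -2.5251 -0.0710
N1  N -1.2895 -1.1348 -0.0847
CM1 C -2.2017 -2.2594 -0.1562
C2  C -1.8804  0.1461 -0.0589
O2  O -3.1074  0.2792 -0.0960
N3  N -1.0212  1.2433  0.0097
CM3 C -1.5488  2.5951  0.0402
"""

# Bondi van der Waals radii, Å.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52}

# Default eight-group coarse-graining scheme.  Each heavy atom belongs to
# exactly one group; the fused carbons C4/C5 are assigned to the
# five-membered ring bead.
DEFAULT_CAFFEINE_GROUPS = {
    "RC6": ("N1", "C2", "N3", "C6"),  # six-membered ring core
    "RC5": ("C4", "C5", "N7"),        # five-membered ring core
    "IMI": ("C8", "N9"),              # -N=CH- imine moiety
    "ME1": ("CM1",),
    "ME3": ("CM3",),
    "ME7": ("CM7",),
    "OC6": ("O6",),
    "OC2": ("O2",),
}

#: Beads carrying surface tension / TFE in the default two-site model.
TWO_SITE = ("RC6", "RC5")
#: Five-site variant: methyls added at a relative strength.
FIVE_SITE = ("RC6", "RC5", "ME1", "ME3", "ME7")

#: Group-radius convention: root-mean-square spread of the heavy atoms
#: about the group centroid combined with their mean van der Waals
#: radius.  Chosen so the pairwise-approximated monomer SASA of caffeine
#: is close to an atomistic Shrake-Rupley SASA of the same geometry.
GROUP_RADIUS_CONVENTION = "rms"


def caffeine_heavy_atoms():
    """Return (names, elements, coords (14,3)) of the reference geometry."""
    names, elements, xyz = [], [], []
    for line in _CAFFEINE_ATOMS.strip().splitlines():
        parts = line.split()
        names.append(parts[0])
        elements.append(parts[1])
        xyz.append([float(v) for v in parts[2:5]])
    return names, elements, np.array(xyz)


@dataclass(frozen=True)
class BeadSpec:
    """One coarse-grained bead in the molecule body frame."""

    name: str
    position: np.ndarray        # (3,) Å, body frame
    sasa_radius: float          # Å, group radius + probe radius
    wca_sigma: float            # Å
    wca_epsilon: float          # kJ/mol
    surface_tension: float = 0.0  # γ_i, kJ/(mol Å²)
    tfe: float = 0.0              # ε_i,TFE, kJ/(mol Å² M)

    def __post_init__(self):
        if self.sasa_radius <= 0 or self.wca_sigma <= 0:
            raise ValueError(f"bead {self.name}: radii must be positive")
        vals = [self.sasa_radius, self.wca_sigma, self.wca_epsilon,
                self.surface_tension, self.tfe]
        if not np.all(np.isfinite(np.asarray(vals, dtype=float))):
            raise ValueError(f"bead {self.name}: non-finite coefficient")


@dataclass(frozen=True)
class MoleculeTemplate:
    """Rigid bead geometry plus per-bead energetic coefficients.

    ``reference_areas`` are the per-bead exposed areas of the isolated
    molecule (union-surface exposure against all other beads of the
    molecule); their sum is the monomer SASA entering the one-body
    transfer term.
    """

    beads: tuple[BeadSpec, ...]
    reference_areas: np.ndarray = field(default=None)  # type: ignore[assignment]
    monomer_sasa: float = field(default=None)          # type: ignore[assignment]

    def __post_init__(self):
        if len(self.beads) < 1:
            raise ValueError("template needs at least one bead")
        if self.reference_areas is None:
            areas = reference_areas(self)
            object.__setattr__(self, "reference_areas", areas)
            object.__setattr__(self, "monomer_sasa", float(areas.sum()))

    # -- array views used by the sampling kernels ------------------------
    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def body_coords(self) -> np.ndarray:
        return np.array([b.position for b in self.beads], dtype=float)

    @property
    def sasa_radii(self) -> np.ndarray:
        return np.array([b.sasa_radius for b in self.beads])

    @property
    def wca_sigmas(self) -> np.ndarray:
        return np.array([b.wca_sigma for b in self.beads])

    @property
    def wca_epsilons(self) -> np.ndarray:
        return np.array([b.wca_epsilon for b in self.beads])

    @property
    def surface_tensions(self) -> np.ndarray:
        return np.array([b.surface_tension for b in self.beads])

    @property
    def tfes(self) -> np.ndarray:
        return np.array([b.tfe for b in self.beads])

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.beads)

    @property
    def radius(self) -> float:
        """Distance from the body origin to the farthest bead surface, Å."""
        pos = self.body_coords
        return float(np.max(np.linalg.norm(pos, axis=1) + self.sasa_radii))

    def internal_distances(self) -> np.ndarray:
        pos = self.body_coords
        return np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)

    def with_coefficients(self, surface_tension=None, tfe=None,
                          sites=None) -> "MoleculeTemplate":
        """Return a copy with γ and/or ε_TFE reassigned on ``sites``
        (bead names; default: beads that currently carry γ ≠ 0)."""
        if sites is None:
            sites = [b.name for b in self.beads if b.surface_tension != 0.0]
        beads = []
        for b in self.beads:
            kw = {}
            if surface_tension is not None:
                kw["surface_tension"] = surface_tension if b.name in sites else 0.0
            if tfe is not None:
                kw["tfe"] = tfe if b.name in sites else 0.0
            beads.append(replace(b, **kw) if kw else b)
        return MoleculeTemplate(beads=tuple(beads))


def rotation_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    """Proper rotation matrix about ``axis`` by ``angle`` (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be nonzero")
    x, y, z = axis / n
    ca, sa = np.cos(angle), np.sin(angle)
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + sa * K + (1.0 - ca) * (K @ K)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (uniform axis, uniform angle in
    [0, π] weighted by the Haar measure via quaternion sampling)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def molecule_bead_coordinates(template: MoleculeTemplate,
                              position: np.ndarray,
                              orientation: np.ndarray) -> np.ndarray:
    """Bead coordinates of the rigid molecule at a pose.

    ``orientation`` must be a proper rotation matrix (orthogonal,
    det = +1); internal distances are preserved exactly.
    """
    Rm = np.asarray(orientation, dtype=float)
    if Rm.shape != (3, 3) or not np.allclose(Rm @ Rm.T, np.eye(3), atol=1e-8) \
            or np.linalg.det(Rm) < 0:
        raise ValueError("orientation must be a proper rotation matrix")
    return template.body_coords @ Rm.T + np.asarray(position, dtype=float)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + 5.0**0.5) * i
    z = 1.0 - 2.0 * i / n
    s = np.sqrt(1.0 - z * z)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def reference_areas(template: MoleculeTemplate, n_points: int = 8192) -> np.ndarray:
    """Per-bead exposed areas A_i^ref (Å²) of the isolated molecule.

    The eight caffeine beads overlap each other heavily, so a pairwise
    lens subtraction over-counts the buried area and clamps every bead to
    zero.  The reference areas are therefore the exact union-surface
    exposures: the fraction of each bead's sphere outside all other
    beads of the same molecule, evaluated on a deterministic Fibonacci
    spherical quadrature (relative error ~1e-3 at the default density).
    The intermolecular *pair* potential keeps the pairwise lens form,
    where a single overlap dominates at a time.
    """
    pos = template.body_coords
    R = template.sasa_radii
    n = len(R)
    areas = np.empty(n)
    unit = _fibonacci_sphere(n_points)
    for i in range(n):
        pts = pos[i] + R[i] * unit
        exposed = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            exposed &= np.einsum(
                "ij,ij->i", pts - pos[j], pts - pos[j]) > R[j] ** 2
        areas[i] = 4.0 * np.pi * R[i] ** 2 * exposed.mean()
    return areas


def reference_areas_pairwise(template: MoleculeTemplate) -> np.ndarray:
    """Pairwise-lens approximation to A_i^ref (full sphere minus all
    pairwise buried caps, clamped at zero).  Kept for comparison; heavily
    fused templates bury everything under this approximation."""
    pos = template.body_coords
    R = template.sasa_radii
    n = len(R)
    areas = 4.0 * np.pi * R**2
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = float(np.linalg.norm(pos[i] - pos[j]))
            Ri, Rj = R[i], R[j]
            if d >= Ri + Rj:
                continue
            if d <= abs(Ri - Rj):
                if Ri <= Rj:
                    areas[i] = 0.0
                continue
            h_i = (Rj - Ri + d) * (Rj + Ri - d) / (2.0 * d)
            areas[i] -= 2.0 * np.pi * Ri * h_i
    return np.clip(areas, 0.0, None)


def _group_radius(coords: np.ndarray, elements: list[str],
                  convention: str) -> float:
    """Bare group radius (before probe inflation) from heavy-atom spread."""
    center = coords.mean(axis=0)
    dist = np.linalg.norm(coords - center, axis=1)
    rv = np.array([VDW_RADII[e] for e in elements])
    if convention == "rms":
        return float(np.sqrt(np.mean(dist**2) + np.mean(rv**2)))
    if convention == "mean":
        return float(np.mean(dist) + np.mean(rv))
    if convention == "max":
        return float(np.max(dist + rv))
    raise ValueError(f"unknown group-radius convention {convention!r}")


def build_caffeine_template(atom_coords=None,
                            mapping=None,
                            probe_radius: float = c.PROBE_RADIUS_DEFAULT,
                            surface_tension: float = c.GAMMA_CALIBRATED,
                            tfe: float = 0.0,
                            attractive_sites=TWO_SITE,
                            tfe_sites=FIVE_SITE,
                            wca_epsilon: float = c.WCA_EPSILON_DEFAULT,
                            radius_convention: str = GROUP_RADIUS_CONVENTION,
                            wca_core_scale: float = c.WCA_CORE_SCALE,
                            ) -> MoleculeTemplate:
    """Build the coarse-grained caffeine template.

    Parameters
    ----------
    atom_coords : dict name -> (3,) array, optional
        Heavy-atom coordinates (Å).  Defaults to the shipped reference
        geometry.  Elements are inferred from the first letter of atom
        names not present in the reference table.
    mapping : dict group -> tuple of atom names, optional
        Group assignment; every heavy atom must appear in exactly one
        group.  Defaults to the eight-group caffeine scheme.
    probe_radius : float
        Solvent probe radius added to group radii, Å.
    surface_tension, tfe : float
        γ (kJ/mol/Å²) placed on ``attractive_sites`` (default: the two
        ring beads, the caffeine stacking sites) and ε_TFE (kJ/mol/Å²/M)
        placed on ``tfe_sites`` (default: rings plus the three methyl
        beads, since the hydrophobic surface governs salt specificity).
    """
    if tfe_sites is None:
        tfe_sites = attractive_sites
    ref_names, ref_elements, ref_xyz = caffeine_heavy_atoms()
    element_of = dict(zip(ref_names, ref_elements))
    if atom_coords is None:
        atom_coords = {n: ref_xyz[i] for i, n in enumerate(ref_names)}
    if mapping is None:
        mapping = DEFAULT_CAFFEINE_GROUPS

    assigned = [a for atoms in mapping.values() for a in atoms]
    if len(assigned) != len(set(assigned)):
        dup = sorted({a for a in assigned if assigned.count(a) > 1})
        raise ValueError(f"atoms assigned to more than one group: {dup}")
    missing = sorted(set(atom_coords) - set(assigned))
    if missing:
        raise ValueError(f"unassigned atoms: {missing}")
    unknown = sorted(set(assigned) - set(atom_coords))
    if unknown:
        raise ValueError(f"mapped atoms without coordinates: {unknown}")

    beads = []
    for group, atoms in mapping.items():
        if len(atoms) == 0:
            raise ValueError(f"group {group!r} is empty")
        coords = np.array([atom_coords[a] for a in atoms], dtype=float)
        elements = [element_of.get(a, a[0]) for a in atoms]
        r_group = _group_radius(coords, elements, radius_convention)
        beads.append(BeadSpec(
            name=group,
            position=coords.mean(axis=0),
            sasa_radius=r_group + probe_radius,
            wca_sigma=2.0 * r_group * wca_core_scale,
            wca_epsilon=wca_epsilon,
            surface_tension=surface_tension if group in attractive_sites else 0.0,
            tfe=tfe if group in tfe_sites else 0.0,
        ))
    return MoleculeTemplate(beads=tuple(beads))
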