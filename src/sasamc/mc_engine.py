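"""Metropolis-Hastings sampling of the CG model.

Canonical and grand-canonical ensembles with the move set used for the
caffeine studies: single-molecule translation and rotation, a
COM-distance-threshold cluster move with a detailed-balance membership
guard, and (grand canonical) molecule insertion/deletion at fixed molar
activity.  One "MC iteration" is a sweep of N attempted moves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as k
from . import constants as c
from .cg_model import MoleculeTemplate, random_rotation
from .sasa_potential import PairTable, SaltField

__all__ = [
    "SystemState",
    "MoveParams",
    "RunProtocol",
    "RunResult",
    "metropolis_accept",
    "Engine",
]


@dataclass
class MoveParams:
    """Displacement parameters of the MC move set (Å, rad).

    Defaults follow the canonical-ensemble protocol of the caffeine
    study: 2.5 Å / 0.5 rad single-molecule moves and a 7.5 Å / 1.0 rad
    cluster move with a 6.5 Å threshold.  Grand-canonical runs use 10 Å
    translations and 1 rad rotations with insertion/deletion enabled.
    """

    max_translation: float = 2.5
    max_rotation: float = 0.5
    cluster_translation: float = 7.5
    cluster_rotation: float = 1.0
    cluster_threshold: float = 6.5
    weight_translation: float = 1.0
    weight_rotation: float = 1.0
    weight_cluster: float = 0.0
    weight_gc: float = 0.0

    @classmethod
    def canonical_default(cls) -> "MoveParams":
        return cls(weight_cluster=0.2)

    @classmethod
    def grand_canonical_default(cls) -> "MoveParams":
        return cls(max_translation=10.0, max_rotation=1.0,
                   weight_cluster=0.0, weight_gc=1.0)

    def validate(self):
        for name in ("max_translation", "max_rotation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.weight_cluster > 0 and (self.cluster_translation <= 0
                                        or self.cluster_threshold <= 0):
            raise ValueError("cluster move enabled with nonpositive parameters")


@dataclass
class RunProtocol:
    """Iteration counts (in sweeps of N attempted moves) and seed."""

    equilibration: int = 1000
    production: int = 10000
    seed: int = 1
    sample_stride: int = 10    # sweeps between observable samples

    def __post_init__(self):
        if self.sample_stride < 1:
            raise ValueError("sample_stride must be >= 1")


class SystemState:
    """Periodic cubic box of rigid molecules.

    Stores centers of mass (wrapped into [0, L)) and rotated bead
    offsets for up to ``capacity`` molecules; ``n`` is the current
    molecule count (grand-canonical runs change it).
    """

    def __init__(self, template: MoleculeTemplate, box_length: float,
                 n: int = 0, temperature: float = c.T_DEFAULT,
                 salt: SaltField = SaltField(), ensemble: str = "canonical",
                 activity: float | None = None, capacity: int | None = None):
        if ensemble not in ("canonical", "grand_canonical"):
            raise ValueError(f"unknown ensemble {ensemble!r}")
        if ensemble == "grand_canonical" and activity is None:
            raise ValueError("grand-canonical state needs a molar activity")
        self.template = template
        self.box_length = float(box_length)
        self.temperature = float(temperature)
        self.salt = salt
        self.ensemble = ensemble
        self.activity = activity
        if capacity is None:
            capacity = max(4 * n + 64, 256)
        nb = template.n_beads
        self.com = np.zeros((capacity, 3))
        self.offsets = np.zeros((capacity, nb, 3))
        self.n = n

    @property
    def capacity(self) -> int:
        return self.com.shape[0]

    @property
    def volume(self) -> float:
        return self.box_length ** 3

    @property
    def density_molar(self) -> float:
        return c.number_density_to_molar(self.n / self.volume)

    @classmethod
    def random(cls, template, box_length, n, rng=None, max_tries=200,
               **kwargs) -> "SystemState":
        """Random non-overlapping-ish initial configuration (poses drawn
        uniformly; clashes relaxed during equilibration)."""
        if rng is None:
            rng = np.random.default_rng(0)
        state = cls(template, box_length, n=n, **kwargs)
        body = template.body_coords
        for i in range(n):
            state.com[i] = rng.random(3) * box_length
            state.offsets[i] = body @ random_rotation(rng).T
        return state

    def bead_coordinates(self) -> np.ndarray:
        """(n, n_beads, 3) absolute bead coordinates."""
        return self.com[:self.n, None, :] + self.offsets[:self.n]

    def copy(self) -> "SystemState":
        new = SystemState(self.template, self.box_length, n=self.n,
                          temperature=self.temperature, salt=self.salt,
                          ensemble=self.ensemble, activity=self.activity,
                          capacity=self.capacity)
        new.com[:] = self.com
        new.offsets[:] = self.offsets
        return new


def metropolis_accept(delta_u: float, bias: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Standard Metropolis-Hastings criterion.

    Accept with probability min(1, exp(-ΔU/kT + bias)); ΔU = +inf is
    always rejected; a NaN ΔU signals an energy bug and raises.
    """
    if np.isnan(delta_u):
        raise FloatingPointError("NaN energy change in Metropolis step")
    if np.isinf(delta_u) and delta_u > 0:
        return False
    beta = 1.0 / c.kT(temperature)
    arg = -beta * delta_u + bias
    if arg >= 0:
        return True
    return rng.random() < np.exp(arg)


@dataclass
class RunResult:
    state: SystemState
    attempts: np.ndarray
    accepts: np.ndarray
    energy_initial: float
    energy_final: float
    du_accumulated: float
    sweeps: int
    seed: int

    @property
    def acceptance_ratios(self) -> dict:
        names = ("translation", "rotation", "cluster", "gc")
        out = {}
        for i, name in enumerate(names):
            if self.attempts[i] > 0:
                out[name] = self.accepts[i] / self.attempts[i]
        return out

    @property
    def energy_drift(self) -> float:
        """|U(final) - U(initial) - ΣΔU| in kJ/mol; should be ~1e-9."""
        return abs(self.energy_final - self.energy_initial
                   - self.du_accumulated)


class Engine:
    """Runs MC sweeps and dispatches observer callbacks.

    Observers are objects with ``stride`` (sweeps) and ``sample(state)``;
    they are called during production only.  The run is fully
    reproducible from the protocol seed: one kernel RNG stream is seeded
    once and shared by moves and estimator insertions.
    """

    def __init__(self, table: PairTable):
        self.table = table

    def _kernel_args(self, state: SystemState):
        t = self.table
        coeff = t.coefficients(state.salt)
        return (t.sigma ** 2, t.epsilon, coeff, t.contact, t.area0,
                t.mol_cutoff ** 2)

    def total_energy(self, state: SystemState) -> float:
        u_pair = k.total_energy(state.com[:state.n], state.offsets[:state.n],
                                state.box_length, *self._kernel_args(state))
        u_one = state.salt.c_s * self.table.u_one_coeff
        return u_pair + state.n * u_one

    def run(self, state: SystemState, moves: MoveParams,
            protocol: RunProtocol, observers=()) -> RunResult:
        moves.validate()
        if state.box_length < 2.0 * self.table.cutoff:
            raise ValueError("box too small for the interaction cutoff")
        t = self.table
        beta = 1.0 / c.kT(state.temperature)
        u_one = state.salt.c_s * t.u_one_coeff
        w_gc = moves.weight_gc if state.ensemble == "grand_canonical" else 0.0
        act = c.molar_to_number_density(state.activity) if w_gc > 0 else 0.0
        body = np.ascontiguousarray(state.template.body_coords)
        member = np.zeros(state.capacity, dtype=np.int8)
        stack = np.zeros(state.capacity, dtype=np.int64)
        args = self._kernel_args(state)

        u0 = self.total_energy(state)
        if not np.isfinite(u0) and u0 < k.BIG:
            raise FloatingPointError("non-finite initial energy")

        k.seed_rng(protocol.seed % 2**31)
        attempts = np.zeros(4, dtype=np.int64)
        accepts = np.zeros(4, dtype=np.int64)
        du_total = 0.0

        # One sweep is a fixed number of attempted moves, frozen at run
        # start (grand-canonical N fluctuates; a state-dependent chunk
        # length would oversample low-N states between observer calls).
        sweep_moves = max(state.n, 1)

        def sweep_chunk(n_sweeps):
            nonlocal du_total
            n_moves = n_sweeps * sweep_moves
            n_new, du, att, acc = k.mc_chunk(
                state.com, state.offsets, state.n, state.box_length, *args,
                beta, u_one,
                moves.max_translation, moves.max_rotation,
                moves.cluster_translation, moves.cluster_rotation,
                moves.cluster_threshold,
                moves.weight_translation, moves.weight_rotation,
                moves.weight_cluster, w_gc,
                act, body, n_moves, -1, member, stack)
            state.n = int(n_new)
            du_total += du
            attempts[:] += att
            accepts[:] += acc

        if protocol.equilibration > 0:
            sweep_chunk(protocol.equilibration)

        stride = protocol.sample_stride
        done = 0
        while done < protocol.production:
            step = min(stride, protocol.production - done)
            sweep_chunk(step)
            done += step
            for obs in observers:
                if done % getattr(obs, "stride", stride) == 0:
                    obs.sample(state)

        u1 = self.total_energy(state)
        if np.isnan(u1):
            raise FloatingPointError("energy diverged during run")
        return RunResult(state=state, attempts=attempts, accepts=accepts,
                         energy_initial=u0, energy_final=u1,
                         du_accumulated=du_total,
                         sweeps=protocol.equilibration + protocol.production,
                         seed=protocol.seed)

    # -- estimator hooks needing kernel access -------------------------
    def widom_sum(self, state: SystemState, n_insert: int) -> float:
        """Σ exp(-βΔU_insert) over n_insert random-pose insertions
        (continues the engine RNG stream)."""
        beta = 1.0 / c.kT(state.temperature)
        u_one = state.salt.c_s * self.table.u_one_coeff
        body = np.ascontiguousarray(state.template.body_coords)
        return k.widom_insertions(
            state.com, state.offsets, state.n, state.box_length,
            *self._kernel_args(state), beta, u_one, body, n_insert, -1)

    def perturbed_energy(self, state: SystemState, scale: float) -> float:
        """Total pair energy with COMs scaled isotropically by ``scale``
        (rigid molecules), for virtual-volume pressure estimates."""
        return k.scaled_total_energy(
            state.com, state.offsets, state.n, state.box_length, scale,
            *self._kernel_args(state))
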