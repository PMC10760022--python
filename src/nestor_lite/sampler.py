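"""Metropolis sampling of bead models from the modified prior.

The nested-sampling loop needs two things from a sampler: approximately
independent draws from the modified prior, and draws from the *constrained*
modified prior (log-likelihood strictly above a threshold).  Constrained
draws are plain prior draws filtered by rejection, matching the scheme of
replacing the worst live point with a fresh prior sample subject to the
likelihood constraint.

Single-temperature Metropolis is used; the proposal distribution is symmetric
(isotropic Gaussian bead translations, Gaussian rigid-body translations and
rotation vectors), so acceptance is min(1, exp(Δ log modified prior)).  A
replica-exchange ladder could be layered on top of :class:`StructuralScorer`
without touching the nested-sampling loop, which only consumes the
``sample_from_modified_prior`` / ``constrained_sample`` / ``log_likelihood``
contract.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .assembly_model import BeadTopology, StructureModel
from .errors import InvalidParameterError
from .restraints import CompiledScore, RestraintConfig


@dataclass(frozen=True)
class MoveSet:
    """Proposal step sizes for one Metropolis move."""

    bead_step: float = 3.0          # Å, flexible-bead translation scale
    rb_trans_step: float = 3.0      # Å, rigid-body translation scale
    rb_rot_step: float = 0.3        # rad, rigid-body rotation-vector scale
    n_steps_per_sample: int = 50    # MCMC steps between returned samples

    def __post_init__(self) -> None:
        if self.bead_step < 0 or self.rb_trans_step < 0 or self.rb_rot_step < 0:
            raise InvalidParameterError("move step sizes must be >= 0")
        if self.n_steps_per_sample < 0:
            raise InvalidParameterError("n_steps_per_sample must be >= 0")


@dataclass(frozen=True)
class SampleFailure:
    """Constrained sampling gave up: ``attempts`` draws, none strictly above threshold.

    ``best_log_likelihood`` is the highest rejected log-likelihood; the
    nested-sampling loop uses it to tell a likelihood plateau (draws landing
    exactly on the threshold) from a genuine sampling failure.
    """

    attempts: int
    best_log_likelihood: float


def _movable_units(topology: BeadTopology) -> list[tuple[str, object]]:
    units: list[tuple[str, object]] = [("bead", int(i)) for i in topology.flexible_indices]
    units.extend(("body", np.array(members, dtype=int)) for members in topology.rigid_bodies.values())
    return units


def propose_move(model: StructureModel, moves: MoveSet, rng: np.random.Generator) -> StructureModel:
    """One symmetric proposal: translate a random flexible bead, or move a rigid body.

    A rigid body receives a Gaussian translation and a rotation about its
    centroid by an isotropic Gaussian rotation vector; both are symmetric, so
    detailed balance needs no Hastings correction.  The input model is left
    unmodified.
    """
    units = _movable_units(model.topology)
    coords = model.coordinates.copy()
    if not units:
        return StructureModel(coords, model.topology)
    kind, target = units[rng.integers(len(units))]
    if kind == "bead":
        coords[target] = coords[target] + rng.normal(scale=moves.bead_step, size=3)
    else:
        members = target
        centroid = coords[members].mean(axis=0)
        rotvec = rng.normal(scale=moves.rb_rot_step, size=3)
        shift = rng.normal(scale=moves.rb_trans_step, size=3)
        rot = Rotation.from_rotvec(rotvec)
        coords[members] = rot.apply(coords[members] - centroid) + centroid + shift
    return StructureModel(coords, model.topology)


def initialize_model(
    topology: BeadTopology, rng: np.random.Generator, box_scale: float = 3.0
) -> StructureModel:
    """Place beads by a bond-respecting random walk inside a bounding sphere.

    The sphere radius is ``box_scale`` times the volume-equivalent radius of
    the whole assembly, (Σ rᵢ³)^(1/3), so the initial spread scales with the
    physical size of the assembly rather than with the bead count.  Chain
    starts are uniform in the sphere; each subsequent bead sits at contact
    distance from its predecessor in a random direction.
    """
    radii = topology.radii
    bound = box_scale * float(np.sum(radii**3) ** (1.0 / 3.0))
    coords = np.zeros((topology.n_beads, 3))
    prev_chain = None
    for i, bead in enumerate(topology.beads):
        if bead.chain_id != prev_chain:
            # rejection sampling of a uniform point in the bounding sphere
            while True:
                pt = rng.uniform(-bound, bound, size=3)
                if np.dot(pt, pt) <= bound**2:
                    break
            coords[i] = pt
            prev_chain = bead.chain_id
        else:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            coords[i] = coords[i - 1] + direction * (radii[i - 1] + radii[i])
    return StructureModel(coords, topology)


def _metropolis_steps(
    coords: np.ndarray,
    score: CompiledScore,
    moves: MoveSet,
    units: list[tuple[str, object]],
    rng: np.random.Generator,
    n_steps: int,
) -> np.ndarray:
    """In-place Metropolis chain on the modified prior (hot path, no object churn)."""
    current_lp = score.log_modified_prior(coords)
    for _ in range(n_steps):
        if not units:
            break
        kind, target = units[rng.integers(len(units))]
        if kind == "bead":
            saved = coords[target].copy()
            coords[target] += rng.normal(scale=moves.bead_step, size=3)
        else:
            saved = coords[target].copy()
            centroid = saved.mean(axis=0)
            rot = Rotation.from_rotvec(rng.normal(scale=moves.rb_rot_step, size=3))
            shift = rng.normal(scale=moves.rb_trans_step, size=3)
            coords[target] = rot.apply(saved - centroid) + centroid + shift
        prop_lp = score.log_modified_prior(coords)
        if prop_lp >= current_lp or rng.uniform() < math.exp(prop_lp - current_lp):
            current_lp = prop_lp
        else:
            coords[target] = saved
    return coords


def sample_from_modified_prior(
    initial: StructureModel,
    config: RestraintConfig | CompiledScore,
    moves: MoveSet,
    rng: np.random.Generator,
) -> tuple[StructureModel, int, float]:
    """Run ``n_steps_per_sample`` Metropolis steps on the modified prior.

    Returns the final state, the number of steps taken, and the measured mean
    wall time per step (0.0 for an empty chain).
    """
    score = config if isinstance(config, CompiledScore) else CompiledScore(initial.topology, config)
    units = _movable_units(initial.topology)
    coords = initial.coordinates.copy()
    n_steps = moves.n_steps_per_sample
    t0 = time.perf_counter()
    coords = _metropolis_steps(coords, score, moves, units, rng, n_steps)
    elapsed = time.perf_counter() - t0
    per_step = elapsed / n_steps if n_steps else 0.0
    return StructureModel(coords, initial.topology), n_steps, per_step


def constrained_sample(
    initial: StructureModel,
    config: RestraintConfig | CompiledScore,
    log_l_threshold: float,
    moves: MoveSet,
    max_attempts: int,
    rng: np.random.Generator,
) -> StructureModel | SampleFailure:
    """Draw from the modified prior until log-likelihood > threshold (strict).

    Each attempt advances the Markov chain by ``n_steps_per_sample`` steps and
    checks the resulting draw against the threshold; after ``max_attempts``
    consecutive rejections a :class:`SampleFailure` is returned.
    """
    if max_attempts < 1:
        raise InvalidParameterError(f"max_attempts must be >= 1, got {max_attempts}")
    score = config if isinstance(config, CompiledScore) else CompiledScore(initial.topology, config)
    state = initial
    best = -math.inf
    for attempt in range(1, max_attempts + 1):
        state, _, _ = sample_from_modified_prior(state, score, moves, rng)
        ll = score.log_likelihood(state.coordinates)
        if ll > log_l_threshold:
            return state
        best = max(best, ll)
    return SampleFailure(attempts=max_attempts, best_log_likelihood=best)


class StructuralScorer:
    """Adapter exposing the nested-sampling contract for one representation.

    Maintains a persistent Markov chain on the modified prior; successive
    returned samples are ``n_steps_per_sample`` Metropolis steps apart.
    Accumulates total MCMC wall time and step count so a run can report its
    mean sampling time per step.
    """

    def __init__(
        self,
        topology: BeadTopology,
        config: RestraintConfig,
        moves: MoveSet | None = None,
        max_attempts: int = 50,
        box_scale: float = 3.0,
    ):
        self.topology = topology
        self.config = config
        self.moves = moves or MoveSet()
        self.max_attempts = max_attempts
        self.box_scale = box_scale
        self._score = CompiledScore(topology, config)
        self._units = _movable_units(topology)
        self._coords: np.ndarray | None = None
        self.total_steps = 0
        self.total_time = 0.0

    def _advance(self, rng: np.random.Generator) -> StructureModel:
        if self._coords is None:
            self._coords = initialize_model(self.topology, rng, self.box_scale).coordinates
            # untimed warm-up chain: excludes interpreter/numpy warm-up and the
            # relaxation from the artificial initial walk from the timing
            self._coords = _metropolis_steps(
                self._coords, self._score, self.moves, self._units, rng,
                self.moves.n_steps_per_sample,
            )
        t0 = time.perf_counter()
        self._coords = _metropolis_steps(
            self._coords, self._score, self.moves, self._units, rng, self.moves.n_steps_per_sample
        )
        self.total_time += time.perf_counter() - t0
        self.total_steps += self.moves.n_steps_per_sample
        return StructureModel(self._coords.copy(), self.topology)

    def sample_from_modified_prior(self, rng: np.random.Generator) -> StructureModel:
        return self._advance(rng)

    def log_likelihood(self, state: StructureModel) -> float:
        return self._score.log_likelihood(state.coordinates)

    def constrained_sample(
        self, log_l_threshold: float, rng: np.random.Generator
    ) -> StructureModel | SampleFailure:
        best = -math.inf
        for _ in range(self.max_attempts):
            state = self._advance(rng)
            ll = self.log_likelihood(state)
            if ll > log_l_threshold:
                return state
            best = max(best, ll)
        return SampleFailure(attempts=self.max_attempts, best_log_likelihood=best)

    @property
    def per_step_time(self) -> float:
        return self.total_time / self.total_steps if self.total_steps else 0.0
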