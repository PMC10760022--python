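"""Repartitioned scoring of bead models: modified prior and likelihood.

Nested sampling is inaccurate when the prior is very dissimilar to the
posterior, so the scoring system is repartitioned: the *modified prior*
consists of the stereochemistry restraints (excluded volume, chain
connectivity) plus a random subset of the crosslinks (by default 30%), and
the *likelihood* consists of the remaining crosslinks.  The product of the
two factors — the posterior — is unchanged by the split.

All distances are bead center-to-center; bead radii enter only the
stereochemistry terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .assembly_model import BeadTopology, StructureModel
from .errors import CrosslinkMappingError, InvalidParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Crosslink:
    """One crosslink: a residue-pair proximity restraint between two chains."""

    protein1: str
    residue1: int
    protein2: str
    residue2: int

    def __post_init__(self) -> None:
        if (self.protein1, self.residue1) == (self.protein2, self.residue2):
            raise InvalidParameterError(f"self-crosslink {self!r}")


@dataclass
class RestraintConfig:
    """The repartitioned scoring system.

    Parameters
    ----------
    prior_crosslinks, likelihood_crosslinks:
        Disjoint crosslink sets; the first scores inside the modified prior,
        the second forms the likelihood.
    xl_cutoff:
        Sigmoid midpoint d0 of the crosslink satisfaction probability (Å).
    xl_slope:
        Sigmoid width λ (Å).
    xl_floor:
        False-positive floor ω: p(d) → ω as d → ∞, keeping log-likelihoods
        bounded below (the likelihood-plateau test relies on this bound).
    ev_strength, conn_strength:
        Harmonic force constants of the excluded-volume and connectivity
        penalties (1/Å²).
    """

    prior_crosslinks: list[Crosslink] = field(default_factory=list)
    likelihood_crosslinks: list[Crosslink] = field(default_factory=list)
    xl_cutoff: float = 21.0
    xl_slope: float = 2.0
    xl_floor: float = 0.01
    ev_strength: float = 1.0
    conn_strength: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.xl_floor < 1.0):
            raise InvalidParameterError(f"xl_floor must be in [0, 1), got {self.xl_floor}")
        for name in ("xl_cutoff", "xl_slope", "ev_strength", "conn_strength"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        overlap = set(self.prior_crosslinks) & set(self.likelihood_crosslinks)
        if overlap:
            raise InvalidParameterError(f"crosslink sets overlap: {sorted(map(str, overlap))[:3]}")


def repartition_restraints(
    crosslinks: list[Crosslink], prior_fraction: float, seed: int
) -> tuple[list[Crosslink], list[Crosslink]]:
    """Split crosslinks at random into a prior set and a likelihood set.

    ``round(prior_fraction * N)`` crosslinks are drawn uniformly without
    replacement into the prior set; the rest inform the likelihood.  The same
    seed always yields the same split.
    """
    if not (0.0 <= prior_fraction <= 1.0):
        raise InvalidParameterError(f"prior_fraction must be in [0, 1], got {prior_fraction}")
    if not crosslinks:
        if prior_fraction > 0:
            logger.warning("repartition_restraints called with an empty crosslink list")
        return [], []
    rng = np.random.default_rng(seed)
    n_prior = int(round(prior_fraction * len(crosslinks)))
    chosen = set(rng.choice(len(crosslinks), size=n_prior, replace=False).tolist())
    prior_set = [xl for i, xl in enumerate(crosslinks) if i in chosen]
    likelihood_set = [xl for i, xl in enumerate(crosslinks) if i not in chosen]
    return prior_set, likelihood_set


def _crosslink_bead_pairs(topology: BeadTopology, crosslinks: list[Crosslink]) -> np.ndarray:
    pairs = []
    for xl in crosslinks:
        try:
            i = topology.bead_index(xl.protein1, xl.residue1)
            j = topology.bead_index(xl.protein2, xl.residue2)
        except CrosslinkMappingError as exc:
            raise CrosslinkMappingError(f"cannot map crosslink {xl}: {exc}") from exc
        pairs.append((i, j))
    return np.array(pairs, dtype=int).reshape(-1, 2)


def _xl_log_prob(d: np.ndarray, d0: float, slope: float, floor: float) -> np.ndarray:
    # p(d) = ω + (1-ω) σ((d0 - d)/λ); bounded in (ω, 1) so the log is finite
    p = floor + (1.0 - floor) * expit((d0 - d) / slope)
    return np.log(p)


def crosslink_loglik(
    model: StructureModel,
    crosslinks: list[Crosslink],
    d0: float | None = None,
    slope: float | None = None,
    floor: float | None = None,
) -> float:
    """Sum of log sigmoid-with-floor satisfaction probabilities over crosslinks.

    Each crosslink contributes log[ω + (1-ω)/(1 + exp((d - d0)/λ))] where d is
    the center-to-center distance of the two beads covering its residues.
    """
    defaults = RestraintConfig()
    d0 = defaults.xl_cutoff if d0 is None else d0
    slope = defaults.xl_slope if slope is None else slope
    floor = defaults.xl_floor if floor is None else floor
    if not crosslinks:
        return 0.0
    pairs = _crosslink_bead_pairs(model.topology, crosslinks)
    diff = model.coordinates[pairs[:, 0]] - model.coordinates[pairs[:, 1]]
    d = np.linalg.norm(diff, axis=1)
    return float(np.sum(_xl_log_prob(d, d0, slope, floor)))


def excluded_volume_logprior(model: StructureModel, k_ev: float = 1.0) -> float:
    """Soft-sphere overlap penalty: −(k/2) Σ max(0, rᵢ + rⱼ − dᵢⱼ)² over non-rigid pairs."""
    pairs = model.topology.ev_pairs
    if len(pairs) == 0:
        return 0.0
    diff = model.coordinates[pairs[:, 0]] - model.coordinates[pairs[:, 1]]
    d = np.linalg.norm(diff, axis=1)
    overlap = np.maximum(
        0.0, model.topology.radii[pairs[:, 0]] + model.topology.radii[pairs[:, 1]] - d
    )
    return float(-0.5 * k_ev * np.sum(overlap**2))


def connectivity_logprior(model: StructureModel, k_conn: float = 1.0) -> float:
    """Chain connectivity: −(k/2) Σ max(0, dᵢⱼ − (rᵢ + rⱼ))² over consecutive beads."""
    pairs = model.topology.consecutive_pairs
    if len(pairs) == 0:
        return 0.0
    diff = model.coordinates[pairs[:, 0]] - model.coordinates[pairs[:, 1]]
    d = np.linalg.norm(diff, axis=1)
    stretch = np.maximum(
        0.0, d - (model.topology.radii[pairs[:, 0]] + model.topology.radii[pairs[:, 1]])
    )
    return float(-0.5 * k_conn * np.sum(stretch**2))


def score_model(model: StructureModel, config: RestraintConfig) -> tuple[float, float]:
    """Return (log modified prior, log likelihood) of a model under ``config``.

    The sum of the two is invariant to how the crosslinks were split
    (posterior repartitioning keeps the product of prior and likelihood
    unchanged).
    """
    log_prior = (
        excluded_volume_logprior(model, config.ev_strength)
        + connectivity_logprior(model, config.conn_strength)
        + crosslink_loglik(
            model, config.prior_crosslinks, config.xl_cutoff, config.xl_slope, config.xl_floor
        )
    )
    log_lik = crosslink_loglik(
        model, config.likelihood_crosslinks, config.xl_cutoff, config.xl_slope, config.xl_floor
    )
    return log_prior, log_lik


class CompiledScore:
    """Precompiled scorer for one (topology, config) pair.

    Resolves crosslinks to bead-index arrays once so that the per-step cost of
    MCMC is pure vectorized arithmetic on the coordinate array.
    """

    def __init__(self, topology: BeadTopology, config: RestraintConfig):
        self.topology = topology
        self.config = config
        self._prior_pairs = _crosslink_bead_pairs(topology, config.prior_crosslinks)
        self._lik_pairs = _crosslink_bead_pairs(topology, config.likelihood_crosslinks)
        self._ev = topology.ev_pairs
        self._conn = topology.consecutive_pairs
        r = topology.radii
        self._ev_contact = r[self._ev[:, 0]] + r[self._ev[:, 1]] if len(self._ev) else None
        self._conn_contact = r[self._conn[:, 0]] + r[self._conn[:, 1]] if len(self._conn) else None

    def _pair_dist(self, coords: np.ndarray, pairs: np.ndarray) -> np.ndarray:
        diff = coords[pairs[:, 0]] - coords[pairs[:, 1]]
        return np.sqrt(np.einsum("ij,ij->i", diff, diff))

    def log_modified_prior(self, coords: np.ndarray) -> float:
        total = 0.0
        if self._ev_contact is not None:
            overlap = np.maximum(0.0, self._ev_contact - self._pair_dist(coords, self._ev))
            total -= 0.5 * self.config.ev_strength * float(np.sum(overlap**2))
        if self._conn_contact is not None:
            stretch = np.maximum(0.0, self._pair_dist(coords, self._conn) - self._conn_contact)
            total -= 0.5 * self.config.conn_strength * float(np.sum(stretch**2))
        if len(self._prior_pairs):
            d = self._pair_dist(coords, self._prior_pairs)
            total += float(
                np.sum(_xl_log_prob(d, self.config.xl_cutoff, self.config.xl_slope, self.config.xl_floor))
            )
        return total

    def log_likelihood(self, coords: np.ndarray) -> float:
        if not len(self._lik_pairs):
            return 0.0
        d = self._pair_dist(coords, self._lik_pairs)
        return float(
            np.sum(_xl_log_prob(d, self.config.xl_cutoff, self.config.xl_slope, self.config.xl_floor))
        )


# ---------------------------------------------------------------------------
# Crosslink CSV I/O (protein1,residue1,protein2,residue2 dialect)
# ---------------------------------------------------------------------------

def read_crosslink_csv(path: str | Path, deduplicate: bool = False) -> list[Crosslink]:
    df = pd.read_csv(path, dtype={"protein1": str, "protein2": str})
    required = ["protein1", "residue1", "protein2", "residue2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"crosslink CSV missing columns: {missing}")
    if deduplicate:
        df = df.drop_duplicates(subset=required)
    return [
        Crosslink(str(r.protein1), int(r.residue1), str(r.protein2), int(r.residue2))
        for r in df.itertuples(index=False)
    ]


def write_crosslink_csv(crosslinks: list[Crosslink], path: str | Path) -> None:
    pd.DataFrame(
        {
            "protein1": [x.protein1 for x in crosslinks],
            "residue1": [x.residue1 for x in crosslinks],
            "protein2": [x.protein2 for x in crosslinks],
            "residue2": [x.residue2 for x in crosslinks],
        }
    ).to_csv(path, index=False)
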