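"""Synthetic reference assemblies and simulated crosslink datasets.

Real benchmark assemblies are multi-chain, globular complexes with
crosslinking mass-spectrometry data containing a fraction of false positives.
This module emulates those statistical features at desk scale: each chain is
a fixed-bond-length (3.8 Å, the Cα–Cα step) self-avoiding random walk confined
to a sphere so the assembly reaches a target radius of gyration, and
crosslinks are sampled either from residue pairs within a distance cutoff
(true positives) or uniformly from all pairs (false positives).

What this does *not* emulate: secondary structure, realistic contact order,
sequence content, or crosslinker chemistry — passing tests show the method
ranks representations correctly for compact assemblies with cutoff-type
distance data, not that it handles every pathology of real XL-MS datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .assembly_model import ChainSpec
from .errors import GenerationError, InvalidParameterError
from .restraints import Crosslink

#: Cα–Cα virtual bond length (Å).
BOND_LENGTH = 3.8
#: Soft self-avoidance distance during chain growth (Å).
MIN_CLEARANCE = 2.5


@dataclass(frozen=True)
class AssemblySpec:
    """Blueprint for a synthetic assembly: chains, compactness and a seed."""

    chains: tuple[ChainSpec, ...]
    compactness: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.chains) < 1:
            raise InvalidParameterError("need at least one chain")

    @property
    def n_residues(self) -> int:
        return sum(c.length for c in self.chains)

    @property
    def target_rg(self) -> float:
        """Target radius of gyration: compactness × N^(1/3) × 3 Å (globular scaling)."""
        return self.compactness * self.n_residues ** (1.0 / 3.0) * 3.0


@dataclass
class ReferenceStructure:
    """Ground-truth per-residue coordinates of a synthetic assembly."""

    chains: dict[str, np.ndarray]  # chain_id -> (length, 3) Å
    spec: AssemblySpec

    residue_index: list[tuple[str, int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.residue_index = [
            (cid, r + 1) for cid, xyz in self.chains.items() for r in range(len(xyz))
        ]

    @property
    def coordinates(self) -> np.ndarray:
        """All residue coordinates stacked in residue_index order."""
        return np.concatenate(list(self.chains.values()), axis=0)

    @property
    def radius_of_gyration(self) -> float:
        xyz = self.coordinates
        return float(np.sqrt(np.mean(np.sum((xyz - xyz.mean(axis=0)) ** 2, axis=1))))

    def distance(self, chain1: str, res1: int, chain2: str, res2: int) -> float:
        return float(np.linalg.norm(self.chains[chain1][res1 - 1] - self.chains[chain2][res2 - 1]))

    def to_pdb(self, path: str | Path) -> None:
        """Write one Cα pseudo-atom per residue."""
        lines = []
        serial = 0
        for cid, xyz in self.chains.items():
            for r, pt in enumerate(xyz, start=1):
                serial += 1
                lines.append(
                    f"ATOM  {serial:5d}  CA  GLY {cid[:1]}{r:4d}    "
                    f"{pt[0]:8.3f}{pt[1]:8.3f}{pt[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {'C':>2s}"
                )
        lines.append("END")
        Path(path).write_text("\n".join(lines) + "\n")


def _grow_chain(
    length: int,
    confinement_radius: float,
    existing: list[np.ndarray],
    rng: np.random.Generator,
    max_tries: int = 30,
) -> np.ndarray:
    """Fixed-bond random walk, biased inward at the confinement boundary, softly self-avoiding."""
    occupied = np.concatenate(existing, axis=0) if existing else np.zeros((0, 3))
    coords = np.zeros((length, 3))
    # start inside the inner half of the confinement sphere
    while True:
        start = rng.uniform(-confinement_radius, confinement_radius, size=3)
        if np.linalg.norm(start) <= 0.5 * confinement_radius:
            break
    coords[0] = start
    for i in range(1, length):
        prev = coords[i - 1]
        best = None
        for _ in range(max_tries):
            step = rng.normal(size=3)
            step /= np.linalg.norm(step)
            candidate = prev + BOND_LENGTH * step
            if np.linalg.norm(candidate) > confinement_radius:
                continue
            near_self = i > 1 and np.min(np.linalg.norm(coords[: i - 1] - candidate, axis=1)) < MIN_CLEARANCE
            near_other = len(occupied) > 0 and np.min(
                np.linalg.norm(occupied - candidate, axis=1)
            ) < MIN_CLEARANCE
            best = candidate  # last in-sphere candidate, kept as fallback
            if not (near_self or near_other):
                break
        if best is None:
            # boxed in at the boundary: step straight inward
            inward = -prev / np.linalg.norm(prev)
            best = prev + BOND_LENGTH * inward
        coords[i] = best
    return coords


def generate_reference_assembly(spec: AssemblySpec) -> ReferenceStructure:
    """Generate ground-truth coordinates for ``spec`` (seed-deterministic).

    Chains are grown one after another inside a common confinement sphere
    sized so that a space-filling walk reaches the target radius of gyration
    (for a uniform ball, Rg = √(3/5)·R).
    """
    rng = np.random.default_rng(spec.seed)
    confinement = spec.target_rg * np.sqrt(5.0 / 3.0)
    chains: dict[str, np.ndarray] = {}
    grown: list[np.ndarray] = []
    for c in spec.chains:
        xyz = _grow_chain(c.length, confinement, grown, rng)
        chains[c.chain_id] = xyz
        grown.append(xyz)
    return ReferenceStructure(chains=chains, spec=spec)


def simulate_crosslinks(
    ref: ReferenceStructure,
    n: int,
    cutoff: float = 25.0,
    fp_rate: float = 0.1,
    seed: int = 0,
    return_truth: bool = False,
) -> list[Crosslink] | tuple[list[Crosslink], list[bool]]:
    """Simulate ``n`` crosslinks from a reference structure.

    With probability ``1 − fp_rate`` a crosslink is a uniform draw from the
    residue pairs within ``cutoff`` Å (a true positive); otherwise it is a
    uniform draw from all distinct residue pairs (a false positive).
    Duplicates are allowed, as in real datasets.  With ``return_truth`` the
    per-record truth flags are returned alongside (testing side channel).
    """
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    if not (0.0 <= fp_rate <= 1.0):
        raise InvalidParameterError(f"fp_rate must be in [0, 1], got {fp_rate}")
    xyz = ref.coordinates
    d = squareform(pdist(xyz))
    iu, ju = np.triu_indices(len(xyz), k=1)
    within = d[iu, ju] <= cutoff
    tp_pool = np.flatnonzero(within)
    if tp_pool.size == 0:
        raise GenerationError(f"no residue pair within {cutoff} Å; cannot simulate true positives")
    rng = np.random.default_rng(seed)
    links: list[Crosslink] = []
    truth: list[bool] = []
    for _ in range(n):
        is_tp = rng.uniform() >= fp_rate
        k = rng.choice(tp_pool) if is_tp else rng.integers(len(iu))
        c1, r1 = ref.residue_index[iu[k]]
        c2, r2 = ref.residue_index[ju[k]]
        links.append(Crosslink(c1, r1, c2, r2))
        truth.append(bool(is_tp))
    if return_truth:
        return links, truth
    return links


# ---------------------------------------------------------------------------
# The standard desk-scale benchmark used throughout tests and examples
# ---------------------------------------------------------------------------

def benchmark_assembly(seed: int = 0) -> AssemblySpec:
    """Two flexible chains (100 + 60 residues), compact globular fold."""
    return AssemblySpec(
        chains=(ChainSpec("A", 100), ChainSpec("B", 60)),
        compactness=1.0,
        seed=seed,
    )


def benchmark_dataset(
    seed: int = 0, n_crosslinks: int = 40, cutoff: float = 25.0, fp_rate: float = 0.1
) -> tuple[ReferenceStructure, list[Crosslink]]:
    """Reference structure plus a simulated crosslink table for the desk benchmark."""
    spec = benchmark_assembly(seed)
    ref = generate_reference_assembly(spec)
    links = simulate_crosslinks(ref, n_crosslinks, cutoff=cutoff, fp_rate=fp_rate, seed=seed + 1)
    return ref, links
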