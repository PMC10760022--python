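"""Coarse-grained bead representations of macromolecular assemblies.

A candidate representation maps each chain of an assembly onto a string of
spherical beads, every bead covering a fixed number of contiguous residues
(the last bead of a chain absorbs the remainder).  Chains may be grouped into
rigid bodies that move as single units with six degrees of freedom; all other
beads are flexible with three degrees of freedom each.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, TopologyError

#: Mean amino-acid volume used for volume-equivalent bead radii (Å³/residue).
RESIDUE_VOLUME = 130.0


@dataclass(frozen=True)
class ChainSpec:
    """One chain of the assembly: an id, a residue count and an optional rigid-body label.

    Chains sharing a ``rigid_body`` label move as one rigid unit; a chain with
    ``rigid_body=None`` is fully flexible.
    """

    chain_id: str
    length: int
    rigid_body: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise InvalidParameterError(
                f"chain {self.chain_id!r}: length must be >= 1, got {self.length}"
            )


@dataclass(frozen=True)
class Bead:
    """A spherical bead covering residues ``residue_start..residue_end`` (1-based, inclusive)."""

    chain_id: str
    residue_start: int
    residue_end: int
    radius: float
    flexible: bool

    @property
    def n_residues(self) -> int:
        return self.residue_end - self.residue_start + 1


@dataclass
class BeadTopology:
    """A candidate coarse-grained representation.

    Attributes
    ----------
    beads:
        Ordered bead list; beads of one chain are consecutive and cover the
        chain's residues exactly.
    residues_per_bead:
        Nominal coarse-graining level (the last bead of a chain may be smaller).
    rigid_bodies:
        Mapping from rigid-body label to the indices of its member beads.
    """

    beads: list[Bead]
    residues_per_bead: int
    rigid_bodies: dict[str, list[int]] = field(default_factory=dict)
    chains: list[ChainSpec] = field(default_factory=list)

    # derived arrays, built once for fast scoring
    radii: np.ndarray = field(init=False, repr=False)
    flexible_indices: np.ndarray = field(init=False, repr=False)
    consecutive_pairs: np.ndarray = field(init=False, repr=False)
    ev_pairs: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.radii = np.array([b.radius for b in self.beads], dtype=float)
        self.flexible_indices = np.array(
            [i for i, b in enumerate(self.beads) if b.flexible], dtype=int
        )
        self.consecutive_pairs = self._consecutive_pairs()
        self.ev_pairs = self._ev_pairs()
        self._bead_lookup = self._build_lookup()

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    def _consecutive_pairs(self) -> np.ndarray:
        pairs = []
        for i in range(len(self.beads) - 1):
            if self.beads[i].chain_id == self.beads[i + 1].chain_id:
                pairs.append((i, i + 1))
        return np.array(pairs, dtype=int).reshape(-1, 2)

    def _ev_pairs(self) -> np.ndarray:
        """All bead pairs i<j that interact through excluded volume.

        Pairs within one rigid body are skipped: their distance is fixed, so a
        constant penalty would only shift the unnormalized prior.
        """
        n = len(self.beads)
        body_of = np.full(n, -1, dtype=int)
        for k, members in enumerate(self.rigid_bodies.values()):
            body_of[list(members)] = k
        iu, ju = np.triu_indices(n, k=1)
        same_body = (body_of[iu] >= 0) & (body_of[iu] == body_of[ju])
        return np.column_stack([iu[~same_body], ju[~same_body]])

    def _build_lookup(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        lookup: dict[str, list[tuple[int, int]]] = {}
        for i, b in enumerate(self.beads):
            lookup.setdefault(b.chain_id, []).append((b.residue_start, i))
        return {
            cid: (
                np.array([s for s, _ in entries], dtype=int),
                np.array([i for _, i in entries], dtype=int),
            )
            for cid, entries in lookup.items()
        }

    def bead_index(self, chain_id: str, residue: int) -> int:
        """Index of the bead covering ``residue`` of ``chain_id``."""
        from .errors import CrosslinkMappingError

        if chain_id not in self._bead_lookup:
            raise CrosslinkMappingError(f"unknown chain {chain_id!r}")
        starts, idx = self._bead_lookup[chain_id]
        pos = int(np.searchsorted(starts, residue, side="right")) - 1
        if pos < 0:
            raise CrosslinkMappingError(f"residue {residue} of chain {chain_id!r} not covered")
        i = int(idx[pos])
        if residue > self.beads[i].residue_end:
            raise CrosslinkMappingError(f"residue {residue} of chain {chain_id!r} not covered")
        return i


@dataclass
class StructureModel:
    """One configuration of a representation: bead center coordinates in Å."""

    coordinates: np.ndarray
    topology: BeadTopology

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (self.topology.n_beads, 3):
            raise TopologyError(
                f"expected coordinates of shape {(self.topology.n_beads, 3)}, "
                f"got {self.coordinates.shape}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise TopologyError("coordinates must be finite")

    def copy(self) -> "StructureModel":
        return StructureModel(self.coordinates.copy(), self.topology)


def bead_radius(n_residues: int) -> float:
    """Radius (Å) of a sphere with the volume of ``n_residues`` average residues."""
    if n_residues < 1:
        raise InvalidParameterError(f"n_residues must be >= 1, got {n_residues}")
    return (3.0 * n_residues * RESIDUE_VOLUME / (4.0 * math.pi)) ** (1.0 / 3.0)


def build_representation(chains: list[ChainSpec], residues_per_bead: int) -> BeadTopology:
    """Coarse-grain ``chains`` into beads of ``residues_per_bead`` residues each.

    Per chain, beads cover consecutive residue blocks of ``residues_per_bead``
    residues; a final smaller bead absorbs any remainder.  Rigid-body labels
    propagate from chains to their beads.
    """
    if residues_per_bead < 1:
        raise InvalidParameterError(
            f"residues_per_bead must be >= 1, got {residues_per_bead}"
        )
    seen: set[str] = set()
    for c in chains:
        if c.chain_id in seen:
            raise TopologyError(f"duplicate chain_id {c.chain_id!r}")
        seen.add(c.chain_id)

    beads: list[Bead] = []
    rigid_bodies: dict[str, list[int]] = {}
    for c in chains:
        flexible = c.rigid_body is None
        for start in range(1, c.length + 1, residues_per_bead):
            end = min(start + residues_per_bead - 1, c.length)
            beads.append(
                Bead(
                    chain_id=c.chain_id,
                    residue_start=start,
                    residue_end=end,
                    radius=bead_radius(end - start + 1),
                    flexible=flexible,
                )
            )
            if not flexible:
                rigid_bodies.setdefault(c.rigid_body, []).append(len(beads) - 1)
    return BeadTopology(
        beads=beads,
        residues_per_bead=residues_per_bead,
        rigid_bodies=rigid_bodies,
        chains=list(chains),
    )


def count_free_parameters(topology: BeadTopology) -> int:
    """Upper bound 3n + 6m on free parameters: n flexible beads, m rigid bodies."""
    n_flex = int(len(topology.flexible_indices))
    n_bodies = len(topology.rigid_bodies)
    return 3 * n_flex + 6 * n_bodies


# ---------------------------------------------------------------------------
# I/O: topology TSV and bead-model PDB
# ---------------------------------------------------------------------------

def read_topology_tsv(path: str | Path) -> list[ChainSpec]:
    """Read a topology TSV with columns chain_id, length, rigid_body (empty = flexible)."""
    df = pd.read_csv(path, sep="\t", dtype={"chain_id": str, "rigid_body": str})
    required = {"chain_id", "length"}
    if not required.issubset(df.columns):
        raise TopologyError(f"topology file must have columns {sorted(required)}")
    chains = []
    for row in df.itertuples(index=False):
        rb = getattr(row, "rigid_body", None)
        if rb is None or (isinstance(rb, float) and math.isnan(rb)) or rb == "":
            rb = None
        chains.append(ChainSpec(chain_id=str(row.chain_id), length=int(row.length), rigid_body=rb))
    return chains


def write_topology_tsv(chains: list[ChainSpec], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chain_id": [c.chain_id for c in chains],
            "length": [c.length for c in chains],
            "rigid_body": [c.rigid_body or "" for c in chains],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_bead_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a bead model as PDB HETATM pseudo-atoms.

    One carbon pseudo-atom per bead; occupancy 1.00, B-factor = bead radius,
    residue number = the bead's first residue.  Chain ids longer than one
    character are truncated to their first character (PDB column limit).
    """
    lines = []
    for serial, (bead, xyz) in enumerate(zip(model.topology.beads, model.coordinates), start=1):
        lines.append(
            f"HETATM{serial:5d}  C   BEA {bead.chain_id[:1]}{bead.residue_start:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{bead.radius:6.2f}"
            f"          {'C':>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
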