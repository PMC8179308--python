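"""Domain types and periodic geometry for biphasic-slab trajectories.

Units are Å for length, ps for time, kcal/mol for energy, and Kelvin for
temperature throughout the package.  Boxes are orthorhombic with per-axis
periodicity flags; molecule identity is positional (record order) and
constant across the frames of a trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

# Atom roles used by the hydrogen-bond and orientation definitions.
WATER_O = "water_O"
WATER_H = "water_H"
HYDROXYL_O = "hydroxyl_O"
HYDROXYL_H = "hydroxyl_H"
CHAIN_C = "chain_C"
TERMINAL_C = "terminal_C"
OTHER = "other"

ROLES = frozenset(
    {WATER_O, WATER_H, HYDROXYL_O, HYDROXYL_H, CHAIN_C, TERMINAL_C, OTHER}
)

WATER = "water"
OCTANOL = "octanol"

#: roles that carry a molecule's hydrogen-bonding oxygen
_KEY_O_ROLES = (WATER_O, HYDROXYL_O)
#: roles that carry a donatable (covalent O–H) hydrogen
_DONOR_H_ROLES = (WATER_H, HYDROXYL_H)


@dataclass
class Atom:
    """A typed point particle.  ``role`` drives all geometric criteria."""

    id: int
    element: str
    role: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.id}: non-finite position")
        if self.role not in ROLES:
            raise ValueError(f"atom {self.id}: unknown role {self.role!r}")


@dataclass
class Molecule:
    id: int
    species: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if self.species not in (WATER, OCTANOL):
            raise ValueError(f"molecule {self.id}: unknown species {self.species!r}")
        roles = [a.role for a in self.atoms]
        if self.species == WATER and roles.count(WATER_O) != 1:
            raise ValueError(f"water molecule {self.id} must have exactly one water_O")
        if self.species == OCTANOL:
            for need in (HYDROXYL_O, HYDROXYL_H, TERMINAL_C):
                if roles.count(need) != 1:
                    raise ValueError(
                        f"octanol molecule {self.id} must have exactly one {need}"
                    )

    def atom_with_role(self, role: str) -> Atom:
        for a in self.atoms:
            if a.role == role:
                return a
        raise KeyError(f"molecule {self.id} has no atom with role {role!r}")

    @property
    def key_oxygen(self) -> Atom:
        """The hydrogen-bonding oxygen (water_O or hydroxyl_O)."""
        for a in self.atoms:
            if a.role in _KEY_O_ROLES:
                return a
        raise KeyError(f"molecule {self.id} lacks an O role")

    @property
    def donor_hydrogens(self) -> list[Atom]:
        return [a for a in self.atoms if a.role in _DONOR_H_ROLES]


@dataclass(frozen=True)
class Box:
    Lx: float
    Ly: float
    Lz: float
    periodicity: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self) -> None:
        if min(self.Lx, self.Ly, self.Lz) <= 0:
            raise ValueError("box lengths must be positive")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.Lx, self.Ly, self.Lz])

    @property
    def periodic_mask(self) -> np.ndarray:
        return np.array(self.periodicity, dtype=bool)


@dataclass
class Frame:
    time: float
    molecules: list[Molecule]
    box: Box

    def __len__(self) -> int:
        return len(self.molecules)

    def molecule(self, mol_id: int) -> Molecule:
        for m in self.molecules:
            if m.id == mol_id:
                return m
        raise KeyError(mol_id)

    # ---- vectorized accessors -------------------------------------------
    def key_oxygens(self, mol_ids: Iterable[int] | None = None):
        """(ids, positions) of each molecule's H-bonding oxygen."""
        wanted = None if mol_ids is None else set(mol_ids)
        ids, pos = [], []
        for m in self.molecules:
            if wanted is not None and m.id not in wanted:
                continue
            ids.append(m.id)
            pos.append(m.key_oxygen.position)
        return np.array(ids, dtype=int), (
            np.array(pos) if pos else np.empty((0, 3))
        )

    def positions_of_role(self, role: str):
        """(molecule ids, positions) for every atom with the given role."""
        ids, pos = [], []
        for m in self.molecules:
            for a in m.atoms:
                if a.role == role:
                    ids.append(m.id)
                    pos.append(a.position)
        return np.array(ids, dtype=int), (
            np.array(pos) if pos else np.empty((0, 3))
        )


@dataclass
class Trajectory:
    frames: list[Frame]
    sampling_interval: float

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        counts = {len(f.molecules) for f in self.frames}
        if len(counts) > 1:
            raise ValueError("molecule count must be constant across frames")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


# ---------------------------------------------------------------------------
# periodic geometry


def minimum_image(a, b, box: Box) -> np.ndarray:
    """Minimum-image displacement ``b - a`` under the box's periodicity.

    Each periodic component of the result lies in [-L/2, L/2).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite input to minimum_image")
    d = b - a
    L = box.lengths
    per = box.periodic_mask
    d = np.where(per, d - L * np.floor(d / L + 0.5), d)
    return d


def minimum_image_displacements(A, B, box: Box) -> np.ndarray:
    """Vectorized pairwise displacements B[j] - A[i] → (len(A), len(B), 3)."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    d = B[None, :, :] - A[:, None, :]
    L = box.lengths
    per = box.periodic_mask
    shifted = d - L * np.floor(d / L + 0.5)
    return np.where(per, shifted, d)


def wrap_positions(positions, box: Box) -> np.ndarray:
    pos = np.asarray(positions, dtype=float)
    L = box.lengths
    per = box.periodic_mask
    return np.where(per, pos - L * np.floor(pos / L), pos)


def wrap(frame: Frame) -> Frame:
    """Return a copy of ``frame`` with all positions in the primary cell.

    Idempotent; minimum-image pair distances are unchanged.
    """
    new_mols = []
    for m in frame.molecules:
        new_atoms = [
            Atom(a.id, a.element, a.role, wrap_positions(a.position, frame.box))
            for a in m.atoms
        ]
        new_mols.append(Molecule(m.id, m.species, new_atoms))
    return Frame(frame.time, new_mols, frame.box)
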