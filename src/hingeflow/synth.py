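"""Synthetic water/octanol fixtures with known ground truth.

Real input to this pipeline is MD output; every analysis stage here can
instead be exercised on generated configurations:

* ``gen_slab`` — a biphasic slab with a (optionally corrugated) interface,
  Layer-1 octanols planted head-toward-water at a 45° mean tilt, Layer-2
  bilayer islands with attached waters, penetrated waters deep in the
  organic phase, and a bulk octanol region.  Ground-truth labels for every
  planted feature are returned alongside the frame.
* ``gen_event_trajectory`` — scripted transport events (diffusion, flip,
  hinge) in isolated xy cells, with molecules moving along smooth rigid
  paths, plus the ground-truth event table.  Region labels for these
  scenes come from fixed z bands (``assignment_from_zbands``).
* ``gen_pressure_series`` — a stationary pressure-tensor series with
  prescribed mean anisotropy.
* ``gen_rate_event_stream`` — Poisson event streams at planted Arrhenius
  rates for rate/barrier recovery tests.

Octanol is generated as a 10-site chain (hydroxyl O, hydroxyl H, 8 C at
1.5 Å spacing) in the elongated linear conformation; waters are 3-site.
All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import (
    Atom,
    Box,
    CHAIN_C,
    Frame,
    HYDROXYL_H,
    HYDROXYL_O,
    Molecule,
    OCTANOL,
    TERMINAL_C,
    Trajectory,
    WATER,
    WATER_H,
    WATER_O,
)
from .events import DIFFUSION, FLIP, HINGE, TransportEvent
from .hbond import MoleculeCluster
from .layers import (
    BULK_OCTANOL,
    BULK_WATER,
    LAYER1,
    LAYER2,
    LayerAssignment,
    WATER_SURFACE,
)
from .thermo import PressureSeries

OH_BOND = 0.96  # Å
CC_BOND = 1.5  # Å
N_CHAIN = 8
CHAIN_LENGTH = CC_BOND * N_CHAIN  # 12 Å


class _Builder:
    """Accumulates molecules with globally unique atom/molecule ids."""

    def __init__(self) -> None:
        self.molecules: list[Molecule] = []
        self._atom_id = 0
        self._mol_id = 0

    def _atom(self, element, role, pos) -> Atom:
        a = Atom(self._atom_id, element, role, np.asarray(pos, dtype=float))
        self._atom_id += 1
        return a

    def water(self, o_pos, h_dir1=None, rng=None) -> int:
        o_pos = np.asarray(o_pos, dtype=float)
        if h_dir1 is None:
            h_dir1 = _random_unit(rng)
        h_dir1 = np.asarray(h_dir1, dtype=float)
        h_dir1 = h_dir1 / np.linalg.norm(h_dir1)
        perp = _any_perpendicular(h_dir1, rng)
        ang = math.radians(104.5)
        h_dir2 = math.cos(ang) * h_dir1 + math.sin(ang) * perp
        atoms = [
            self._atom("O", WATER_O, o_pos),
            self._atom("H", WATER_H, o_pos + OH_BOND * h_dir1),
            self._atom("H", WATER_H, o_pos + OH_BOND * h_dir2),
        ]
        m = Molecule(self._mol_id, WATER, atoms)
        self._mol_id += 1
        self.molecules.append(m)
        return m.id

    def octanol(self, o_pos, h_dir, chain_dir) -> int:
        """10-site elongated octanol: O, H along h_dir, C1..C8 along chain_dir."""
        o_pos = np.asarray(o_pos, dtype=float)
        h_dir = np.asarray(h_dir, dtype=float)
        h_dir = h_dir / np.linalg.norm(h_dir)
        u = np.asarray(chain_dir, dtype=float)
        u = u / np.linalg.norm(u)
        atoms = [
            self._atom("O", HYDROXYL_O, o_pos),
            self._atom("H", HYDROXYL_H, o_pos + OH_BOND * h_dir),
        ]
        for k in range(1, N_CHAIN + 1):
            role = TERMINAL_C if k == N_CHAIN else CHAIN_C
            atoms.append(self._atom("C", role, o_pos + k * CC_BOND * u))
        m = Molecule(self._mol_id, OCTANOL, atoms)
        self._mol_id += 1
        self.molecules.append(m)
        return m.id


def _random_unit(rng) -> np.ndarray:
    if rng is None:
        rng = np.random.default_rng()
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _any_perpendicular(v, rng=None) -> np.ndarray:
    ref = _random_unit(rng) if rng is not None else np.array([0.0, 0.0, 1.0])
    p = ref - np.dot(ref, v) * v
    n = np.linalg.norm(p)
    if n < 1e-8:
        ref = np.array([1.0, 0.0, 0.0])
        p = ref - np.dot(ref, v) * v
        n = np.linalg.norm(p)
    return p / n


# ---------------------------------------------------------------------------
# static slab


@dataclass
class SlabSpec:
    box: Box = field(default_factory=lambda: Box(40.0, 40.0, 80.0, (True, True, False)))
    interface_z: float = 28.0  # mean water/octanol boundary
    water_spacing: float = 3.1  # Å, aqueous lattice constant
    roughness_amplitude: float = 0.0  # Å
    roughness_wavelength: float = 20.0  # Å
    layer1_stride: int = 2  # one Layer-1 octanol per this many surface sites
    island_sizes: tuple[int, ...] = (4, 4, 5)
    island_water_slope: float = 0.5  # waters per island octanol
    island_head_depth: float = 26.0  # hydroxyl height above the water top
    n_penetrated: int = 1
    penetration_depth: float = 16.0  # Å past the boundary (≥ 15)
    n_bulk_octanol: int = 12
    bulk_octanol_depth: float = 34.0  # hydroxyl height above the water top
    jitter: float = 0.08  # Å, positional noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.roughness_amplitude >= self.interface_z / 2:
            raise ValueError("roughness amplitude exceeds half slab thickness")
        if self.penetration_depth < 15.0:
            raise ValueError("penetrated waters must sit ≥ 15 Å past the boundary")


@dataclass
class SlabTruth:
    """Ground-truth labels for a generated slab."""

    surface_waters: frozenset[int]
    layer1_octanols: frozenset[int]
    islands: list[tuple[frozenset[int], frozenset[int]]]  # (octanols, waters)
    penetrated_waters: frozenset[int]
    bulk_octanols: frozenset[int]
    interface_z: float

    @property
    def layer2_octanols(self) -> frozenset[int]:
        return frozenset().union(*(o for o, _ in self.islands)) if self.islands else frozenset()

    @property
    def layer2_waters(self) -> frozenset[int]:
        return frozenset().union(*(w for _, w in self.islands)) if self.islands else frozenset()


def gen_slab(spec: SlabSpec) -> tuple[Frame, SlabTruth]:
    """Build one frame of a biphasic slab with planted interfacial structure.

    Waters fill a jittered lattice from z = 2 up to the (sinusoidal)
    boundary; the topmost water of each lattice column is the ground-truth
    surface water.  Layer-1 octanols stand on every ``layer1_stride``-th
    surface site, hydrogen-bonded to their surface water, with end-to-end
    vectors at 45° to the normal.  Layer-2 islands hang ``island_head_depth``
    above the boundary with hydroxyls toward the organic phase and their
    attached waters H-bonded in; bulk octanols lie flat higher up.
    """
    rng = np.random.default_rng(spec.seed)
    b = _Builder()
    box = spec.box
    # stretch the lattice so columns tile the periodic cell exactly
    nx = max(1, int(round(box.Lx / spec.water_spacing)))
    ny = max(1, int(round(box.Ly / spec.water_spacing)))
    ax = box.Lx / nx
    ay = box.Ly / ny
    a = spec.water_spacing

    def boundary(x):
        return spec.interface_z + spec.roughness_amplitude * math.sin(
            2 * math.pi * x / spec.roughness_wavelength
        )

    # --- aqueous lattice, column by column
    surface_ids = []
    surface_sites = []  # (x, y, z_top) of each surface water
    for i in range(nx):
        for j in range(ny):
            x = (i + 0.5) * ax
            y = (j + 0.5) * ay
            z_top_allowed = boundary(x)
            n_levels = int((z_top_allowed - 2.0) // a)
            top_id = None
            top_z = None
            for k in range(n_levels):
                z = 2.0 + k * a
                pos = np.array([x, y, z]) + rng.normal(0, spec.jitter, 3)
                is_top = k == n_levels - 1
                h1 = np.array([0.0, 0.0, 1.0]) if is_top else None
                wid = b.water(pos, h_dir1=h1, rng=rng)
                if is_top:
                    top_id, top_z = wid, pos[2]
            if top_id is not None:
                surface_ids.append(top_id)
                surface_sites.append((x, y, top_z))

    # heights of planted organic-phase features are measured from the
    # actual instantaneous water top, not the nominal boundary
    z_top_mean = float(np.mean([s[2] for s in surface_sites]))

    # --- Layer-1 octanols on strided surface sites
    layer1_ids = []
    tilt = math.radians(45.0)
    for idx, (x, y, z_top) in enumerate(surface_sites):
        i, j = idx // ny, idx % ny
        if i % spec.layer1_stride or j % spec.layer1_stride:
            continue
        o_pos = np.array([x, y, z_top + 2.8])
        # all chains tilt in the same (+x) azimuth: parallel tails pack
        # without clashes, as in an ordered monolayer
        axis = np.array([math.sin(tilt), 0.0, math.cos(tilt)])
        # hydroxyl H anti-parallel to the chain so the end-to-end (H→C8)
        # vector is exactly the 45° axis; the HB comes from the surface
        # water donating upward.
        layer1_ids.append(b.octanol(o_pos, h_dir=-axis, chain_dir=axis))

    # --- Layer-2 bilayer islands
    islands = []
    n_isl = len(spec.island_sizes)
    for isl_idx, size in enumerate(spec.island_sizes):
        cx = (isl_idx + 0.5) * box.Lx / max(n_isl, 1)
        cy = box.Ly / 2
        z_head = z_top_mean + spec.island_head_depth
        oct_ids = []
        # compact two-column packing keeps islands well separated from
        # each other while every O-O neighbour distance stays ≤ 3 Å
        offsets = [((k % 2) * 3.0 - 1.5, (k // 2) * 3.0 - 1.5) for k in range(size)]
        for dx, dy in offsets:
            o_pos = np.array([cx + dx, cy + dy, z_head]) + rng.normal(
                0, spec.jitter, 3
            )
            # tails hang straight down, meeting the Layer-1 tails end-to-end
            down = np.array([0.0, 0.0, -1.0])
            oct_ids.append(b.octanol(o_pos, h_dir=np.array([0.0, 0.0, 1.0]), chain_dir=down))
        n_wat = max(1, round(spec.island_water_slope * size))
        wat_ids = []
        for k in range(n_wat):
            host = b.molecules[[m.id for m in b.molecules].index(oct_ids[k % size])]
            host_o = host.atom_with_role(HYDROXYL_O).position
            w_pos = host_o + np.array([0.0, 0.0, 2.8])
            # water donates down into the island hydroxyl O
            wat_ids.append(b.water(w_pos, h_dir1=(host_o - w_pos), rng=rng))
        islands.append((frozenset(oct_ids), frozenset(wat_ids)))

    # --- penetrated waters, far from islands in xy
    penetrated = []
    for k in range(spec.n_penetrated):
        x = (k + 0.5) * box.Lx / max(spec.n_penetrated, 1)
        y = box.Ly * 0.15
        z = z_top_mean + spec.penetration_depth + k * 1.3
        penetrated.append(b.water(np.array([x, y, z]), rng=rng))

    # --- bulk octanol, lying flat well above the Layer-2 depth bound
    bulk = []
    n_side = max(1, int(math.ceil(math.sqrt(spec.n_bulk_octanol))))
    pitch_x = box.Lx / n_side
    pitch_y = box.Ly / n_side
    count = 0
    for i in range(n_side):
        for j in range(n_side):
            if count >= spec.n_bulk_octanol:
                break
            x = (i + 0.5) * pitch_x
            y = (j + 0.5) * pitch_y
            z = z_top_mean + spec.bulk_octanol_depth + (count % 3) * 3.0
            flat = np.array([1.0, 0.0, 0.0])
            bulk.append(
                b.octanol(np.array([x, y, z]), h_dir=np.array([0.0, 0.0, 1.0]), chain_dir=flat)
            )
            count += 1

    frame = Frame(0.0, b.molecules, box)
    _check_heavy_overlaps(frame)
    truth = SlabTruth(
        surface_waters=frozenset(surface_ids),
        layer1_octanols=frozenset(layer1_ids),
        islands=islands,
        penetrated_waters=frozenset(penetrated),
        bulk_octanols=frozenset(bulk),
        interface_z=spec.interface_z,
    )
    return frame, truth


def _check_heavy_overlaps(frame: Frame, min_dist: float = 2.0) -> None:
    """Error on intermolecular heavy-atom (O, C) contacts below min_dist."""
    pos, mol_of = [], []
    for m in frame.molecules:
        for a in m.atoms:
            if a.element != "H":
                pos.append(a.position)
                mol_of.append(m.id)
    pos = np.asarray(pos)
    mol_of = np.asarray(mol_of)
    tree = cKDTree(pos)
    for i, j in tree.query_pairs(min_dist):
        if mol_of[i] != mol_of[j]:
            raise ValueError(
                f"overfilled box: molecules {mol_of[i]} and {mol_of[j]} "
                f"have heavy atoms closer than {min_dist} Å"
            )


# ---------------------------------------------------------------------------
# scripted event trajectories


@dataclass
class ZBands:
    """Region boundaries for scripted scenes (labels from the key-O z)."""

    bulk_water_top: float = 6.0
    surface_top: float = 12.0
    layer1_top: float = 24.0
    layer2_top: float = 36.0

    def region(self, z: float, species: str) -> str:
        if z < self.bulk_water_top:
            return BULK_WATER if species == WATER else BULK_OCTANOL
        if z < self.surface_top:
            return WATER_SURFACE if species == WATER else LAYER1
        if z < self.layer1_top:
            return LAYER1
        if z < self.layer2_top:
            return LAYER2
        return BULK_OCTANOL


def assignment_from_zbands(frame: Frame, bands: ZBands) -> LayerAssignment:
    regions = {}
    for m in frame.molecules:
        z = float(m.key_oxygen.position[2])
        regions[m.id] = bands.region(z, m.species)
    return LayerAssignment(frame.time, regions)


@dataclass
class PlantedEvent:
    mechanism: str  # diffusion | flip | hinge
    direction: str  # "L1→L2" or "L2→L1"
    t_start: float  # ps
    duration: float  # ps
    n_oct: int
    m_water: int

    def __post_init__(self) -> None:
        if self.mechanism == DIFFUSION and self.n_oct != 0:
            raise ValueError("diffusion events carry no octanol")
        if self.mechanism == FLIP and self.n_oct != 1:
            raise ValueError("flip events carry exactly one octanol")
        if self.mechanism == HINGE and self.n_oct < 2:
            raise ValueError("hinge events need at least two octanols")
        if self.mechanism in (DIFFUSION, HINGE) and self.m_water < 1:
            raise ValueError(f"{self.mechanism} events must transfer ≥ 1 water")


@dataclass
class EventScript:
    events: list[PlantedEvent]


@dataclass
class EventTruth:
    mechanism: str
    direction: str
    water_ids: frozenset[int]
    octanol_ids: frozenset[int]
    t_start: float
    t_end: float


_CELL = 16.0  # Å, xy pitch between independent event sites


def gen_event_trajectory(
    script: EventScript,
    sampling: float = 10.0,
    n_background: int = 6,
    jitter: float = 0.05,
    seed: int = 0,
    bands: ZBands | None = None,
) -> tuple[Trajectory, list[EventTruth], ZBands]:
    """Scripted smooth-motion trajectory with ground-truth event table.

    Each planted event lives in its own xy cell.  Hinge carriers rotate
    rigidly about a pivot in the Layer-1/Layer-2 boundary plane (the
    door-hinge swing); flips rotate a single elongated octanol about its
    centre; diffusing waters translate across the boundary with no octanol
    within hydrogen-bonding reach.  Background molecules only jitter.
    Region labels for the scene follow the fixed z bands returned
    alongside.
    """
    bands = bands or ZBands()
    rng = np.random.default_rng(seed)
    n_cells = len(script.events) + n_background
    n_side = max(2, int(math.ceil(math.sqrt(n_cells))))
    box = Box(n_side * _CELL, n_side * _CELL, 60.0, (True, True, False))
    z_boundary = bands.layer1_top  # L1/L2 boundary the events cross

    t_end_max = max((e.t_start + e.duration for e in script.events), default=0.0)
    n_frames = int(round(t_end_max / sampling)) + 3
    times = np.arange(n_frames) * sampling

    def cell_centre(idx):
        return ((idx % n_side) + 0.5) * _CELL, ((idx // n_side) + 0.5) * _CELL

    # --- build the reference (t = 0) configuration and motion closures
    b = _Builder()
    movers = []  # (mol_id, fn(t) -> offset applied to all atoms) OR rotators
    truths: list[EventTruth] = []

    def ease(t, t0, dur):
        tau = min(max((t - t0) / dur, 0.0), 1.0)
        return 0.5 * (1.0 - math.cos(math.pi * tau))

    rotations = []  # (atom selector, pivot, axis-angle fn)

    mol_paths: dict[int, object] = {}  # mol id → callable(t, base_atoms)->positions

    for idx, ev in enumerate(script.events):
        cx, cy = cell_centre(idx)
        fwd = ev.direction == "L1→L2"
        sgn0 = -1.0 if fwd else 1.0  # start below (L1) or above (L2)

        if ev.mechanism == DIFFUSION:
            z0 = z_boundary - 6.0 if fwd else z_boundary + 6.0
            z1 = z_boundary + 6.0 if fwd else z_boundary - 6.0
            wid = b.water(np.array([cx, cy, z0]), rng=rng)

            def path(t, base, z0=z0, z1=z1, ev=ev):
                dz = (z1 - z0) * ease(t, ev.t_start, ev.duration)
                return base + np.array([0.0, 0.0, dz])

            mol_paths[wid] = path
            truths.append(
                EventTruth(
                    DIFFUSION, ev.direction, frozenset({wid}), frozenset(),
                    ev.t_start, ev.t_start + ev.duration,
                )
            )

        elif ev.mechanism == FLIP:
            centre = np.array([cx, cy, z_boundary])
            r_hat0 = np.array([0.0, 0.0, sgn0])  # O starts in the source layer
            oid = b.octanol(
                centre + 6.0 * r_hat0,
                h_dir=r_hat0,
                chain_dir=-r_hat0,
            )
            wid = None
            if ev.m_water >= 1:
                w_pos = centre + 8.8 * r_hat0
                wid = b.water(w_pos, h_dir1=-r_hat0, rng=rng)

            def rot(t, base, centre=centre, ev=ev, sgn0=sgn0):
                # rotate all atoms about the centre in the y-z plane
                ang = sgn0 * math.pi * ease(t, ev.t_start, ev.duration)
                rel = base - centre
                c, s = math.cos(ang), math.sin(ang)
                out = rel.copy()
                out[:, 1] = rel[:, 1] * c - rel[:, 2] * s
                out[:, 2] = rel[:, 1] * s + rel[:, 2] * c
                return centre + out

            mol_paths[oid] = rot
            if wid is not None:
                mol_paths[wid] = rot
                truths.append(
                    EventTruth(
                        FLIP, ev.direction, frozenset({wid}), frozenset({oid}),
                        ev.t_start, ev.t_start + ev.duration,
                    )
                )

        else:  # HINGE
            pivot = np.array([cx, cy, z_boundary])
            span = ev.n_oct + ev.m_water
            members = []
            alpha0 = -math.pi / 2 if fwd else math.pi / 2
            centre0 = pivot + 7.0 * np.array(
                [0.0, math.cos(alpha0), math.sin(alpha0)]
            )
            oct_ids, wat_ids = [], []
            for k in range(span):
                off = np.array([(k - (span - 1) / 2) * 2.8, 0.0, 0.0])
                if k < ev.n_oct:
                    oct_ids.append(
                        b.octanol(
                            centre0 + off,
                            h_dir=np.array([0.0, 0.0, 1.0]),
                            chain_dir=np.array([0.0, 1.0, 0.0]),
                        )
                    )
                else:
                    wat_ids.append(b.water(centre0 + off, rng=rng))
            members = oct_ids + wat_ids

            def swing(t, base, pivot=pivot, ev=ev, fwd=fwd):
                ang = math.pi * ease(t, ev.t_start, ev.duration)
                if not fwd:
                    ang = -ang
                rel = base - pivot
                c, s = math.cos(ang), math.sin(ang)
                out = rel.copy()
                out[:, 1] = rel[:, 1] * c - rel[:, 2] * s
                out[:, 2] = rel[:, 1] * s + rel[:, 2] * c
                return pivot + out

            for mid in members:
                mol_paths[mid] = swing
            truths.append(
                EventTruth(
                    HINGE, ev.direction, frozenset(wat_ids), frozenset(oct_ids),
                    ev.t_start, ev.t_start + ev.duration,
                )
            )

    # --- static background molecules spread over the remaining cells
    bg_templates = [
        (WATER, 3.0),  # bulk water
        (WATER, 9.0),  # surface
        (OCTANOL, 18.0),  # layer1
        (OCTANOL, 30.0),  # layer2
        (OCTANOL, 45.0),  # bulk octanol
        (WATER, 3.5),
    ]
    for k in range(n_background):
        cx, cy = cell_centre(len(script.events) + k)
        species, z = bg_templates[k % len(bg_templates)]
        if species == WATER:
            b.water(np.array([cx, cy, z]), rng=rng)
        else:
            b.octanol(
                np.array([cx, cy, z]),
                h_dir=np.array([0.0, 0.0, 1.0]),
                chain_dir=np.array([1.0, 0.0, 0.0]),
            )

    base_atoms = {
        m.id: np.array([a.position for a in m.atoms]) for m in b.molecules
    }

    frames = []
    for t in times:
        mols = []
        atom_id = 0
        for m in b.molecules:
            base = base_atoms[m.id]
            pos = mol_paths[m.id](t, base) if m.id in mol_paths else base
            pos = pos + rng.normal(0.0, jitter, pos.shape)
            atoms = []
            for a, p in zip(m.atoms, pos):
                atoms.append(Atom(atom_id, a.element, a.role, p))
                atom_id += 1
            mols.append(Molecule(m.id, m.species, atoms))
        frames.append(Frame(float(t), mols, box))
    traj = Trajectory(frames, sampling)
    return traj, truths, bands


# ---------------------------------------------------------------------------
# pressure series and rate streams


def gen_pressure_series(
    mean_anisotropy: float,
    noise_sd: float,
    n: int,
    L_z: float,
    seed: int = 0,
    base_pressure: float = 1.0,
    dt: float = 10.0,
    N_int: int = 2,
) -> PressureSeries:
    """Gaussian pressure-tensor series with prescribed mean
    P_zz − (P_xx + P_yy)/2."""
    if n < 3:
        raise ValueError("need n ≥ 3 samples")
    rng = np.random.default_rng(seed)
    times = np.arange(n) * dt
    pxx = base_pressure + rng.normal(0, noise_sd, n)
    pyy = base_pressure + rng.normal(0, noise_sd, n)
    pzz = base_pressure + mean_anisotropy + rng.normal(0, noise_sd, n)
    return PressureSeries(times, pxx, pyy, pzz, L_z, N_int)


def gen_rate_event_stream(
    A: float,
    Ea_fwd: float,
    Ea_rev: float,
    duration: float,
    T: float = 300.0,
    seed: int = 0,
    n_oct: int = 2,
    m_water: int = 1,
) -> list[TransportEvent]:
    """Poisson hinge-event streams at planted Arrhenius rates.

    Forward (L1→L2) events arrive at rate A·exp(−Ea_fwd/RT) per ps and the
    reverse at A·exp(−Ea_rev/RT); every event transfers ``m_water`` waters
    in an (oct)_n(H2O)_m carrier.  With unit layer concentrations the
    planted barriers are recoverable exactly through the Arrhenius
    relation.
    """
    from .events import R_KCAL

    rng = np.random.default_rng(seed)
    events: list[TransportEvent] = []
    next_id = 0
    for direction, ea in (("L1→L2", Ea_fwd), ("L2→L1", Ea_rev)):
        rate = A * math.exp(-ea / (R_KCAL * T))  # waters per ps
        event_rate = rate / m_water
        t = 0.0
        while True:
            t += rng.exponential(1.0 / event_rate)
            if t >= duration:
                break
            wat = frozenset(range(next_id, next_id + m_water))
            next_id += m_water
            octs = frozenset(range(next_id, next_id + n_oct))
            next_id += n_oct
            events.append(
                TransportEvent(
                    water_ids=wat,
                    direction=direction,
                    t_start=t,
                    t_end=t,
                    carrier=MoleculeCluster(wat | octs, (n_oct, m_water), t),
                    mechanism=HINGE,
                )
            )
    events.sort(key=lambda e: e.t_start)
    return events
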