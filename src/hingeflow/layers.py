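"""Region assignment and in-plane/out-of-plane structure of the interface.

Five regions partition every frame of a water/octanol slab: bulk water, the
instantaneous water surface, Layer-1 (octanols at the instantaneous surface
with hydroxyls toward water, plus their H-bonded waters), Layer-2 (the
second, semi-organised octanol layer with hydroxyls toward the organic
phase, plus its waters), and bulk octanol.  The module also provides the
standard structural observables for those layers: orientation and density
profiles along z, 2D radial distribution functions, the excess coordination
number, surface packing density, and bilayer-island detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .core import (
    Frame,
    HYDROXYL_H,
    HYDROXYL_O,
    OCTANOL,
    TERMINAL_C,
    Trajectory,
    WATER,
    minimum_image_displacements,
)
from .hbond import HBGraph, MoleculeCluster, find_clusters
from .surfaces import (
    ItimParams,
    SurfaceSet,
    interfacial_octanols,
    itim_layer,
    split_penetrated_waters,
)

BULK_WATER = "bulk_water"
WATER_SURFACE = "water_surface"
LAYER1 = "layer1"
LAYER2 = "layer2"
BULK_OCTANOL = "bulk_octanol"
REGIONS = (BULK_WATER, WATER_SURFACE, LAYER1, LAYER2, BULK_OCTANOL)


@dataclass
class LayerAssignment:
    frame_time: float
    regions: dict[int, str]

    def members(self, region: str) -> frozenset[int]:
        return frozenset(i for i, r in self.regions.items() if r == region)

    def __getitem__(self, mol_id: int) -> str:
        return self.regions[mol_id]


@dataclass
class OrientationRecord:
    molecule_id: int
    cos_theta: float
    z_bin: float


@dataclass
class Rdf2d:
    r: np.ndarray
    g: np.ndarray
    density: float  # molecules / Å^2


@dataclass
class EcnCurve:
    r: np.ndarray
    n_excess: np.ndarray


@dataclass
class BilayerIsland:
    cluster: MoleculeCluster

    @property
    def octanol_count(self) -> int:
        return self.cluster.composition[0]

    @property
    def water_count(self) -> int:
        return self.cluster.composition[1]


def octanol_axis(mol) -> np.ndarray | None:
    """Unit end-to-end vector, hydroxyl H → terminal C (None if degenerate)."""
    v = mol.atom_with_role(TERMINAL_C).position - mol.atom_with_role(
        HYDROXYL_H
    ).position
    n = np.linalg.norm(v)
    if n == 0:
        return None
    return v / n


def assign_layers(
    frame: Frame,
    hbgraph: HBGraph,
    itim_params: ItimParams | None = None,
    dbscan_eps: float = 3.5,
    dbscan_min_samples: int = 3,
    layer2_max_depth: float = 28.0,
    cluster_cutoff: float = 3.5,
) -> LayerAssignment:
    """Assign every molecule of a frame to one of the five regions.

    Procedure: (1) DBSCAN separates penetrated waters from the aqueous
    phase; (2) ITIM on the aqueous waters gives the instantaneous water
    surface; (3) Layer-1 octanols are those H-bonded to a surface water;
    (4) a second ITIM pass over the remaining octanols, approached from the
    water side, proposes Layer-2 candidates, kept when their hydroxyl
    points toward the organic phase and their head group lies within
    ``layer2_max_depth`` of the mean surface-water height; (5) waters
    H-bonded to Layer-1/Layer-2 octanols inherit that label (majority rule,
    ties to Layer-1); everything else is bulk by species.
    """
    water_ids = [m.id for m in frame.molecules if m.species == WATER]
    oct_ids = [m.id for m in frame.molecules if m.species == OCTANOL]
    if not water_ids or not oct_ids:
        raise ValueError("layer assignment needs both water and octanol")

    # which side of the water slab the organic phase sits on
    _, w_pos = frame.key_oxygens(water_ids)
    _, o_pos = frame.key_oxygens(oct_ids)
    organic_up = o_pos[:, 2].mean() > w_pos[:, 2].mean()

    aqueous, penetrated = split_penetrated_waters(
        frame, hbgraph, eps=dbscan_eps, min_samples=dbscan_min_samples
    )
    params = itim_params or ItimParams()
    water_params = ItimParams(
        probe_radius=params.probe_radius,
        grid_spacing=params.grid_spacing,
        atomic_radii=params.atomic_radii,
        direction="+z" if organic_up else "-z",
    )
    surface = itim_layer(frame, aqueous, water_params)
    layer1_oct = interfacial_octanols(frame, surface, hbgraph)

    # second ITIM pass for Layer-2, probes arriving from the water side
    remaining_oct = [i for i in oct_ids if i not in layer1_oct]
    layer2_oct: set[int] = set()
    if remaining_oct:
        oct_params = ItimParams(
            probe_radius=params.probe_radius,
            grid_spacing=params.grid_spacing,
            atomic_radii=params.atomic_radii,
            direction="-z" if organic_up else "+z",
        )
        candidates = itim_layer(frame, remaining_oct, oct_params).molecule_ids
        surf_ids, surf_pos = frame.key_oxygens(surface.molecule_ids)
        z_surface = float(surf_pos[:, 2].mean()) if len(surf_ids) else float(
            w_pos[:, 2].max() if organic_up else w_pos[:, 2].min()
        )
        sign = 1.0 if organic_up else -1.0
        for i in candidates:
            mol = frame.molecule(i)
            axis = octanol_axis(mol)
            if axis is None:
                continue
            # hydroxyl toward the organic phase == tail toward water
            if axis[2] * sign >= 0:
                continue
            depth = sign * (mol.atom_with_role(HYDROXYL_O).position[2] - z_surface)
            if depth > layer2_max_depth:
                continue
            layer2_oct.add(i)

    # waters attached to layer octanols inherit the layer label
    neighbour_layers: dict[int, list[str]] = {}
    water_set = set(water_ids)
    for d, a, _ in hbgraph.edges:
        for w, o in ((d, a), (a, d)):
            if w in water_set:
                if o in layer1_oct:
                    neighbour_layers.setdefault(w, []).append(LAYER1)
                elif o in layer2_oct:
                    neighbour_layers.setdefault(w, []).append(LAYER2)

    regions: dict[int, str] = {}
    for m in frame.molecules:
        i = m.id
        if m.species == OCTANOL:
            if i in layer1_oct:
                regions[i] = LAYER1
            elif i in layer2_oct:
                regions[i] = LAYER2
            else:
                regions[i] = BULK_OCTANOL
        else:
            if i in surface.molecule_ids:
                regions[i] = WATER_SURFACE
            elif i in neighbour_layers:
                labs = neighbour_layers[i]
                n1 = labs.count(LAYER1)
                n2 = labs.count(LAYER2)
                regions[i] = LAYER1 if n1 >= n2 else LAYER2
            else:
                regions[i] = BULK_WATER
    return LayerAssignment(frame.time, regions)


def orientation_profile(
    trajectory: Trajectory, bin_width: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean octanol end-to-end cos(theta) vs z (binned by hydroxyl O height).

    theta is measured between the hydroxyl-H → terminal-C vector and the
    +z surface normal.  Returns (bin centres, mean cos theta, counts).
    """
    zs, cts = [], []
    for frame in trajectory:
        for m in frame.molecules:
            if m.species != OCTANOL:
                continue
            axis = octanol_axis(m)
            if axis is None:
                import warnings

                warnings.warn(f"octanol {m.id}: zero-length end-to-end vector")
                continue
            zs.append(m.atom_with_role(HYDROXYL_O).position[2])
            cts.append(axis[2])
    zs = np.asarray(zs)
    cts = np.asarray(cts)
    Lz = trajectory.frames[0].box.Lz
    edges = np.arange(0.0, Lz + bin_width, bin_width)
    idx = np.clip(np.digitize(zs, edges) - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    sums = np.bincount(idx, weights=cts, minlength=len(edges) - 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return centres, means, counts


def density_profile(
    trajectory: Trajectory, role: str, bin_width: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Frame-averaged number density of atoms with ``role`` vs z (Å^-3)."""
    box = trajectory.frames[0].box
    edges = np.arange(0.0, box.Lz + bin_width, bin_width)
    hist = np.zeros(len(edges) - 1)
    for frame in trajectory:
        _, pos = frame.positions_of_role(role)
        if len(pos):
            h, _ = np.histogram(pos[:, 2], bins=edges)
            hist += h
    vol = box.Lx * box.Ly * np.diff(edges)
    rho = hist / (len(trajectory) * vol)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return centres, rho


def rdf2d(
    frames_members,
    bin_width: float = 0.1,
    r_max: float | None = None,
) -> Rdf2d:
    """2D radial distribution function of key oxygens within a planar layer.

    ``frames_members`` is a sequence of (frame, member ids).  Pair distances
    are xy-projected minimum-image distances; normalisation uses the ideal
    2D gas with per-frame density N/(Lx·Ly) and the (N-1) finite-size
    convention, so g → 1 for homogeneous input.
    """
    frames_members = list(frames_members)
    box = frames_members[0][0].box
    if r_max is None:
        r_max = min(box.Lx, box.Ly) / 2
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    annulus = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    g_acc = np.zeros(len(edges) - 1)
    rho_acc = 0.0
    n_frames = 0
    for frame, members in frames_members:
        members = list(members)
        if len(members) < 2:
            raise ValueError("rdf2d needs at least two members per frame")
        _, pos = frame.key_oxygens(members)
        disp = minimum_image_displacements(pos, pos, frame.box)
        dxy = np.linalg.norm(disp[..., :2], axis=-1)
        iu = np.triu_indices(len(pos), k=1)
        hist, _ = np.histogram(dxy[iu], bins=edges)
        N = len(pos)
        area = frame.box.Lx * frame.box.Ly
        rho_pair = (N - 1) / area
        g_acc += hist / (0.5 * N * rho_pair * annulus)
        rho_acc += N / area
        n_frames += 1
    centres = 0.5 * (edges[:-1] + edges[1:])
    return Rdf2d(centres, g_acc / n_frames, rho_acc / n_frames)


def ecn(rdf: Rdf2d) -> EcnCurve:
    """Excess coordination number N_excess(r) = ρ ∫₀^r (g−1) 2πr′ dr′.

    Positive values mean local enrichment relative to a uniform layer,
    negative values depletion.  Trapezoidal quadrature on the RDF grid,
    anchored at N_excess(0) = 0.
    """
    r = np.concatenate([[0.0], rdf.r])
    integrand = np.concatenate([[0.0], (rdf.g - 1.0) * 2 * np.pi * rdf.r])
    n_ex = rdf.density * cumulative_trapezoid(integrand, r, initial=0.0)
    return EcnCurve(r, n_ex)


def packing_density(counts, areas) -> float:
    """Mean surface packing density in molecules nm⁻² from per-frame
    (molecule count, surface area Å²) pairs."""
    counts = np.asarray(counts, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if np.any(areas <= 0):
        raise ValueError("surface area must be positive")
    return float(np.mean(counts / areas) * 100.0)  # Å^-2 → nm^-2


def find_bilayer_islands(
    assignment: LayerAssignment,
    frame: Frame,
    cutoff: float = 3.5,
    min_octanols: int = 2,
) -> list[BilayerIsland]:
    """Hydrogen-bonded octanol/water clusters within Layer-2.

    Clusters over Layer-2 members (octanols plus their attached waters)
    with the O-O proximity cutoff; only clusters with at least
    ``min_octanols`` octanols count as bilayer islands.
    """
    members = assignment.members(LAYER2)
    if not members:
        return []
    clusters = find_clusters(frame, members, cutoff=cutoff)
    return [
        BilayerIsland(c) for c in clusters if c.composition[0] >= min_octanols
    ]
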