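"""Instantaneous-interface detection for a biphasic slab.

Two complementary surface definitions are provided:

* ITIM — probe spheres descend along a grid of test lines normal to the
  interface; the molecules they touch first are the truly interfacial ones.
  A density-based cluster correction removes waters that have penetrated
  the organic phase before the probes are dropped, and octanols are counted
  as interfacial when their hydroxyl is hydrogen-bonded to an interfacial
  water.
* Willard-Chandler — an isosurface of the Gaussian coarse-grained water
  density at a fraction of the bulk density, giving a continuous surface
  and its area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from sklearn.cluster import DBSCAN

from .core import (
    Frame,
    OCTANOL,
    WATER,
    minimum_image_displacements,
)
from .hbond import HBGraph

# Bondi-type van der Waals radii (Å) by atom role.
DEFAULT_RADII = {
    "water_O": 1.52,
    "water_H": 1.10,
    "hydroxyl_O": 1.52,
    "hydroxyl_H": 1.10,
    "chain_C": 1.70,
    "terminal_C": 1.70,
    "other": 1.52,
}


@dataclass
class ItimParams:
    probe_radius: float = 1.5  # Å
    grid_spacing: float = 0.2  # Å
    atomic_radii: dict = field(default_factory=lambda: dict(DEFAULT_RADII))
    direction: str = "+z"  # probes travel -z ("+z": dropped from above)

    def __post_init__(self) -> None:
        if self.probe_radius <= 0 or self.grid_spacing <= 0:
            raise ValueError("probe_radius and grid_spacing must be positive")
        if self.direction not in ("+z", "-z"):
            raise ValueError("direction must be '+z' or '-z'")


@dataclass
class SurfaceSet:
    frame_time: float
    molecule_ids: frozenset[int]
    side: str = "upper"

    def __contains__(self, mol_id: int) -> bool:
        return mol_id in self.molecule_ids


def itim_layer(frame: Frame, phase_member_ids, params: ItimParams | None = None) -> SurfaceSet:
    """Identify truly interfacial molecules of one phase by probe descent.

    A test line at (x, y) is claimed by the molecule whose atom the probe
    sphere (radius ``probe_radius``) touches first while travelling along
    the ITIM direction; a molecule is interfacial iff it claims at least one
    line.  Touch means the probe centre comes within atom vdW radius +
    probe radius of the atom centre.  The xy grid is periodic in the box.
    """
    params = params or ItimParams()
    members = list(phase_member_ids)
    if not members:
        raise ValueError("empty phase membership")
    member_set = set(members)
    box = frame.box
    nx = max(1, int(round(box.Lx / params.grid_spacing)))
    ny = max(1, int(round(box.Ly / params.grid_spacing)))
    dx, dy = box.Lx / nx, box.Ly / ny

    descending = params.direction == "+z"
    best_z = np.full((nx, ny), -np.inf if descending else np.inf)
    best_mol = np.full((nx, ny), -1, dtype=int)

    for m in frame.molecules:
        if m.id not in member_set:
            continue
        for a in m.atoms:
            R = params.atomic_radii.get(a.role, 1.5) + params.probe_radius
            ax, ay, az = a.position
            # grid-index window covering the atom's xy disk (periodic)
            i_lo = int(np.floor((ax - R) / dx))
            i_hi = int(np.ceil((ax + R) / dx))
            j_lo = int(np.floor((ay - R) / dy))
            j_hi = int(np.ceil((ay + R) / dy))
            ii = np.arange(i_lo, i_hi + 1)
            jj = np.arange(j_lo, j_hi + 1)
            gx = ii * dx
            gy = jj * dy
            dxs = gx - ax
            dys = gy - ay
            if box.periodicity[0]:
                dxs -= box.Lx * np.round(dxs / box.Lx)
            if box.periodicity[1]:
                dys -= box.Ly * np.round(dys / box.Ly)
            d2 = dxs[:, None] ** 2 + dys[None, :] ** 2
            inside = d2 <= R * R
            if not inside.any():
                continue
            h = np.sqrt(np.maximum(R * R - d2, 0.0))
            zc = az + h if descending else az - h
            I = np.mod(ii, nx)[:, None].repeat(len(jj), axis=1)
            J = np.mod(jj, ny)[None, :].repeat(len(ii), axis=0)
            sel = inside
            better = (
                zc > best_z[I, J] if descending else zc < best_z[I, J]
            ) & sel
            # scatter with duplicate (I, J) safe: iterate the few winners
            for i_loc, j_loc in zip(*np.nonzero(better)):
                gi, gj = I[i_loc, j_loc], J[i_loc, j_loc]
                z_val = zc[i_loc, j_loc]
                if (descending and z_val > best_z[gi, gj]) or (
                    not descending and z_val < best_z[gi, gj]
                ):
                    best_z[gi, gj] = z_val
                    best_mol[gi, gj] = m.id

    claimed = np.unique(best_mol[best_mol >= 0])
    side = "upper" if descending else "lower"
    return SurfaceSet(frame.time, frozenset(int(i) for i in claimed), side)


def split_penetrated_waters(
    frame: Frame,
    hbgraph: HBGraph | None = None,
    eps: float = 3.5,
    min_samples: int = 3,
) -> tuple[frozenset[int], frozenset[int]]:
    """Separate aqueous-phase waters from waters inside the organic phase.

    DBSCAN on the water oxygen positions (minimum-image metric) finds dense
    water clusters; the largest cluster is the aqueous phase, and any other
    cluster hydrogen-bonded to it (directly or transitively) is pulled in.
    Everything else — including DBSCAN noise — is penetrated.
    """
    water_ids, o_pos = frame.key_oxygens(
        [m.id for m in frame.molecules if m.species == WATER]
    )
    if len(water_ids) == 0:
        raise ValueError("frame contains no waters")
    disp = minimum_image_displacements(o_pos, o_pos, frame.box)
    dist = np.linalg.norm(disp, axis=-1)
    labels = DBSCAN(eps=eps, min_samples=min_samples, metric="precomputed").fit(
        dist
    ).labels_
    # noise points become singleton clusters so HB attachment can rescue them
    next_label = labels.max() + 1 if labels.size else 0
    labels = labels.copy()
    for k in np.nonzero(labels == -1)[0]:
        labels[k] = next_label
        next_label += 1

    cluster_of = {int(w): int(l) for w, l in zip(water_ids, labels)}
    sizes = {}
    for l in labels:
        sizes[int(l)] = sizes.get(int(l), 0) + 1
    core = max(sizes, key=lambda l: (sizes[l], -l))

    aqueous_clusters = {core}
    if hbgraph is not None:
        water_set = set(int(w) for w in water_ids)
        pairs = [
            tuple(p)
            for p in (sorted(q) for q in hbgraph.undirected_pairs())
            if p[0] in water_set and p[1] in water_set
        ]
        changed = True
        while changed:
            changed = False
            for a, b in pairs:
                ca, cb = cluster_of[a], cluster_of[b]
                if (ca in aqueous_clusters) != (cb in aqueous_clusters):
                    aqueous_clusters.update((ca, cb))
                    changed = True

    aqueous = frozenset(
        w for w in cluster_of if cluster_of[w] in aqueous_clusters
    )
    penetrated = frozenset(int(w) for w in water_ids) - aqueous
    return aqueous, penetrated


def interfacial_octanols(
    frame: Frame, surface_waters: SurfaceSet, hbgraph: HBGraph
) -> frozenset[int]:
    """Octanols whose hydroxyl is H-bonded to at least one surface water."""
    oct_ids = {m.id for m in frame.molecules if m.species == OCTANOL}
    out = set()
    for d, a, _ in hbgraph.edges:
        if d in oct_ids and a in surface_waters.molecule_ids:
            out.add(d)
        elif a in oct_ids and d in surface_waters.molecule_ids:
            out.add(a)
    return frozenset(out)


@dataclass
class WcParams:
    coarse_len: float = 2.5  # Gaussian width xi, Å
    level: float = 0.90  # fraction of bulk water density
    voxel: float = 1.0  # grid spacing, Å
    cutoff_sigmas: float = 4.0


@dataclass
class WcSurface:
    frame_time: float
    params: WcParams
    verts: np.ndarray
    faces: np.ndarray
    area: float  # Å^2
    bulk_density: float  # Å^-3
    level_density: float  # Å^-3


def _coarse_density(positions, box, params: WcParams):
    """Gaussian coarse-grained number density on a voxel grid (node-centred)."""
    xi = params.coarse_len
    L = box.lengths
    n = np.maximum(np.round(L / params.voxel).astype(int), 4)
    d = L / n
    field = np.zeros(tuple(n))
    cut = params.cutoff_sigmas * xi
    norm = (2 * np.pi * xi * xi) ** -1.5
    win = np.ceil(cut / d).astype(int)
    axes_idx = [np.arange(-w, w + 1) for w in win]
    for p in positions:
        centre = np.round(p / d).astype(int)
        offs = []
        for k in range(3):
            coords = (centre[k] + axes_idx[k]) * d[k] - p[k]
            if box.periodicity[k]:
                coords -= L[k] * np.round(coords / L[k])
            offs.append(coords)
        g = np.exp(
            -(
                offs[0][:, None, None] ** 2
                + offs[1][None, :, None] ** 2
                + offs[2][None, None, :] ** 2
            )
            / (2 * xi * xi)
        )
        idx = [np.mod(centre[k] + axes_idx[k], n[k]) for k in range(3)]
        field[np.ix_(idx[0], idx[1], idx[2])] += norm * g
    return field, d, n


def willard_chandler(
    frame: Frame,
    water_ids=None,
    params: WcParams | None = None,
    z_window: tuple[float, float] | None = None,
) -> WcSurface:
    """Willard-Chandler instantaneous surface of the water phase.

    The water oxygen density is coarse-grained with Gaussians of width
    ``coarse_len``; the surface is the marching-cubes isosurface at
    ``level`` x bulk density, with bulk density measured in the central 20%
    of the aqueous slab.  The area is the summed triangle area; with
    ``z_window`` given only triangles whose centroid lies inside it count,
    which isolates one interface of a slab (the finite slab bottom, or the
    second interface of a doubly periodic cell, would otherwise also
    contribute a sheet).
    """
    params = params or WcParams()
    if water_ids is None:
        water_ids = [m.id for m in frame.molecules if m.species == WATER]
    _, o_pos = frame.key_oxygens(water_ids)
    if len(o_pos) == 0:
        raise ValueError("no waters given")
    box = frame.box
    field, d, n = _coarse_density(o_pos, box, params)

    z_vals = o_pos[:, 2]
    z_lo, z_hi = np.percentile(z_vals, [5, 95])
    centre = 0.5 * (z_lo + z_hi)
    half_band = 0.10 * (z_hi - z_lo)
    z_nodes = np.arange(n[2]) * d[2]
    band = (z_nodes >= centre - half_band) & (z_nodes <= centre + half_band)
    if not band.any():
        band = np.argsort(np.abs(z_nodes - centre))[:2]
    bulk = float(field[:, :, band].mean())
    level = params.level * bulk

    # pad periodic axes with the wrapped first slice so the mesh spans [0, L]
    pad = field
    if box.periodicity[0]:
        pad = np.concatenate([pad, pad[:1, :, :]], axis=0)
    if box.periodicity[1]:
        pad = np.concatenate([pad, pad[:, :1, :]], axis=1)
    if box.periodicity[2]:
        pad = np.concatenate([pad, pad[:, :, :1]], axis=2)

    if not (pad.min() < level < pad.max()):
        raise ValueError(
            f"no isosurface at {level:.3g} Å^-3; field spans "
            f"[{pad.min():.3g}, {pad.max():.3g}] Å^-3"
        )
    verts, faces, _, _ = measure.marching_cubes(pad, level=level, spacing=tuple(d))
    tri = verts[faces]
    if z_window is not None:
        zc = tri[:, :, 2].mean(axis=1)
        keep = (zc >= z_window[0]) & (zc <= z_window[1])
        tri = tri[keep]
        faces = faces[keep]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    area = float(0.5 * np.linalg.norm(cross, axis=1).sum())
    return WcSurface(frame.time, params, verts, faces, area, bulk, level)
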