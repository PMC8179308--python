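import math

import numpy as np
import pytest

from hingeflow.core import Box, Frame
from hingeflow.hbond import detect_hbonds
from hingeflow.surfaces import (
    DEFAULT_RADII,
    ItimParams,
    SurfaceSet,
    WcParams,
    interfacial_octanols,
    itim_layer,
    split_penetrated_waters,
    willard_chandler,
)

from conftest import make_water, random_water_frame


def brute_force_itim(frame, member_ids, params):
    """Line-major oracle: analytic ray-sphere first contact per test line."""
    box = frame.box
    nx = max(1, int(round(box.Lx / params.grid_spacing)))
    ny = max(1, int(round(box.Ly / params.grid_spacing)))
    dx, dy = box.Lx / nx, box.Ly / ny
    descending = params.direction == "+z"
    member_set = set(member_ids)
    claimed = set()
    atoms = []
    for m in frame.molecules:
        if m.id in member_set:
            for a in m.atoms:
                atoms.append((m.id, a.position, params.atomic_radii.get(a.role, 1.5)))
    for i in range(nx):
        for j in range(ny):
            gx, gy = i * dx, j * dy
            best_z, best_mol = None, None
            for mid, pos, rad in atoms:
                R = rad + params.probe_radius
                ddx = gx - pos[0]
                ddy = gy - pos[1]
                if box.periodicity[0]:
                    ddx -= box.Lx * round(ddx / box.Lx)
                if box.periodicity[1]:
                    ddy -= box.Ly * round(ddy / box.Ly)
                d2 = ddx * ddx + ddy * ddy
                if d2 > R * R:
                    continue
                h = math.sqrt(R * R - d2)
                zc = pos[2] + h if descending else pos[2] - h
                if (
                    best_z is None
                    or (descending and zc > best_z)
                    or (not descending and zc < best_z)
                ):
                    best_z, best_mol = zc, mid
            if best_mol is not None:
                claimed.add(best_mol)
    return claimed


class TestItim:
    def test_occlusion_upper_blocks_lower(self):
        box = Box(10, 10, 30)
        lower = make_water(0, (5, 5, 10))
        upper = make_water(1, (5, 5, 14), atom_id0=3)
        s = itim_layer(Frame(0, [lower, upper], box), [0, 1], ItimParams(grid_spacing=0.5))
        assert s.molecule_ids == frozenset({1})

    def test_flat_monolayer_all_interfacial(self):
        box = Box(16, 16, 20)
        mols = [
            make_water(4 * i + j, (2 + 4 * i, 2 + 4 * j, 8), atom_id0=3 * (4 * i + j))
            for i in range(4)
            for j in range(4)
        ]
        s = itim_layer(Frame(0, mols, box), range(16), ItimParams(grid_spacing=0.5))
        assert s.molecule_ids == frozenset(range(16))

    @pytest.mark.parametrize("seed,direction", [(s, d) for s in range(3) for d in ("+z", "-z")])
    def test_matches_ray_sphere_oracle(self, seed, direction):
        rng = np.random.default_rng(seed)
        box = Box(12, 12, 30)
        mols = [
            make_water(i, rng.uniform((0, 0, 5), (12, 12, 15)), atom_id0=3 * i)
            for i in range(35)
        ]
        frame = Frame(0, mols, box)
        params = ItimParams(grid_spacing=0.6, direction=direction)
        mine = itim_layer(frame, range(35), params).molecule_ids
        assert mine == frozenset(brute_force_itim(frame, range(35), params))

    def test_xy_translation_invariance(self):
        rng = np.random.default_rng(5)
        box = Box(12, 12, 30)
        mols = [
            make_water(i, rng.uniform((0, 0, 5), (12, 12, 15)), atom_id0=3 * i)
            for i in range(30)
        ]
        params = ItimParams(grid_spacing=0.6)
        base = itim_layer(Frame(0, mols, box), range(30), params).molecule_ids
        shift = np.array([10 * 0.6, 5 * 0.6, 0.0])  # grid-commensurate
        for m in mols:
            for a in m.atoms:
                a.position = np.mod(a.position + shift, box.lengths)
        moved = itim_layer(Frame(0, mols, box), range(30), params).molecule_ids
        assert base == moved

    def test_probe_radius_monotonicity(self):
        # a larger probe bridges gaps and rests higher, so the first-contact
        # set can only shrink (occlusion monotonicity)
        rng = np.random.default_rng(9)
        mols = [
            make_water(i, rng.uniform((0, 0, 5), (12, 12, 15)), atom_id0=3 * i)
            for i in range(35)
        ]
        frame = Frame(0, mols, Box(12, 12, 30))
        small = itim_layer(frame, range(35), ItimParams(probe_radius=1.0, grid_spacing=0.5))
        big = itim_layer(frame, range(35), ItimParams(probe_radius=2.5, grid_spacing=0.5))
        assert big.molecule_ids <= small.molecule_ids

    def test_empty_phase_errors(self):
        box = Box(10, 10, 10)
        f = Frame(0, [make_water(0, (5, 5, 5))], box)
        with pytest.raises(ValueError):
            itim_layer(f, [])


class TestSplitPenetrated:
    def _slab_waters(self, n_side=6, z_levels=3, spacing=3.0):
        mols = []
        mid = 0
        for i in range(n_side):
            for j in range(n_side):
                for k in range(z_levels):
                    mols.append(
                        make_water(mid, (1 + i * spacing, 1 + j * spacing, 2 + k * spacing), atom_id0=3 * mid)
                    )
                    mid += 1
        return mols

    def test_single_deep_water_is_penetrated(self):
        mols = self._slab_waters()
        deep_id = len(mols)
        mols.append(make_water(deep_id, (9, 9, 30), atom_id0=3 * deep_id))
        frame = Frame(0, mols, Box(20, 20, 40, (True, True, False)))
        aqueous, penetrated = split_penetrated_waters(frame)
        assert penetrated == frozenset({deep_id})

    def test_all_close_means_none_penetrated(self):
        mols = self._slab_waters()
        frame = Frame(0, mols, Box(20, 20, 40, (True, True, False)))
        aqueous, penetrated = split_penetrated_waters(frame)
        assert penetrated == frozenset()
        assert len(aqueous) == len(mols)

    def test_two_blob_split_matches_component_oracle(self):
        mols = self._slab_waters(n_side=5)
        n_main = len(mols)
        # a second, smaller blob far away: its own DBSCAN cluster
        for k in range(4):
            mid = len(mols)
            mols.append(make_water(mid, (3 + 3.0 * k, 3, 34), atom_id0=3 * mid))
        frame = Frame(0, mols, Box(20, 20, 44, (True, True, False)))
        _, penetrated = split_penetrated_waters(frame)
        # component oracle at the same eps: everything not connected to the
        # biggest O-O component is penetrated
        from test_hbond import brute_force_clusters

        comps = brute_force_clusters(frame, [m.id for m in mols], 3.5)
        biggest = max(comps, key=len)
        assert penetrated == frozenset(m.id for m in mols) - biggest

    def test_no_waters_errors(self):
        from hingeflow.synth import _Builder

        b = _Builder()
        b.octanol((2, 2, 2), h_dir=(0, 0, 1), chain_dir=(1, 0, 0))
        frame = Frame(0, b.molecules, Box(20, 20, 20))
        with pytest.raises(ValueError):
            split_penetrated_waters(frame)


class TestInterfacialOctanols:
    def test_only_surface_hb_counts(self, slab_assignment):
        frame, truth, graph, _ = slab_assignment
        surface = SurfaceSet(0.0, truth.surface_waters)
        octs = interfacial_octanols(frame, surface, graph)
        assert octs == truth.layer1_octanols
        # octanols H-bonded only to island (penetrated) waters are excluded
        not_surface = SurfaceSet(0.0, truth.layer2_waters)
        assert interfacial_octanols(frame, not_surface, graph) <= truth.layer2_octanols


def _lattice_slab(box, spacing, height_fn, z_min=2.0):
    """Waters on a lattice filling z_min .. height_fn(x, y)."""
    mols = []
    mid = 0
    nx = int(round(box.Lx / spacing))
    ny = int(round(box.Ly / spacing))
    for i in range(nx):
        for j in range(ny):
            x = (i + 0.5) * box.Lx / nx
            y = (j + 0.5) * box.Ly / ny
            z = z_min
            while z <= height_fn(x, y):
                mols.append(make_water(mid, (x, y, z), atom_id0=3 * mid))
                mid += 1
                z += spacing
    return Frame(0, mols, box)


class TestWillardChandler:
    def test_flat_slab_area_near_projected(self):
        box = Box(24, 24, 40, (True, True, False))
        frame = _lattice_slab(box, 2.0, lambda x, y: 16.0)
        wc = willard_chandler(frame, params=WcParams(voxel=0.8), z_window=(9, 40))
        assert wc.area == pytest.approx(box.Lx * box.Ly, rel=0.02)

    def test_sinusoid_area_matches_quadrature(self):
        A, box = 3.0, Box(40, 20, 45, (True, True, False))
        frame = _lattice_slab(
            box, 1.8, lambda x, y: 16.0 + A * math.sin(2 * math.pi * x / box.Lx)
        )
        wc = willard_chandler(frame, params=WcParams(voxel=0.8), z_window=(9, 45))
        xs = np.linspace(0, box.Lx, 4001)
        slope = A * 2 * math.pi / box.Lx * np.cos(2 * math.pi * xs / box.Lx)
        analytic = np.trapezoid(np.sqrt(1 + slope**2), xs) * box.Ly
        assert wc.area == pytest.approx(analytic, rel=0.03)

    def test_zero_amplitude_reduces_to_flat(self):
        box = Box(24, 24, 40, (True, True, False))
        flat = willard_chandler(
            _lattice_slab(box, 2.0, lambda x, y: 16.0),
            params=WcParams(voxel=0.8),
            z_window=(9, 40),
        )
        zero_amp = willard_chandler(
            _lattice_slab(box, 2.0, lambda x, y: 16.0 + 0.0 * x),
            params=WcParams(voxel=0.8),
            z_window=(9, 40),
        )
        assert flat.area == zero_amp.area

    def test_area_not_below_projected(self, slab_fixture):
        frame, _ = slab_fixture
        wc = willard_chandler(frame, z_window=(12, frame.box.Lz))
        assert wc.area >= 0.99 * frame.box.Lx * frame.box.Ly

    def test_missing_isosurface_reports_range(self):
        box = Box(12, 12, 12)  # fully periodic, uniformly filled
        mols = []
        mid = 0
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    mols.append(make_water(mid, (1.5 + 3 * i, 1.5 + 3 * j, 1.5 + 3 * k), atom_id0=3 * mid))
                    mid += 1
        with pytest.raises(ValueError, match="isosurface"):
            willard_chandler(Frame(0, mols, box))
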