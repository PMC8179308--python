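import numpy as np
import pytest
from scipy.stats import spearmanr

from hingeflow.core import Box, Frame, Trajectory, OCTANOL, WATER
from hingeflow.hbond import detect_hbonds
from hingeflow.layers import (
    BULK_OCTANOL,
    BULK_WATER,
    LAYER1,
    LAYER2,
    REGIONS,
    Rdf2d,
    WATER_SURFACE,
    assign_layers,
    density_profile,
    ecn,
    find_bilayer_islands,
    octanol_axis,
    orientation_profile,
    packing_density,
    rdf2d,
)
from hingeflow.synth import SlabSpec, _Builder, gen_slab

from conftest import make_water


class TestAssignLayers:
    def test_regions_partition_the_frame(self, slab_assignment):
        frame, _, _, asg = slab_assignment
        assert set(asg.regions) == {m.id for m in frame.molecules}
        assert set(asg.regions.values()) <= set(REGIONS)

    def test_planted_labels_recovered(self, slab_assignment):
        frame, truth, _, asg = slab_assignment
        assert asg.members(WATER_SURFACE) == truth.surface_waters
        l1_oct = {i for i in asg.members(LAYER1) if frame.molecule(i).species == OCTANOL}
        assert l1_oct == truth.layer1_octanols
        l2 = asg.members(LAYER2)
        assert {i for i in l2 if frame.molecule(i).species == OCTANOL} == truth.layer2_octanols
        assert {i for i in l2 if frame.molecule(i).species == WATER} == truth.layer2_waters
        assert asg.members(BULK_OCTANOL) == truth.bulk_octanols

    def test_unattached_deep_octanol_is_bulk(self, slab_assignment):
        frame, truth, _, asg = slab_assignment
        for i in truth.bulk_octanols:
            assert asg[i] == BULK_OCTANOL

    def test_deterministic(self, slab_assignment):
        frame, _, graph, asg = slab_assignment
        again = assign_layers(frame, graph)
        assert again.regions == asg.regions

    def test_missing_phase_errors(self):
        frame = Frame(0, [make_water(0, (5, 5, 5))], Box(10, 10, 10))
        with pytest.raises(ValueError):
            assign_layers(frame, detect_hbonds(frame))


class TestOrientationProfile:
    def _octanol_traj(self, chain_dirs, box=None):
        b = _Builder()
        box = box or Box(60, 20, 40, (True, True, False))
        for k, d in enumerate(chain_dirs):
            d = np.asarray(d, dtype=float)
            d = d / np.linalg.norm(d)
            b.octanol((5 + 14 * (k % 4), 10, 20 + 0.01 * k), h_dir=-d, chain_dir=d)
        return Trajectory([Frame(0.0, b.molecules, box)], 10.0)

    def test_aligned_octanol(self):
        traj = self._octanol_traj([(0, 0, 1)])
        z, mean, counts = orientation_profile(traj)
        assert mean[counts > 0][0] == pytest.approx(1.0)

    def test_45_degrees(self):
        s = 1 / np.sqrt(2)
        traj = self._octanol_traj([(s, 0, s)])
        z, mean, counts = orientation_profile(traj)
        assert mean[counts > 0][0] == pytest.approx(0.707, abs=1e-3)

    def test_isotropic_null(self):
        rng = np.random.default_rng(3)
        dirs = rng.normal(size=(400, 3))
        b = _Builder()
        box = Box(300, 300, 40, (True, True, False))
        for k, d in enumerate(dirs):
            d = d / np.linalg.norm(d)
            b.octanol((1 + (k % 20) * 15, 1 + (k // 20) * 15, 20), h_dir=-d, chain_dir=d)
        traj = Trajectory([Frame(0.0, b.molecules, box)], 10.0)
        z, mean, counts = orientation_profile(traj, bin_width=40.0)
        m = mean[counts > 0]
        sem = 1 / np.sqrt(3 * counts.max())  # cos theta variance is 1/3
        assert abs(m[0]) < 3 * sem

    def test_planted_interface_tilt(self, slab_assignment):
        frame, truth, _, _ = slab_assignment
        traj = Trajectory([frame], 10.0)
        z, mean, counts = orientation_profile(traj, bin_width=4.0)
        # the bin holding the Layer-1 heads shows the planted 45° tilt
        frame_ids = {m.id for m in frame.molecules}
        head_z = np.mean(
            [frame.molecule(i).atoms[0].position[2] for i in truth.layer1_octanols]
        )
        k = np.searchsorted(z + 2.0, head_z)
        assert mean[k] == pytest.approx(0.707, abs=0.05)


class TestDensityProfile:
    def test_uniform_gas_is_flat_and_conserves_count(self):
        rng = np.random.default_rng(1)
        mols = [
            make_water(i, rng.uniform(0, 20, 3), atom_id0=3 * i) for i in range(300)
        ]
        traj = Trajectory([Frame(0.0, mols, Box(20, 20, 20))], 1.0)
        z, rho = density_profile(traj, "water_O", bin_width=2.0)
        vol_bin = 20 * 20 * 2.0
        assert rho.sum() * vol_bin == pytest.approx(300)
        assert rho.std() / rho.mean() < 0.5  # counting noise only

    def test_two_slab_step_profile(self):
        mols = []
        mid = 0
        for z0 in (5.0, 15.0):
            for i in range(10):
                for j in range(10):
                    mols.append(make_water(mid, (1 + 1.8 * i, 1 + 1.8 * j, z0), atom_id0=3 * mid))
                    mid += 1
        traj = Trajectory([Frame(0.0, mols, Box(20, 20, 20))], 1.0)
        z, rho = density_profile(traj, "water_O", bin_width=2.0)
        assert rho[2] > 0 and rho[7] > 0
        assert rho[0] == rho[4] == 0


class TestRdf2d:
    def _points_frame(self, pts, box_len=30.0):
        mols = [make_water(i, (p[0], p[1], 5.0), atom_id0=3 * i) for i, p in enumerate(pts)]
        return Frame(0.0, mols, Box(box_len, box_len, 20.0, (True, True, False)))

    def test_ideal_gas_g_near_one(self):
        rng = np.random.default_rng(5)
        frames = [
            (self._points_frame(rng.uniform(0, 30, (150, 2))), range(150))
            for _ in range(20)
        ]
        out = rdf2d(frames, bin_width=0.5)
        far = out.g[out.r > 3.0]
        assert abs(far.mean() - 1.0) < 0.02
        assert (out.g >= 0).all()

    def test_fixed_pair_peak_normalization(self):
        d = 5.0
        frame = self._points_frame([(10, 10), (10 + d, 10)])
        out = rdf2d([(frame, [0, 1])], bin_width=0.5)
        k = int(d / 0.5)  # d sits on a bin edge; histogram puts it in [5.0, 5.5)
        # one pair in the annulus bin: g = A / (N/2 * (N-1) * π Δ(r²))
        area = 30.0 * 30.0
        expect = 1.0 / (0.5 * 2 * 1 / area * np.pi * (5.5**2 - 5.0**2))
        assert out.g[k] == pytest.approx(expect, rel=1e-6)
        assert out.g[out.g > 0].size == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_histogram(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 30, (60, 2))
        frame = self._points_frame(pts)
        out = rdf2d([(frame, range(60))], bin_width=0.25)
        # naive O(N²) periodic histogram with identical normalisation
        edges = np.arange(0.0, 15.0 + 0.25, 0.25)
        hist = np.zeros(len(edges) - 1)
        for i in range(60):
            for j in range(i + 1, 60):
                dxy = pts[j] - pts[i]
                dxy -= 30.0 * np.round(dxy / 30.0)
                r = np.hypot(*dxy)
                if r < edges[-1]:
                    k = min(int(r / 0.25), len(hist) - 1)
                    hist[k] += 1
        annulus = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        g_ref = hist / (0.5 * 60 * (59 / 900.0) * annulus)
        assert np.allclose(out.g, g_ref)

    def test_too_few_members_errors(self):
        frame = self._points_frame([(5, 5)])
        with pytest.raises(ValueError):
            rdf2d([(frame, [0])])


class TestEcn:
    def test_uniform_g_gives_zero(self):
        r = np.linspace(0.05, 10, 200)
        curve = ecn(Rdf2d(r, np.ones_like(r), density=0.3))
        assert np.allclose(curve.n_excess, 0.0)
        assert curve.n_excess[0] == 0.0

    def test_unit_weight_bump_plateaus_at_density(self):
        r = np.linspace(0.005, 10, 4000)
        g = np.ones_like(r)
        # bump with ∫ (g-1) 2πr dr = 1 around r0
        r0, w = 3.0, 0.2
        mask = np.abs(r - r0) < w
        g[mask] += 1.0 / (2 * np.pi * r[mask] * (2 * w))
        curve = ecn(Rdf2d(r, g, density=0.7))
        assert curve.n_excess[-1] == pytest.approx(0.7, rel=1e-2)

    def test_depletion_gives_negative_values(self):
        r = np.linspace(0.05, 10, 500)
        g = np.where((r > 2) & (r < 4), 0.2, 1.0)
        curve = ecn(Rdf2d(r, g, density=0.5))
        assert curve.n_excess[-1] < 0

    def test_matches_direct_excess_counting(self):
        # ecn∘rdf2d equals N(r) − ρπr² counted brute-force on a fixture
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 30, (80, 2))
        mols = [make_water(i, (p[0], p[1], 5.0), atom_id0=3 * i) for i, p in enumerate(pts)]
        frame = Frame(0.0, mols, Box(30, 30, 20, (True, True, False)))
        out = rdf2d([(frame, range(80))], bin_width=0.1)
        curve = ecn(out)
        r_test = 6.0
        counts = []
        for i in range(80):
            dxy = pts - pts[i]
            dxy -= 30.0 * np.round(dxy / 30.0)
            d = np.hypot(dxy[:, 0], dxy[:, 1])
            counts.append(((d < r_test) & (d > 0)).sum())
        rho_pair = 79 / 900.0
        direct = np.mean(counts) - rho_pair * np.pi * r_test**2
        k = np.searchsorted(curve.r, r_test)
        # quadrature and finite-bin tolerance
        assert curve.n_excess[k] * (out.density / rho_pair) == pytest.approx(
            direct, abs=0.05
        )


class TestPackingDensity:
    def test_arithmetic(self):
        assert packing_density([280], [10000.0]) == pytest.approx(2.80)

    def test_intensive(self):
        one = packing_density([50], [2000.0])
        doubled = packing_density([100], [4000.0])
        assert one == doubled

    def test_zero_area_errors(self):
        with pytest.raises(ValueError):
            packing_density([5], [0.0])

    def test_flat_slab_planar_limit(self, slab_assignment):
        from hingeflow.surfaces import willard_chandler

        frame, truth, _, asg = slab_assignment
        wc = willard_chandler(frame, z_window=(12, frame.box.Lz))
        n = len(truth.layer1_octanols)
        rho = packing_density([n], [wc.area])
        assert rho == pytest.approx(100.0 * n / (frame.box.Lx * frame.box.Ly), rel=0.02)


class TestBilayerIslands:
    def test_planted_islands_recovered(self, slab_assignment):
        frame, truth, _, asg = slab_assignment
        islands = find_bilayer_islands(asg, frame)
        got = sorted((i.octanol_count, i.water_count) for i in islands)
        want = sorted((len(o), len(w)) for o, w in truth.islands)
        assert got == want

    def test_no_layer2_no_islands(self, slab_assignment):
        frame, _, _, asg = slab_assignment
        empty = type(asg)(asg.frame_time, {i: BULK_WATER for i in asg.regions})
        assert find_bilayer_islands(empty, frame) == []

    def test_water_load_scales_with_island_size(self):
        frame, truth = gen_slab(
            SlabSpec(seed=7, island_sizes=(2, 3, 4, 5, 6), island_water_slope=1.0)
        )
        sizes = [len(o) for o, _ in truth.islands]
        waters = [len(w) for _, w in truth.islands]
        graph = detect_hbonds(frame)
        asg = assign_layers(frame, graph)
        islands = find_bilayer_islands(asg, frame)
        got = sorted((i.octanol_count, i.water_count) for i in islands)
        assert got == sorted(zip(sizes, waters))
        rho, _ = spearmanr([o for o, _ in got], [w for _, w in got])
        assert rho > 0.9
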