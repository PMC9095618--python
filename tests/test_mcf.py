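"""Fiber-bundle model: placement, sampling/rendering identities, DOPC."""

import numpy as np
import pytest

from mcfholo.errors import GeometryError, OutOfBoundsError, PackingError
from mcfholo.mcf import (CoreHologram, CoreMap, OPDMap, apply_opd,
                         conjugate_compensation, disk_pixel_indices,
                         load_core_map, make_synthetic_core_map, random_opd,
                         reconstruct_far_field, render_core_field,
                         sample_core_phases, save_core_map)

TWO_PI = 2 * np.pi
GEOM = dict(pitch_x=2.0, pitch_y=2.0)
LAM = 0.532


def phase_diff(a, b):
    return np.abs(np.angle(np.exp(1j * (a - b))))


class TestCoreMapGeneration:
    def test_single_core_at_center(self):
        cm = make_synthetic_core_map(1, seed=0)
        np.testing.assert_array_equal(cm.centers, [[0.0, 0.0]])

    @pytest.mark.parametrize("n,spacing,facet", [(50, 3.5, 70.0), (200, 3.5, 70.0)])
    def test_all_pairs_spacing_brute_force(self, n, spacing, facet):
        cm = make_synthetic_core_map(n, core_radius=1.5, min_spacing=spacing,
                                     facet_diameter=facet, seed=3)
        c = cm.centers
        # independent O(n^2) verification, no KDTree
        d2 = np.sum((c[:, None, :] - c[None, :, :]) ** 2, axis=-1)
        d2[np.arange(n), np.arange(n)] = np.inf
        assert np.sqrt(d2.min()) >= spacing
        assert np.all(np.hypot(c[:, 0], c[:, 1]) <= facet / 2 - cm.core_radius + 1e-9)

    def test_seed_reproducibility(self):
        a = make_synthetic_core_map(100, seed=42)
        b = make_synthetic_core_map(100, seed=42)
        np.testing.assert_array_equal(a.centers, b.centers)

    def test_full_bundle_geometry_feasible(self):
        # the real bundle: 10,000 cores in a 350 um facet at ~3.3 um spacing
        cm = make_synthetic_core_map(10_000, core_radius=1.0, min_spacing=3.3,
                                     facet_diameter=350.0, seed=0)
        assert cm.n_cores == 10_000
        assert cm.min_center_distance() >= 3.3

    def test_infeasible_packing_raises(self):
        with pytest.raises(PackingError):
            make_synthetic_core_map(2000, core_radius=1.5, min_spacing=3.5,
                                    facet_diameter=70.0, seed=0)

    def test_overlapping_spacing_rejected(self):
        with pytest.raises(PackingError):
            make_synthetic_core_map(10, core_radius=2.0, min_spacing=3.0,
                                    facet_diameter=70.0, seed=0)


class TestSamplingRendering:
    def test_constant_phase_image_samples_constant(self, core_map):
        img = np.full((64, 64), 1.234)
        holo = sample_core_phases(img, core_map, **GEOM)
        np.testing.assert_allclose(holo.phases, 1.234)

    def test_linear_ramp_sampled_at_nearest_pixel(self, core_map):
        ny = nx = 64
        ramp = np.add.outer(np.arange(ny) * 0.01, np.arange(nx) * 0.02)
        holo = sample_core_phases(ramp, core_map, **GEOM)
        # independent nearest-pixel lookup
        for k, (cx, cy) in enumerate(core_map.centers):
            jx = int(round(cx / 2.0 + (nx - 1) / 2))
            iy = int(round(cy / 2.0 + (ny - 1) / 2))
            assert holo.phases[k] == pytest.approx(ramp[iy, jx] % TWO_PI)

    def test_core_outside_grid_raises(self):
        cm = CoreMap([[40.0, 0.0]], 1.5, 120.0)  # x=40 um is outside a 32x2um grid
        with pytest.raises(OutOfBoundsError):
            sample_core_phases(np.zeros((32, 32)), cm, **GEOM)

    def test_render_zero_phases_gives_real_disk_union(self, core_map):
        holo = CoreHologram(np.zeros(core_map.n_cores))
        f = render_core_field(holo, core_map, (64, 64), 2.0, 2.0, LAM)
        assert np.all(f.values.imag == 0)
        assert np.all(f.values.real >= 0)
        rows, cols, _ = disk_pixel_indices(core_map, (64, 64), 2.0, 2.0)
        assert np.count_nonzero(f.values) == rows.size

    def test_render_energy_equals_disk_pixel_count(self, core_map, rng):
        holo = CoreHologram(rng.uniform(0, TWO_PI, core_map.n_cores))
        f = render_core_field(holo, core_map, (64, 64), 2.0, 2.0, LAM)
        # count disk pixels independently: pixel centers within r of a center
        x = (np.arange(64) - 31.5) * 2.0
        count = 0
        for cx, cy in core_map.centers:
            count += np.count_nonzero(
                (x[None, :] - cx) ** 2 + (x[:, None] - cy) ** 2
                <= core_map.core_radius ** 2)
        assert f.energy == pytest.approx(count)

    def test_sample_after_render_is_identity(self, core_map, rng):
        holo = CoreHologram(rng.uniform(0, TWO_PI, core_map.n_cores))
        f = render_core_field(holo, core_map, (64, 64), 2.0, 2.0, LAM)
        back = sample_core_phases(np.angle(f.values), core_map, **GEOM)
        assert np.max(phase_diff(back.phases, holo.phases)) <= 1e-12

    def test_far_field_invariant_under_global_phase(self, core_map, rng):
        base = rng.uniform(0, TWO_PI, core_map.n_cores)
        i1 = reconstruct_far_field(CoreHologram(base), core_map, (64, 64),
                                   2.0, 2.0, LAM, 700.0, normalize=False)
        i2 = reconstruct_far_field(CoreHologram(base + 1.9), core_map, (64, 64),
                                   2.0, 2.0, LAM, 700.0, normalize=False)
        np.testing.assert_allclose(i1, i2, rtol=0, atol=1e-10 * i1.max())

    def test_single_core_far_field_independent_of_phase(self):
        cm = CoreMap([[0.0, 0.0]], 1.5, 70.0)
        r0 = reconstruct_far_field(CoreHologram([0.0]), cm, (32, 32), 2.0, 2.0,
                                   LAM, 700.0, normalize=False)
        r1 = reconstruct_far_field(CoreHologram([2.5]), cm, (32, 32), 2.0, 2.0,
                                   LAM, 700.0, normalize=False)
        np.testing.assert_allclose(r0, r1, atol=1e-12 * r0.max())

    def test_too_small_core_radius_raises(self):
        # pixel centers sit at odd coordinates here; a 0.5 um core at the
        # origin is more than 0.5 um from every one of them
        cm = CoreMap([[0.0, 0.0]], 0.5, 70.0)
        with pytest.raises(GeometryError):
            disk_pixel_indices(cm, (64, 64), 2.0, 2.0)

    def test_hologram_length_mismatch_raises(self, core_map):
        with pytest.raises(GeometryError):
            render_core_field(CoreHologram(np.zeros(3)), core_map, (64, 64),
                              2.0, 2.0, LAM)


class TestOPD:
    def test_zero_opd_is_identity(self, rng):
        h = CoreHologram(rng.uniform(0, TWO_PI, 50))
        h2 = apply_opd(h, OPDMap(np.zeros(50)))
        np.testing.assert_array_equal(h2.phases, h.phases)

    def test_conjugate_compensation_cancels_exactly(self, rng):
        h = CoreHologram(rng.uniform(0, TWO_PI, 128))
        d = random_opd(128, seed=5)
        distorted = apply_opd(h, d)
        compensated = apply_opd(distorted, conjugate_compensation(d))
        np.testing.assert_array_equal(compensated.phases, h.phases)

    def test_dopc_reconstruction_bit_for_bit(self, core_map, rng):
        h = CoreHologram(rng.uniform(0, TWO_PI, core_map.n_cores))
        d = random_opd(core_map.n_cores, seed=9)
        clean = reconstruct_far_field(h, core_map, (64, 64), 2.0, 2.0, LAM, 700.0)
        comp = apply_opd(apply_opd(h, d), conjugate_compensation(d))
        restored = reconstruct_far_field(comp, core_map, (64, 64), 2.0, 2.0,
                                         LAM, 700.0)
        np.testing.assert_array_equal(restored, clean)

    def test_uncompensated_opd_degrades_focus(self, core_map):
        # focusing hologram from the back-propagated point target
        from mcfholo.fields import backpropagate
        t = np.zeros((64, 64))
        t[32, 32] = 1.0
        fld = backpropagate(t, 700.0, pitch_x=2.0, pitch_y=2.0, wavelength=LAM)
        h = sample_core_phases(np.angle(fld.values), core_map, **GEOM)
        from mcfholo.metrics import correlation_coefficient
        clean = reconstruct_far_field(h, core_map, (64, 64), 2.0, 2.0, LAM, 700.0)
        worse = 0
        for seed in range(10):
            d = random_opd(core_map.n_cores, seed=seed)
            dist = reconstruct_far_field(apply_opd(h, d), core_map, (64, 64),
                                         2.0, 2.0, LAM, 700.0)
            if correlation_coefficient(dist, t) < correlation_coefficient(clean, t):
                worse += 1
        assert worse == 10

    def test_length_mismatch_raises(self):
        with pytest.raises(GeometryError):
            apply_opd(CoreHologram(np.zeros(4)), OPDMap(np.zeros(5)))


class TestCoreMapIO:
    def test_json_round_trip(self, tmp_path, core_map):
        p = tmp_path / "cores.json"
        save_core_map(p, core_map)
        back = load_core_map(p)
        np.testing.assert_allclose(back.centers, core_map.centers)
        assert back.core_radius == core_map.core_radius
        assert back.facet_diameter == core_map.facet_diameter

    def test_csv_matches_json(self, tmp_path, core_map):
        pj = tmp_path / "cores.json"
        pc = tmp_path / "cores.csv"
        save_core_map(pj, core_map)
        save_core_map(pc, core_map)
        a = load_core_map(pj)
        b = load_core_map(pc, core_radius=core_map.core_radius,
                          facet_diameter=core_map.facet_diameter)
        np.testing.assert_allclose(a.centers, b.centers)

    def test_malformed_json_names_missing_field(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"centers": [[0, 0]]}')
        from mcfholo.errors import FileFormatError
        with pytest.raises(FileFormatError, match="core_radius"):
            load_core_map(p)
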