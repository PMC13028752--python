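import math

import numpy as np
import pytest

import rbcdeform as r
from rbcdeform import dog
from conftest import match_truth


class TestDogFilter:
    def test_constant_grid_zero(self):
        out = r.dog_filter(r.IntensityGrid(np.full((64, 64), 99.0)))
        assert np.allclose(out.values, 0.0, atol=1e-9)

    def test_impulse_positive_center_flat_far_field(self):
        vals = np.zeros((65, 65))
        vals[32, 32] = 100.0
        out = r.dog_filter(r.IntensityGrid(vals), 0.7, 4.0)
        assert out.values[32, 32] > 0
        assert abs(out.values[2, 2]) < 1e-6

    def test_max_response_inside_cell(self, noise_free_background):
        # the cell interior is a plateau after band-pass filtering, so
        # the global maximum can sit anywhere inside the cell boundary
        img, truth = r.generate_image(noise_free_background, 1, seed=6)
        out = r.dog_filter(img, 0.7, 16.0)
        cy, cx = np.unravel_index(np.argmax(out.values), out.values.shape)
        cell = truth.cells[0]
        th = math.radians(cell.theta_deg)
        dx, dy = cx - cell.center_x, cy - cell.center_y
        u = dx * math.cos(th) + dy * math.sin(th)
        v = -dx * math.sin(th) + dy * math.cos(th)
        assert (u / cell.semi_major_a) ** 2 + (v / cell.semi_minor_b) ** 2 <= 1.0

    def test_sigma_ordering_enforced(self):
        with pytest.raises(ValueError):
            r.dog_filter(r.IntensityGrid(np.zeros((32, 32))), 16.0, 0.7)


class TestTophat:
    def test_full_width_stripe_removed(self):
        vals = np.zeros((40, 200))
        vals[18:22, :] = 80.0
        out = r.tophat_horizontal(r.IntensityGrid(vals), 45)
        assert np.allclose(out.values, 0.0)

    def test_narrow_blob_preserved(self):
        vals = np.zeros((40, 200))
        vals[18:22, 90:99] = 80.0  # 9 px wide < 45 px element
        out = r.tophat_horizontal(r.IntensityGrid(vals), 45)
        assert np.array_equal(out.values, vals)

    def test_bounded_between_zero_and_input(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 255, (48, 96))
        out = r.tophat_horizontal(r.IntensityGrid(vals), 45)
        assert np.all(out.values >= 0)
        assert np.all(out.values <= vals + 1e-12)

    def test_even_length_promoted_with_warning(self):
        vals = np.zeros((32, 64))
        with pytest.warns(UserWarning, match="promoted"):
            r.tophat_horizontal(r.IntensityGrid(vals), 44)


def brute_force_otsu(values, nbins=256):
    """Exhaustive search over all histogram split points (test oracle)."""
    counts, edges = np.histogram(values.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    total = counts.sum()
    scores = np.full(nbins - 1, -np.inf)
    for k in range(nbins - 1):
        w0 = counts[: k + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: k + 1] * centers[: k + 1]).sum() / w0
        mu1 = (counts[k + 1 :] * centers[k + 1 :]).sum() / w1
        scores[k] = w0 * w1 * (mu0 - mu1) ** 2
    top = scores.max()
    # smallest member of the near-tie set (same rule as the implementation)
    return centers[np.flatnonzero(scores >= top - 1e-10 * abs(top))[0]]


class TestOtsu:
    def test_two_value_image(self):
        vals = np.concatenate([np.full(50, 10.0), np.full(50, 200.0)])
        t = r.otsu_threshold(vals.reshape(10, 10))
        assert 10.0 < t < 200.0
        assert t == pytest.approx(brute_force_otsu(vals))

    def test_bimodal_gaussians(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate(
            [rng.normal(50, 10, 500), rng.normal(200, 10, 500)]
        ).reshape(20, 50)
        t = r.otsu_threshold(vals)
        assert 80.0 <= t <= 170.0
        assert t == pytest.approx(brute_force_otsu(vals))

    def test_constant_grid_error(self):
        with pytest.raises(ValueError):
            r.otsu_threshold(np.full((8, 8), 7.0))

    def test_matches_brute_force_on_random_grids(self):
        rng = np.random.default_rng(42)
        for i in range(100):
            kind = i % 3
            if kind == 0:
                vals = rng.uniform(0, 255, (12, 12))
            elif kind == 1:
                vals = rng.normal(100, 30, (10, 14))
            else:
                vals = np.concatenate(
                    [rng.normal(40, 8, 80), rng.normal(180, 20, 64)]
                ).reshape(12, 12)
            assert r.otsu_threshold(vals) == pytest.approx(brute_force_otsu(vals))

    def test_matches_skimage_on_continuous_grid(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(5)
        vals = np.concatenate(
            [rng.normal(60, 10, 600), rng.normal(190, 15, 400)]
        ).reshape(25, 40)
        assert r.otsu_threshold(vals) == pytest.approx(threshold_otsu(vals, nbins=256))


class TestSegment:
    @staticmethod
    def _grid_with_blocks(blocks):
        vals = np.zeros((200, 200))
        for (row, col, h, w) in blocks:
            vals[row : row + h, col : col + w] = 100.0
        vals[0, 0] = 1.0  # avoid constant-image Otsu error without adding objects
        return r.IntensityGrid(vals)

    @pytest.mark.parametrize(
        "h,w,kept",
        [(7, 7, False), (5, 10, True), (10, 13, True), (1, 131, False)],
    )
    def test_area_bounds_inclusive(self, h, w, kept):
        # areas 49 / 50 / 130 / 131 against the inclusive [50, 130] window
        grid = self._grid_with_blocks([(50, 50, h, w)])
        comps = r.segment(grid, r.PipelineConfig())
        assert (len(comps.pixel_sets) == 1) is kept
        if not kept:
            assert "area" in comps.removed.values()

    def test_border_touching_removed(self):
        grid = self._grid_with_blocks([(0, 50, 8, 10)])
        comps = r.segment(grid, r.PipelineConfig())
        assert comps.pixel_sets == {}
        assert "border" in comps.removed.values()

    def test_interior_cells_all_retained(self, noise_free_background, um_config):
        img, truth = r.generate_image(noise_free_background, 10, seed=15)
        filtered = r.dog_filter(img, 0.7, 16.0)
        hat = r.tophat_horizontal(filtered, 45)
        comps = r.segment(hat, um_config)
        assert len(comps.pixel_sets) == 10


class TestPrincipalAxes:
    def test_horizontal_row_of_seven(self):
        pix = np.array([(5, x) for x in range(3, 10)])
        L_X, L_Y, orient = r.principal_axes(pix)
        assert (L_X, L_Y, orient) == (7.0, 1.0, 0.0)

    def test_rasterized_axis_aligned_ellipse(self):
        # pixels with (x/4)^2 + (y/2)^2 <= 1: X extent 9, Y extent 5
        pix = np.array(
            [(y + 10, x + 10) for y in range(-3, 4) for x in range(-5, 6)
             if (x / 4) ** 2 + (y / 2) ** 2 <= 1]
        )
        L_X, L_Y, orient = r.principal_axes(pix)
        assert L_X == pytest.approx(9.0)
        assert L_Y == pytest.approx(5.0)
        assert orient == pytest.approx(0.0)
        di = r.deformability_index(L_X, L_Y)
        assert di == pytest.approx(4 / 14)

    def test_rotation_equivariance_90deg(self):
        pix = np.array(
            [(y + 10, x + 10) for y in range(-3, 4) for x in range(-5, 6)
             if (x / 4) ** 2 + (y / 2) ** 2 <= 1]
        )
        rotated = np.column_stack([pix[:, 1], pix[:, 0]])  # transpose = 90 deg
        L_X, L_Y, orient = r.principal_axes(rotated)
        assert L_X == pytest.approx(9.0)
        assert L_Y == pytest.approx(5.0)
        assert abs(orient) == pytest.approx(90.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        pix = rng.integers(0, 12, size=(25, 2))
        pix = np.unique(pix, axis=0)
        base = r.principal_axes(pix)
        shifted = r.principal_axes(pix + np.array([17, 31]))
        assert base[0] == pytest.approx(shifted[0])
        assert base[1] == pytest.approx(shifted[1])
        assert base[2] == pytest.approx(shifted[2])

    def test_fewer_than_two_pixels_error(self):
        with pytest.raises(ValueError):
            r.principal_axes(np.array([[3, 3]]))


class TestRunDog:
    def test_background_only_no_cells(self, noise_free_background, um_config):
        img, _ = r.generate_image(noise_free_background, 0, seed=1)
        cells, summary = r.run_dog(img, um_config)
        assert cells == [] and summary.n_cells == 0

    def test_recovery_on_synthetic_cells(self, noise_free_background, um_config):
        ranges = r.CellRanges(
            semi_major=(4.0, 6.8), semi_minor=(3.3, 5.2),
            di=(0.05, 0.30), area_px=(55, 125),
        )
        img, truth = r.generate_image(noise_free_background, 20, ranges, seed=0)
        cells, summary = r.run_dog(img, um_config)
        assert summary.n_cells >= 18
        errs = []
        for c in cells:
            true = match_truth(c, truth)
            assert true is not None
            errs.append(abs(c.DI - true.true_di))
        assert np.mean(errs) <= 0.03

    def test_di_cap_rejects_elongated_artifact(self):
        # L_X=9, L_Y=4 gives DI = 5/13 > 0.35
        ok = r.deformability_index(9.0, 4.0)
        assert ok == pytest.approx(5 / 13)
        assert ok > 0.35
        dets = [
            d
            for d in dog.detect_and_measure(
                _artifact_image(), r.PipelineConfig(criteria_units="micrometers")
            )
        ]
        assert any(not d.accepted and d.reject_reason == "di_cap" for d in dets)
        assert all(d.DI <= 0.35 for d in dets if d.accepted)


def _artifact_image():
    """Flat background plus one very elongated bright object (DI > 0.35)."""
    flat = r.IntensityGrid(np.full((200, 400), 100.0))
    cell = r.SyntheticCellSpec(200.0, 100.0, 8.5, 2.9, amplitude=70.0)
    img, _ = r.render_cells(flat, [cell])
    return img
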