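"""Maxima finding, Otsu masking and object quantification.

The maxima finder is checked against a brute-force prominence oracle:
a regional maximum survives tolerance t iff the connected region of
pixels with value >= peak - t that contains it holds no strictly
higher pixel.
"""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from mitozones.geometry import InvalidParameterError
from mitozones.segment import (
    DegenerateHistogramError,
    ellipse_axes,
    find_maxima,
    otsu_threshold,
    quantify_roundness,
    segment_cells,
)


def gaussian_blob(shape, cx, cy, amp, sigma):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))


def brute_force_maxima_count(img, tol):
    """Oracle: flood each strict local maximum at level peak - tol."""
    h, w = img.shape
    count = 0
    for r in range(h):
        for c in range(w):
            v = img[r, c]
            neigh = img[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2]
            if v < neigh.max() or (neigh == v).sum() > 1:
                continue  # not a strict local maximum
            # flood fill over pixels >= v - tol
            seen = np.zeros_like(img, dtype=bool)
            stack = [(r, c)]
            seen[r, c] = True
            suppressed = False
            while stack and not suppressed:
                rr, cc = stack.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        r2, c2 = rr + dr, cc + dc
                        if 0 <= r2 < h and 0 <= c2 < w and not seen[r2, c2]:
                            if img[r2, c2] > v:
                                suppressed = True
                            if img[r2, c2] >= v - tol:
                                seen[r2, c2] = True
                                stack.append((r2, c2))
            if not suppressed and v - img.min() > tol:
                count += 1
    return count


class TestFindMaxima:
    def test_flat_image_has_no_maxima(self):
        assert len(find_maxima(np.full((20, 20), 7.0), 100)) == 0

    def test_single_bright_pixel(self):
        img = np.zeros((20, 20))
        img[5, 9] = 1000
        m = find_maxima(img, 100)
        np.testing.assert_array_equal(m, [[9.0, 5.0]])

    def test_two_blobs_resolved(self):
        img = gaussian_blob((100, 100), 30, 50, 1000, 4) + gaussian_blob(
            (100, 100), 70, 50, 1000, 4
        )
        m = find_maxima(img, 100)
        assert len(m) == 2
        for cx in (30, 70):
            assert np.min(np.hypot(m[:, 0] - cx, m[:, 1] - 50)) <= 1.0

    def test_close_blobs_merge_below_tolerance(self):
        # centers 9 px apart at sigma 4: ridge dip ~18 counts < tolerance
        img = gaussian_blob((60, 60), 25, 30, 1000, 4) + gaussian_blob(
            (60, 60), 34, 30, 1000, 4
        )
        assert len(find_maxima(img, 100)) == 1
        assert len(find_maxima(img, 10)) == 2  # resolvable at low tolerance

    @pytest.mark.parametrize("tol", [5.0, 50.0, 200.0])
    def test_matches_brute_force_prominence_oracle(self, tol):
        rng = np.random.default_rng(7)
        img = np.zeros((40, 40))
        for _ in range(6):
            img += gaussian_blob(
                (40, 40), rng.uniform(5, 35), rng.uniform(5, 35),
                rng.uniform(200, 1000), rng.uniform(2, 4),
            )
        img += rng.normal(0, 2.0, img.shape)  # break plateau ties
        assert len(find_maxima(img, tol)) == brute_force_maxima_count(img, tol)

    def test_monotone_in_tolerance(self):
        rng = np.random.default_rng(11)
        img = np.zeros((50, 50))
        for _ in range(8):
            img += gaussian_blob(
                (50, 50), rng.uniform(5, 45), rng.uniform(5, 45),
                rng.uniform(100, 1000), rng.uniform(2, 5),
            )
        img += rng.normal(0, 5.0, img.shape)
        counts = [len(find_maxima(img, t)) for t in (0, 10, 50, 100, 500, 2000)]
        assert counts == sorted(counts, reverse=True)

    def test_plateau_reports_centroid(self):
        img = np.zeros((20, 20))
        img[8:11, 4:7] = 500  # 3x3 plateau centred at (5, 9)
        m = find_maxima(img, 100)
        np.testing.assert_allclose(m, [[5.0, 9.0]])


class TestOtsu:
    def test_perfect_bimodal(self):
        img = np.zeros((10, 10), dtype=np.uint16)
        img[:, 5:] = 1000
        t, mask = otsu_threshold(img)
        assert 0 <= t < 1000
        np.testing.assert_array_equal(mask, img == 1000)

    def test_matches_exhaustive_scan(self):
        # histogram {0: 50, 10: 50, 200: 100}
        img = np.array([0] * 50 + [10] * 50 + [200] * 100, dtype=np.uint16).reshape(10, 20)
        t, _ = otsu_threshold(img)
        # brute force: maximize between-class variance over candidate cuts
        vals = img.ravel()
        best_cut, best_var = None, -1.0
        for cut in np.unique(vals)[:-1]:
            lo, hi = vals[vals <= cut], vals[vals > cut]
            var = len(lo) * len(hi) * (lo.mean() - hi.mean()) ** 2
            if var > best_var:
                best_cut, best_var = cut, var
        assert best_cut <= t < 200
        # the mask agrees with the brute-force class split
        assert ((vals > t) == (vals > best_cut)).all()

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(np.full((5, 5), 123, dtype=np.uint16))


class TestRoundness:
    def test_disk_is_round(self):
        yy, xx = np.mgrid[-12:13, -12:13]
        disk = xx**2 + yy**2 <= 100
        r, flag = quantify_roundness(disk)
        assert 1.0 <= r <= 1.1 and not flag

    def test_ellipse_axis_ratio(self):
        yy, xx = np.mgrid[-25:26, -25:26]
        ell = (xx / 20.0) ** 2 + (yy / 10.0) ** 2 <= 1
        major, minor, _ = ellipse_axes(ell)
        assert major / minor == pytest.approx(2.0, rel=0.05)

    def test_single_row_floored_and_flagged(self):
        region = np.zeros((5, 11), dtype=bool)
        region[2, 1:10] = True
        with pytest.warns(UserWarning, match="minor axis floored"):
            r, flag = quantify_roundness(region)
        assert flag and r >= 1.0


class TestSegmentCells:
    def test_blank_image_empty(self):
        assert segment_cells(np.zeros((30, 30), dtype=np.uint16)) == []

    def test_phantom_recovery(self, snr20_section):
        cells = segment_cells(snr20_section.dapi, noise_tolerance=500)
        truth = snr20_section.true_nuclei[["x_um", "y_um"]].to_numpy()
        got = np.array([[c.x, c.y] for c in cells])
        assert len(cells) >= 48
        d_true, _ = cKDTree(got).query(truth)
        assert (d_true / 1.3 < 1.0).mean() >= 0.96  # recall, 1 px tolerance
        d_got, _ = cKDTree(truth).query(got)
        assert (d_got / 1.3 < 2.0).mean() >= 0.96  # precision

    def test_translation_equivariance(self):
        img = np.zeros((80, 80))
        img += gaussian_blob((80, 80), 30, 30, 5000, 3)
        img += gaussian_blob((80, 80), 55, 50, 5000, 3)
        img = np.round(img).astype(np.uint16)
        base = segment_cells(img, noise_tolerance=100, pixel_size=1.0)
        shifted = segment_cells(
            np.roll(img, (7, -5), axis=(0, 1)), noise_tolerance=100, pixel_size=1.0
        )
        assert len(base) == len(shifted) == 2
        for b, s in zip(base, shifted):
            assert s.x - b.x == pytest.approx(-5.0, abs=1e-6)
            assert s.y - b.y == pytest.approx(7.0, abs=1e-6)

    def test_centroids_inside_mask_bounds(self, snr20_section):
        _, mask = otsu_threshold(snr20_section.dapi.pixels)
        rows, cols = np.nonzero(mask)
        cells = segment_cells(snr20_section.dapi, noise_tolerance=500)
        for c in cells:
            assert cols.min() <= c.x / 1.3 <= cols.max()
            assert rows.min() <= c.y / 1.3 <= rows.max()

    def test_merged_blobs_yield_single_object(self):
        img = gaussian_blob((60, 60), 25, 30, 1000, 4) + gaussian_blob(
            (60, 60), 34, 30, 1000, 4
        )
        img = np.round(img).astype(np.uint16)
        cells = segment_cells(img, noise_tolerance=100, pixel_size=1.0)
        assert len(cells) == 1
        assert cells[0].roundness > 1.2  # elongated composite
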