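import numpy as np
import pytest

from mitozones.geometry import Window
from mitozones.synthetic import render_sections


@pytest.fixture(scope="session")
def unit_window():
    return Window.rectangle(0.0, 0.0, 1000.0, 1000.0)


def well_separated_points(n, lo, hi, min_dist, seed):
    """n points uniform in [lo, hi]^2 with pairwise distance >= min_dist."""
    rng = np.random.default_rng(seed)
    pts = []
    while len(pts) < n:
        cand = rng.uniform(lo, hi, size=2)
        if all(np.hypot(*(cand - p)) >= min_dist for p in pts):
            pts.append(cand)
    return np.array(pts)


@pytest.fixture(scope="session")
def snr20_section():
    """One rendered DAPI section: 50 well-separated nuclei at SNR 20.

    psf_sigma 2.5 µm at 1.3 µm/px; spacing >= 25 µm ≈ 7.7 psf sigmas.
    Shared across segmentation tests (read-only).
    """
    pts = well_separated_points(50, 30, 470, 25, seed=3)
    nuclei = np.column_stack([pts, np.full(len(pts), 5.0), np.zeros(len(pts))])
    sections = render_sections(
        nuclei,
        psf_sigma=2.5,
        amplitude=10000.0,
        background_mean=500.0,
        noise_sd=500.0,
        pixel_size=1.3,
        seed=0,
        shape_px=(390, 390),
    )
    return sections[0]
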