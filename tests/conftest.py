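import numpy as np
import pytest

from fcskill.tracing import build_track


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def track():
    return build_track(200.0, 140.0)


def make_trial_trace(points, times):
    """Assemble an (n, 3) trace array from xy points and timestamps."""
    pts = np.asarray(points, dtype=float)
    t = np.asarray(times, dtype=float)
    return np.column_stack([pts, t])


def raster_area(trace, track, step=0.1):
    """Independent rasterization oracle for the area between two polylines.

    Counts step x step cells whose centers fall inside the closed ring
    trace -> reversed track (winding-rule point-in-polygon).
    """
    from matplotlib.path import Path

    ring = np.vstack([np.asarray(trace, float), np.asarray(track, float)[::-1]])
    path = Path(ring, closed=True)
    lo = ring.min(axis=0) - step
    hi = ring.max(axis=0) + step
    xs = np.arange(lo[0] + step / 2, hi[0], step)
    ys = np.arange(lo[1] + step / 2, hi[1], step)
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    inside = path.contains_points(pts)
    return inside.sum() * step * step


def perturbed_section(track_pattern, rng, amp_px=2.0, section_id=1):
    """A smooth random perturbation of one track section (endpoints pinned)."""
    poly = track_pattern.section_polyline(section_id)
    n = len(poly)
    taper = np.sin(np.linspace(0.0, np.pi, n))
    out = poly.copy()
    for dim in range(2):
        raw = rng.standard_normal(n)
        kern = np.hanning(15)
        kern /= kern.sum()
        smooth = np.convolve(raw, kern, mode="same")
        out[:, dim] += amp_px * smooth / np.abs(smooth).max() * taper
    return out
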