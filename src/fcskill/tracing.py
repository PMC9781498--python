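"""Tracing-task geometry and behavioral scoring.

A motor-skill training session consists of trials in which a participant
traces one section of a four-lobed elliptical track with a computer mouse.
Skill is scored by the spatial error of the trace: the unsigned area enclosed
between the pointer trajectory and the intended track section, optionally
inflated by the trial duration and by positional offsets accumulated while
overshooting the destination vertex.

Coordinates are screen pixels; physical units come from a per-pixel area
(default 0.0025 cm^2, i.e. 0.25 mm^2 per pixel) assuming square pixels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString
from shapely.ops import polygonize, unary_union

DEFAULT_PIXEL_AREA_CM2 = 0.0025  # 0.25 mm^2 per pixel
N_SECTIONS = 8


# ---------------------------------------------------------------------------
# Track construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrackPattern:
    """Four-lobed track built from eight quarter-ellipse sections.

    ``sections[k]`` is an (n, 2) polyline in pixel coordinates; consecutive
    sections share a vertex (center or lobe tip), so the eight sections chain
    into a closed figure with five distinct vertices: the center plus the
    four lobe tips.
    """

    sections: tuple[np.ndarray, ...]
    vertices: np.ndarray  # (5, 2): center, +x, +y, -x, -y tips
    pixel_area_cm2: float = DEFAULT_PIXEL_AREA_CM2

    def __post_init__(self) -> None:
        if len(self.sections) != N_SECTIONS:
            raise ValueError(f"expected {N_SECTIONS} sections, got {len(self.sections)}")

    @property
    def cm_per_px(self) -> float:
        return math.sqrt(self.pixel_area_cm2)

    def section_polyline(self, section_id: int, direction: str = "forward") -> np.ndarray:
        """Section polyline oriented in the tracing direction (1-based id)."""
        if not 1 <= section_id <= N_SECTIONS:
            raise ValueError(f"section_id must be in 1..{N_SECTIONS}")
        poly = self.sections[section_id - 1]
        if direction == "forward":
            return poly
        if direction == "reverse":
            return poly[::-1]
        raise ValueError(f"direction must be 'forward' or 'reverse', got {direction!r}")

    def arc_length(self) -> float:
        """Total polyline arc length over the eight sections, in pixels."""
        return float(sum(np.linalg.norm(np.diff(s, axis=0), axis=1).sum() for s in self.sections))


def _quarter_ellipse(p0: np.ndarray, p1: np.ndarray, psi: float, n_points: int) -> np.ndarray:
    """Quarter-ellipse polyline from p0 to p1.

    The ellipse center is placed on the Thales circle over the chord p0-p1 at
    angle ``psi``, which guarantees that p0 and p1 sit on conjugate semi-axes
    (the two radii are perpendicular), so the arc from parameter 0 to pi/2 is
    exactly one quarter of an ellipse. ``psi`` controls which side the arc
    bulges towards and the axis ratio.
    """
    mid = 0.5 * (p0 + p1)
    r = 0.5 * np.linalg.norm(p1 - p0)
    chord_dir = (p1 - p0) / (2.0 * r)
    normal = np.array([-chord_dir[1], chord_dir[0]])
    center = mid + r * (math.cos(psi) * chord_dir + math.sin(psi) * normal)
    t = np.linspace(0.0, 0.5 * math.pi, n_points)
    pts = center + np.outer(np.cos(t), p0 - center) + np.outer(np.sin(t), p1 - center)
    pts[0] = p0
    pts[-1] = p1
    return pts


def build_track(
    extent_x_px: float,
    extent_y_px: float,
    *,
    points_per_section: int = 200,
    bulge_deg: float = 60.0,
    pixel_area_cm2: float = DEFAULT_PIXEL_AREA_CM2,
) -> TrackPattern:
    """Build the four-lobed track from eight quarter-ellipses.

    ``extent_x_px`` / ``extent_y_px`` are the distances between opposing lobe
    tips along x and y (in the study's physical setup these corresponded to
    roughly 35 cm and 25 cm of mouse travel). The pattern is centered at the
    origin and symmetric about both axes. Sections are ordered around the
    four lobes (+x, +y, -x, -y); odd sections run center->tip, even sections
    tip->center, so adjacent sections always share a vertex.
    """
    if extent_x_px <= 0 or extent_y_px <= 0:
        raise ValueError("track extents must be positive")
    psi = math.radians(bulge_deg)
    half = (extent_x_px / 2.0, extent_y_px / 2.0, extent_x_px / 2.0, extent_y_px / 2.0)
    sections: list[np.ndarray] = []
    tips = []
    for lobe in range(4):
        length = half[lobe]
        # canonical lobe along +x: one arc on each side of the lobe axis,
        # mirror images of each other, so the lobe is axis-symmetric
        up = _quarter_ellipse(np.zeros(2), np.array([length, 0.0]), -psi, points_per_section)
        down = (up * np.array([1.0, -1.0]))[::-1]
        theta = lobe * math.pi / 2.0
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        sections.append(up @ rot.T)
        sections.append(down @ rot.T)
        tips.append(rot @ np.array([length, 0.0]))
    vertices = np.vstack([np.zeros(2)] + tips)
    return TrackPattern(tuple(sections), vertices, pixel_area_cm2)


# ---------------------------------------------------------------------------
# Position error
# ---------------------------------------------------------------------------

def _dedupe(points: np.ndarray) -> np.ndarray:
    keep = np.ones(len(points), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(points, axis=0), axis=1) > 0
    return points[keep]


def position_error(trace: np.ndarray, track: np.ndarray) -> float:
    """Unsigned area (px^2) enclosed between a trace and a track polyline.

    The two polylines are joined end-to-end into a closed ring
    (trace followed by the reversed track); self-intersections split the ring
    into sub-loops whose absolute areas are summed, so overlapping excursions
    on opposite sides of the track do not cancel.
    """
    trace = _dedupe(np.asarray(trace, dtype=float))
    track = _dedupe(np.asarray(track, dtype=float))
    if len(trace) < 2 or len(track) < 2:
        raise ValueError("trace and track each need at least 2 distinct points")
    ring = np.vstack([trace, track[::-1], trace[:1]])
    boundary = unary_union(LineString(ring))  # nodes self-intersections
    return float(sum(poly.area for poly in polygonize(boundary)))


# ---------------------------------------------------------------------------
# Trial records and scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialRecord:
    """One tracing trial: pointer samples plus the active track section.

    ``trace`` is an (n, 3) array of (x_px, y_px, t_s) with strictly increasing
    timestamps starting at 0. ``track`` is the section polyline already
    oriented in the tracing direction (the destination vertex is its last
    point).
    """

    section_id: int
    direction: str
    trace: np.ndarray
    track: np.ndarray
    dwell_required_s: float = 1.0

    def __post_init__(self) -> None:
        trace = np.asarray(self.trace, dtype=float)
        if trace.ndim != 2 or trace.shape[1] != 3 or len(trace) == 0:
            raise ValueError("trace must be a non-empty (n, 3) array of (x, y, t)")
        t = trace[:, 2]
        if np.any(np.diff(t) <= 0):
            raise ValueError("trace timestamps must be strictly increasing")
        if t[0] != 0:
            raise ValueError("trace timestamps must start at 0")
        object.__setattr__(self, "trace", trace)
        object.__setattr__(self, "track", np.asarray(self.track, dtype=float))


@dataclass(frozen=True)
class TrialScore:
    position_error_cm2: float
    trace_time_s: float
    endpoint_penalty_cm2: float
    pos_time_cm2s: float
    complete: bool = True


class IncompleteTrialError(ValueError):
    """The pointer never dwelled at the destination vertex."""


def _dwell_start_index(
    xy: np.ndarray, t: np.ndarray, destination: np.ndarray, radius_px: float, dwell_s: float
) -> int | None:
    """First sample index from which the pointer stays within ``radius_px`` of
    the destination for at least ``dwell_s`` seconds (to end of recording also
    counts if it lasts that long)."""
    inside = np.linalg.norm(xy - destination, axis=1) <= radius_px
    n = len(t)
    i = 0
    while i < n:
        if not inside[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and inside[j + 1]:
            j += 1
        if t[j] - t[i] >= dwell_s:
            return i
        i = j + 1
    return None


def score_trial(
    trial: TrialRecord,
    pixel_area_cm2: float = DEFAULT_PIXEL_AREA_CM2,
    *,
    rest_radius_px: float = 5.0,
    onset_displacement_px: float = 1.0,
    penalty_mode: str = "pre",
) -> TrialScore:
    """Score one tracing trial.

    - position error: area between the trace (movement onset to dwell start)
      and the track section, converted to cm^2 via ``pixel_area_cm2``;
    - trace time: movement onset (first displacement > ``onset_displacement_px``
      from the start position) to the start of the required dwell at the
      destination vertex;
    - endpoint penalty: per-sample distance to the destination (converted with
      the linear pixel scale, sqrt of the pixel area) accumulated for samples
      strictly between the first crossing into the rest radius and the start
      of the dwell — it is zero when the pointer arrives and stays;
    - combined score: ``penalty_mode='pre'`` adds the penalty to the position
      error before multiplying by the trace time; ``'post'`` multiplies the
      position error by time first and adds the penalty afterwards.

    A trial whose trace never dwells at the destination for
    ``trial.dwell_required_s`` is returned with ``complete=False`` and scored
    over the full trace.
    """
    if penalty_mode not in ("pre", "post"):
        raise ValueError("penalty_mode must be 'pre' or 'post'")
    xy = trial.trace[:, :2]
    t = trial.trace[:, 2]
    destination = trial.track[-1]
    cm_per_px = math.sqrt(pixel_area_cm2)

    disp = np.linalg.norm(xy - xy[0], axis=1)
    moved = np.nonzero(disp > onset_displacement_px)[0]
    onset = int(moved[0]) if len(moved) else 0

    dwell = _dwell_start_index(xy, t, destination, rest_radius_px, trial.dwell_required_s)
    complete = dwell is not None
    end = dwell if complete else len(xy) - 1

    dist_dest = np.linalg.norm(xy - destination, axis=1)
    arrived = np.nonzero(dist_dest[: end + 1] <= rest_radius_px)[0]
    if len(arrived):
        first_arrival = int(arrived[0])
        penalty_px = float(dist_dest[first_arrival + 1 : end].sum())
    else:
        penalty_px = float(dist_dest[onset + 1 : end].sum())
    endpoint_penalty = penalty_px * cm_per_px

    seg = xy[onset : end + 1]
    if len(seg) >= 2:
        # compare against the span of the track actually traced: the trace is
        # truncated at movement onset and dwell start, so truncate the track at
        # its nearest vertices to the segment endpoints (a perfect trace then
        # scores exactly zero)
        track_pts = trial.track
        i0 = int(np.argmin(np.linalg.norm(track_pts - seg[0], axis=1)))
        i1 = int(np.argmin(np.linalg.norm(track_pts - seg[-1], axis=1)))
        sub = track_pts[i0 : i1 + 1] if i1 > i0 else track_pts
        if len(sub) < 2:
            sub = track_pts
        area_px2 = position_error(seg, sub)
    else:
        area_px2 = 0.0
    pos_err = area_px2 * pixel_area_cm2
    trace_time = float(t[end] - t[onset])
    if penalty_mode == "pre":
        pos_time = (pos_err + endpoint_penalty) * trace_time
    else:
        pos_time = pos_err * trace_time + endpoint_penalty
    return TrialScore(pos_err, trace_time, endpoint_penalty, pos_time, complete)


# ---------------------------------------------------------------------------
# Session summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionPerformance:
    """Behavioral summaries of one training session's trial scores."""

    metric: str  # 'pos_only' | 'pos_time'
    single_median: float
    dual_median_pre: float | None = None
    dual_median_post: float | None = None
    n_trials: int = 0
    values: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def sd_ratio(self, n: int) -> float:
        """SD of the first ``n`` trial values divided by their median.

        Diagnostic of how many trials are needed for a stable performance
        estimate: large early in training, shrinking as tracing becomes
        consistent.
        """
        if not 1 <= n <= len(self.values):
            raise ValueError(f"n must be in 1..{len(self.values)}")
        head = self.values[:n]
        med = float(np.median(head))
        if med == 0:
            return 0.0 if float(np.std(head)) == 0 else float("inf")
        return float(np.std(head) / med)


def _metric_values(scores: list[TrialScore], metric: str) -> np.ndarray:
    if metric == "pos_only":
        return np.array([s.position_error_cm2 for s in scores])
    if metric == "pos_time":
        return np.array([s.pos_time_cm2s for s in scores])
    raise ValueError(f"metric must be 'pos_only' or 'pos_time', got {metric!r}")


def summarize_session(
    scores: list[TrialScore],
    metric: str = "pos_only",
    option: str = "single",
    *,
    block: int = 30,
) -> SessionPerformance:
    """Summarize trial scores into session-level behavior.

    ``option='single'`` takes the median over all trials. ``option='dual'``
    additionally takes the median of the first ``block`` trials (pre-training
    skill) and of the last ``block`` (post-training skill); it requires at
    least ``2 * block`` trials. Incomplete trials are excluded with a warning.
    Even-count medians use the midpoint of the two central order statistics.
    """
    complete = [s for s in scores if s.complete]
    if len(complete) < len(scores):
        warnings.warn(
            f"excluding {len(scores) - len(complete)} incomplete trial(s) from summary",
            stacklevel=2,
        )
    values = _metric_values(complete, metric)
    if option == "single":
        if len(values) < 1:
            raise ValueError("single-median summary needs at least 1 complete trial")
        pre = post = None
    elif option == "dual":
        if len(values) < 2 * block:
            raise ValueError(f"dual-median summary needs at least {2 * block} complete trials")
        pre = float(np.median(values[:block]))
        post = float(np.median(values[-block:]))
    else:
        raise ValueError(f"option must be 'single' or 'dual', got {option!r}")
    return SessionPerformance(
        metric=metric,
        single_median=float(np.median(values)),
        dual_median_pre=pre,
        dual_median_post=post,
        n_trials=len(values),
        values=values,
    )
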