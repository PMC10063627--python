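"""Relative-position polar analysis of vocalization behavior.

Positions of the receiver animal relative to the emitter are expressed in polar
coordinates centered on the emitter's snout, with 0 deg along its head direction
and left/right mirrored onto [0, 180] deg. Raw vocalization histograms are
normalized by the occupancy prior collected over all video frames to yield
conditional vocalization densities, with per-bin permutation significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import IncompatibleMapsError, SlimlocError, ValidationError

DEFAULT_ANGLE_EDGES = np.linspace(0.0, 180.0, 13)  # 12 angular bins
DEFAULT_RADIUS_EDGES = np.linspace(0.0, 250.0, 13)  # 12 radial bins, mm


@dataclass(frozen=True)
class RelativePosition:
    """Snout-to-snout distance (mm) and mirrored relative angle (deg, [0, 180])."""

    distance: float
    angle: float

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValidationError("distance must be non-negative")
        if not 0 <= self.angle <= 180:
            raise ValidationError("angle must lie in [0, 180] degrees")


@dataclass
class PolarMap:
    """Binned relative-position data (angle x radius)."""

    angle_edges: np.ndarray
    radius_edges: np.ndarray
    counts: np.ndarray  # (n_angle, n_radius)
    n_events: int
    n_dropped: int = 0
    density: np.ndarray | None = None  # conditional density (masked bins = nan)
    p_values: np.ndarray | None = None
    signs: np.ndarray | None = None
    values: np.ndarray | None = None  # per-bin property means
    weights: np.ndarray | None = None  # normalized occurrence used for display
    flags: dict = field(default_factory=dict)

    def same_bins(self, other: "PolarMap") -> bool:
        return np.array_equal(self.angle_edges, other.angle_edges) and np.array_equal(
            self.radius_edges, other.radius_edges
        )


def relative_position(
    emitter_snout, emitter_head_center, receiver_snout
) -> RelativePosition:
    """Receiver position relative to the emitter's snout and head direction.

    The head direction points from the head center toward the snout; the angle
    is the absolute angle between that direction and the vector from the
    emitter's snout to the receiver's snout (left/right mirrored).
    """
    s = np.asarray(emitter_snout, dtype=float)
    h = np.asarray(emitter_head_center, dtype=float)
    r = np.asarray(receiver_snout, dtype=float)
    heading = s - h
    if np.linalg.norm(heading) == 0:
        raise SlimlocError("emitter snout and head center coincide: heading undefined")
    v = r - s
    dist = float(np.linalg.norm(v))
    if dist == 0:
        return RelativePosition(0.0, 0.0)
    cosang = np.dot(heading, v) / (np.linalg.norm(heading) * dist)
    ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return RelativePosition(dist, ang)


def _bin_events(
    events: list[RelativePosition], angle_edges: np.ndarray, radius_edges: np.ndarray
) -> tuple[np.ndarray, int]:
    if len(events):
        a = np.array([e.angle for e in events])
        r = np.array([e.distance for e in events])
        counts, _, _ = np.histogram2d(a, r, bins=(angle_edges, radius_edges))
    else:
        counts = np.zeros((len(angle_edges) - 1, len(radius_edges) - 1))
    return counts, len(events) - int(counts.sum())


def occurrence_map(
    events: list[RelativePosition],
    angle_edges: np.ndarray = DEFAULT_ANGLE_EDGES,
    radius_edges: np.ndarray = DEFAULT_RADIUS_EDGES,
) -> PolarMap:
    """Raw count histogram of relative positions."""
    angle_edges = np.asarray(angle_edges, dtype=float)
    radius_edges = np.asarray(radius_edges, dtype=float)
    for e in (angle_edges, radius_edges):
        if np.any(np.diff(e) <= 0):
            raise ValidationError("bin edges must be strictly increasing")
    counts, dropped = _bin_events(events, angle_edges, radius_edges)
    return PolarMap(angle_edges, radius_edges, counts, n_events=int(counts.sum()),
                    n_dropped=dropped)


def conditional_density(voc_map: PolarMap, prior_map: PolarMap) -> PolarMap:
    """Pointwise normalization of the vocalization map by the occupancy prior.

    density = voc_count / prior_count per bin; bins with zero prior are masked
    (nan), never infinite.
    """
    if not voc_map.same_bins(prior_map):
        raise IncompatibleMapsError("vocalization and prior maps use different bins")
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = np.where(prior_map.counts > 0, voc_map.counts / prior_map.counts, np.nan)
    return PolarMap(
        voc_map.angle_edges, voc_map.radius_edges, voc_map.counts,
        n_events=voc_map.n_events, n_dropped=voc_map.n_dropped, density=dens,
    )


def permutation_significance(
    voc_events: list[RelativePosition],
    prior_frames: list[RelativePosition],
    angle_edges: np.ndarray = DEFAULT_ANGLE_EDGES,
    radius_edges: np.ndarray = DEFAULT_RADIUS_EDGES,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> PolarMap:
    """Per-bin permutation test of the conditional vocalization density.

    The null resamples ``n_events`` frame positions from the occupancy prior
    (without replacement when possible; with replacement — flagged in
    ``flags["resampled_with_replacement"]`` — when the prior has fewer frames
    than events) and recomputes the per-bin density ``n_perm`` times. Two-sided
    p-values; sign +1/−1 where the observed density lies above/below the null
    median.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be at least 100")
    rng = np.random.default_rng(rng)
    voc = occurrence_map(voc_events, angle_edges, radius_edges)
    prior = occurrence_map(prior_frames, angle_edges, radius_edges)
    cond = conditional_density(voc, prior)
    n_events = len(voc_events)
    n_frames = len(prior_frames)
    replace = n_frames < n_events

    # precompute each prior frame's flat bin index; prior counts are fixed
    a = np.array([e.angle for e in prior_frames])
    r = np.array([e.distance for e in prior_frames])
    ia = np.clip(np.searchsorted(cond.angle_edges, a, side="right") - 1, 0,
                 len(cond.angle_edges) - 2)
    ir = np.clip(np.searchsorted(cond.radius_edges, r, side="right") - 1, 0,
                 len(cond.radius_edges) - 2)
    flat = ia * (len(cond.radius_edges) - 1) + ir
    nbins = (len(cond.angle_edges) - 1) * (len(cond.radius_edges) - 1)

    null_counts = np.empty((n_perm, nbins))
    for k in range(n_perm):
        idx = rng.choice(n_frames, size=n_events, replace=replace)
        null_counts[k] = np.bincount(flat[idx], minlength=nbins)

    obs = voc.counts.ravel()
    ge = (null_counts >= obs).mean(axis=0)
    le = (null_counts <= obs).mean(axis=0)
    # two-sided: doubled smaller tail, resolution 1/n_perm
    p = np.minimum(1.0, 2.0 * np.minimum(ge, le))
    med = np.median(null_counts, axis=0)
    sign = np.sign(obs - med)

    shape = voc.counts.shape
    cond.p_values = p.reshape(shape)
    cond.signs = sign.reshape(shape)
    cond.flags["resampled_with_replacement"] = replace
    return cond


def property_map(
    events: list[RelativePosition],
    values,
    angle_edges: np.ndarray = DEFAULT_ANGLE_EDGES,
    radius_edges: np.ndarray = DEFAULT_RADIUS_EDGES,
) -> PolarMap:
    """Per-bin mean of a USV property with normalized occurrence weights.

    The property mean (map ``values``) carries the hue in the standard display;
    the weight (peak-normalized count) carries the intensity. Bins without
    events have nan means and zero weight.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(events):
        raise ValidationError("one property value per event required")
    if len(values) and not np.all(np.isfinite(values)):
        raise ValidationError("property values must be finite")
    base = occurrence_map(events, angle_edges, radius_edges)
    if len(events):
        a = np.array([e.angle for e in events])
        r = np.array([e.distance for e in events])
        sums, _, _ = np.histogram2d(a, r, bins=(base.angle_edges, base.radius_edges),
                                    weights=values)
    else:
        sums = np.zeros_like(base.counts)
    with np.errstate(divide="ignore", invalid="ignore"):
        means = np.where(base.counts > 0, sums / base.counts, np.nan)
    peak = base.counts.max()
    base.values = means
    base.weights = base.counts / peak if peak > 0 else base.counts
    return base
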