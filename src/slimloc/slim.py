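"""SLIM: sound localization via intersecting manifolds.

For each microphone pair, the set of candidate source positions compatible with a
measured arrival-time difference is one sheet of a hyperboloid of revolution about
the line connecting the microphones (the constant path-difference surface). Because
the microphones sit a height H above the plane of interaction (the "snout plane"),
the intersection of that surface with the snout plane is a curved line — the
*origin curve* — rather than a planar hyperbola branch. Origin curves from all
pairs are rasterized as ridges on a common grid; their summed intersection density
yields a point estimate (density-weighted centroid of near-maximal cells) and a
per-vocalization accuracy measure LA (scaled spread of those cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .acoustics import AudioRecording, USVSegment, pair_delay
from .errors import (
    InfeasibleDelayError,
    InsufficientPairsError,
    NoDelayError,
    DegenerateSignalError,
    SlimlocError,
)
from .geometry import MicArrayGeometry, PairFrame, pair_frame, project_to_bounds

#: multiplier relating the raw peak-cell spread to actual localization errors
LA_SCALE_FACTOR = 4.0

#: sub-windowing of a vocalization for localization, ms
WINDOW_MS = 60.0
STEP_MS = 3.0

#: windows whose (scaled) LA is at or above this are discarded, mm
LA_MAX_MM = 40.0


def manifold_offset(D: float, R: float, delta_p) -> np.ndarray | float:
    """Axial offset of the constant path-difference surface.

    For two microphones a 3D distance ``D`` apart, and a line S parallel to the
    microphone axis at perpendicular distance ``R``, the point on S whose
    path-length difference to the two microphones equals ``delta_p`` lies at

        dX = (delta_p / 2) * sqrt((4 R^2 + D^2 - delta_p^2) / (D^2 - delta_p^2))

    measured from the plane bisecting the pair axis, positive toward the
    microphone with the *longer* path (``delta_p`` = dist-to-near-end excess,
    see :func:`origin_curve` for the sign convention used there). Reduces to
    ``delta_p / 2`` at R = 0 and grows monotonically with R.
    """
    delta_p = np.asarray(delta_p, dtype=float)
    if np.any(np.abs(delta_p) >= D):
        raise InfeasibleDelayError(
            f"|path difference| must be < D = {D} mm, got {np.max(np.abs(delta_p))}"
        )
    if np.any(np.asarray(R) < 0):
        raise ValueError("R must be non-negative")
    r2 = np.asarray(R, dtype=float) ** 2
    out = 0.5 * delta_p * np.sqrt((4 * r2 + D**2 - delta_p**2) / (D**2 - delta_p**2))
    return out if out.ndim else float(out)


@dataclass
class OriginCurve:
    """One pair's locus of candidate source positions in the snout plane.

    ``delta_p`` is the signed path-length difference dist(p, mic_i) −
    dist(p, mic_j) satisfied by every point of the curve (equal to
    −v_sound·delta_t for delta_t = arrival(j) − arrival(i)).
    """

    pair_ids: tuple[int, int]
    polyline: np.ndarray  # (n, 2) platform-frame mm
    delta_p: float
    validity_mask: np.ndarray
    infeasible: bool = False

    @property
    def valid_points(self) -> np.ndarray:
        return self.polyline[self.validity_mask]


def origin_curve(
    geometry: MicArrayGeometry,
    pair: PairFrame,
    delta_t: float,
    y_step_mm: float = 0.5,
) -> OriginCurve:
    """Sample the origin curve of one pair for a measured delay ``delta_t``.

    ``delta_t`` = arrival time at mic j minus arrival time at mic i (positive:
    source closer to mic i). The curve is computed in the pair's own 3D frame —
    x along the pair axis (toward mic j), R the distance of a snout-plane point
    from that axis, R^2 = y^2 + H_eff^2 — and then rotated/translated into the
    platform frame.
    """
    # path difference consistent with the curve invariant dist_i - dist_j = delta_p
    delta_p = -geometry.speed_of_sound * delta_t
    if abs(delta_p) >= pair.D:
        return OriginCurve(pair.pair_ids, np.empty((0, 2)), float(delta_p),
                           np.empty(0, dtype=bool), infeasible=True)

    bx, by = geometry.bounds()
    reach = math.hypot(bx, by) + math.hypot(*pair.midpoint)
    y = np.arange(-reach, reach + y_step_mm, y_step_mm)
    r = np.hypot(y, pair.H_effective)
    x = manifold_offset(pair.D, r, np.full_like(y, delta_p))
    pts_pair = np.column_stack((x, y))
    pts = pair.from_pair(pts_pair)
    # keep a generous neighborhood of the analysis rectangle so ridges span it fully
    valid = (np.abs(pts[:, 0]) <= bx + 4 * y_step_mm) & (np.abs(pts[:, 1]) <= by + 4 * y_step_mm)
    return OriginCurve(pair.pair_ids, pts, float(delta_p), valid)


def curve_residuals(curve: OriginCurve, geometry: MicArrayGeometry) -> np.ndarray:
    """|dist(p, mic_i) − dist(p, mic_j) − delta_p| for every polyline point (3D)."""
    i, j = curve.pair_ids
    p3 = np.column_stack(
        (curve.polyline, np.full(len(curve.polyline), geometry.snout_plane_z))
    )
    di = np.linalg.norm(p3 - geometry.mic_positions[i], axis=1)
    dj = np.linalg.norm(p3 - geometry.mic_positions[j], axis=1)
    return np.abs(di - dj - curve.delta_p)


@dataclass
class IntersectionDensity:
    """Summed ridge density of all origin curves over the platform + margin grid."""

    grid: np.ndarray  # (ny, nx)
    x_centers: np.ndarray
    y_centers: np.ndarray
    peak_cells: np.ndarray  # (n, 2) cell-center coordinates (x, y), mm
    estimate: np.ndarray  # (2,) mm
    la_raw: float
    la: float


def _resample_arclength(pts: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at uniform arclength spacing <= step."""
    if len(pts) < 2:
        return pts
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate(([0.0], np.cumsum(seg)))
    if s[-1] == 0:
        return pts[:1]
    n = max(2, int(np.ceil(s[-1] / step)) + 1)
    si = np.linspace(0, s[-1], n)
    return np.column_stack((np.interp(si, s, pts[:, 0]), np.interp(si, s, pts[:, 1])))


def intersect_curves(
    curves: list[OriginCurve],
    geometry: MicArrayGeometry,
    cell_mm: float = 1.0,
    ridge_sigma_mm: float = 2.0,
    peak_fraction: float = 0.9,
    la_scale: float = LA_SCALE_FACTOR,
) -> IntersectionDensity:
    """Rasterize origin curves as Gaussian ridges and locate their intersection.

    Each curve contributes a unit-height ridge with Gaussian cross-section
    (sigma = ``ridge_sigma_mm``); ridges are summed across pairs. The point
    estimate is the density-weighted centroid of cells at or above
    ``peak_fraction`` of the maximum; ``la_raw`` is the 2D RMS spread of those
    cell centers about the centroid, and ``la = la_scale * la_raw``.
    """
    usable = [c for c in curves if not c.infeasible and c.validity_mask.any()]
    if len(usable) < 2:
        raise InsufficientPairsError(
            f"need >= 2 usable origin curves, got {len(usable)}"
        )
    bx, by = geometry.bounds()
    x_centers = np.arange(-bx + cell_mm / 2, bx, cell_mm)
    y_centers = np.arange(-by + cell_mm / 2, by, cell_mm)
    nx, ny = len(x_centers), len(y_centers)
    density = np.zeros((ny, nx))
    cutoff = 5.0 * ridge_sigma_mm
    for c in usable:
        pts = _resample_arclength(c.valid_points, cell_mm / 2)
        ix = np.round((pts[:, 0] + bx - cell_mm / 2) / cell_mm).astype(int)
        iy = np.round((pts[:, 1] + by - cell_mm / 2) / cell_mm).astype(int)
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        if not inside.any():
            continue
        mask = np.ones((ny, nx), dtype=bool)
        mask[iy[inside], ix[inside]] = False
        dist = ndimage.distance_transform_edt(mask, sampling=cell_mm)
        ridge = np.where(dist <= cutoff, np.exp(-(dist**2) / (2 * ridge_sigma_mm**2)), 0.0)
        density += ridge

    peak = density.max()
    if peak <= 0:
        raise InsufficientPairsError("no curve crossed the analysis grid")
    py, px = np.nonzero(density >= peak_fraction * peak)
    cells = np.column_stack((x_centers[px], y_centers[py]))
    w = density[py, px]
    centroid = (cells * w[:, None]).sum(axis=0) / w.sum()
    spread2 = float(np.mean(np.sum((cells - centroid) ** 2, axis=1)))
    # floor at the quantization spread of a single cell so LA stays positive
    la_raw = max(math.sqrt(spread2), cell_mm / math.sqrt(12.0))
    return IntersectionDensity(
        grid=density,
        x_centers=x_centers,
        y_centers=y_centers,
        peak_cells=cells,
        estimate=centroid,
        la_raw=la_raw,
        la=la_scale * la_raw,
    )


@dataclass
class LocalizationResult:
    """Final per-USV position estimate with diagnostics."""

    usv_id: int | str
    position: np.ndarray | None  # (2,) mm, or None when unlocalized
    la: float | None
    n_windows_total: int
    n_windows_used: int
    per_window: list[tuple[np.ndarray, float]] = field(default_factory=list)

    @property
    def localized(self) -> bool:
        return self.position is not None


def localize_delays(
    delays_s: dict[tuple[int, int], float],
    geometry: MicArrayGeometry,
    cell_mm: float = 1.0,
    ridge_sigma_mm: float = 2.0,
) -> IntersectionDensity:
    """Localize from per-pair delays (delta_t = arrival(j) − arrival(i))."""
    curves = []
    for (i, j), dt in delays_s.items():
        pf = pair_frame(geometry, i, j)
        curves.append(origin_curve(geometry, pf, dt, y_step_mm=cell_mm / 2))
    return intersect_curves(curves, geometry, cell_mm=cell_mm,
                            ridge_sigma_mm=ridge_sigma_mm)


def localize_usv(
    rec: AudioRecording,
    segment: USVSegment,
    geometry: MicArrayGeometry,
    usv_id: int | str = 0,
    cell_mm: float = 1.0,
    ridge_sigma_mm: float = 2.0,
    window_ms: float = WINDOW_MS,
    step_ms: float = STEP_MS,
    la_max_mm: float = LA_MAX_MM,
) -> LocalizationResult:
    """Localize one vocalization from overlapping sub-windows.

    The segment is covered with ``window_ms`` windows advanced by ``step_ms``
    (a single centered, padded window when the call is shorter). Each window is
    localized independently (EWGCC delay per pair -> origin curves -> ridge
    intersection); windows with LA >= ``la_max_mm`` are discarded. The final
    position is the per-dimension median of kept window estimates, projected to
    the platform + margin rectangle; the final LA is the median kept LA.
    """
    win_s = window_ms * 1e-3
    if segment.duration >= win_s:
        starts = np.arange(segment.onset, segment.offset - win_s + 1e-12, step_ms * 1e-3)
        windows = [(float(s), float(s + win_s)) for s in starts]
    else:
        mid = segment.midpoint
        lo = max(rec.start_time, mid - win_s / 2)
        hi = min(rec.start_time + rec.duration, lo + win_s)
        windows = [(lo, hi)]

    kept: list[tuple[np.ndarray, float]] = []
    for w in windows:
        delays: dict[tuple[int, int], float] = {}
        for i, j in geometry.pairs():
            try:
                d = pair_delay(rec, geometry, i, j, w, band=segment.band)
            except (NoDelayError, DegenerateSignalError):
                continue
            delays[(i, j)] = d.delta_t
        if len(delays) < 2:
            continue
        try:
            dens = localize_delays(delays, geometry, cell_mm, ridge_sigma_mm)
        except InsufficientPairsError:
            continue
        if dens.la < la_max_mm:
            kept.append((dens.estimate, dens.la))

    if not kept:
        return LocalizationResult(usv_id, None, None, len(windows), 0)
    est = np.median(np.array([p for p, _ in kept]), axis=0)
    la = float(np.median([a for _, a in kept]))
    return LocalizationResult(
        usv_id,
        project_to_bounds(est, geometry),
        la,
        len(windows),
        len(kept),
        per_window=kept,
    )
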