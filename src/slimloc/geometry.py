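"""Recording-rig geometry: microphone array, coordinate frames and platform bounds.

All coordinates are platform-centered millimeters, right-handed, z up, with z = 0 at
the platform surface. Pair frames are 2D frames whose x-axis runs along the horizontal
projection of the line connecting a microphone pair.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import GeometryError, InvalidPairError

#: speed of sound in dry air at 20 degC, mm/s
SPEED_OF_SOUND_MM_S = 343_000.0


@dataclass(frozen=True)
class MicArrayGeometry:
    """Layout of microphones around the elevated interaction platform.

    Parameters
    ----------
    mic_positions
        ``(n_mics, 3)`` array-like of microphone membrane centers, mm, in
        platform-centered coordinates (z > 0, above the platform surface).
    platform_half_extent
        Half-length and half-width of the platform rectangle, mm.
    margin
        Width of the band around the platform edge that source estimates may
        occupy before being projected back, mm.
    speed_of_sound
        mm/s.
    sampling_rate
        Audio sampling rate, Hz.
    snout_plane_z
        Height of the horizontal plane in which sources are localized, mm.
    mm_per_px
        Camera scale (mm per image pixel); carried for track-file conversion.
    """

    mic_positions: np.ndarray
    platform_half_extent: tuple[float, float] = (200.0, 150.0)
    margin: float = 50.0
    speed_of_sound: float = SPEED_OF_SOUND_MM_S
    sampling_rate: float = 250_000.0
    snout_plane_z: float = 0.0
    mm_per_px: float = 469.0 / 640.0

    def __post_init__(self) -> None:
        mics = np.asarray(self.mic_positions, dtype=float)
        if mics.ndim != 2 or mics.shape[1] != 3:
            raise GeometryError("mic_positions must be an (n, 3) array")
        if mics.shape[0] < 3:
            raise GeometryError("at least 3 microphones are required")
        if not np.all(np.isfinite(mics)):
            raise GeometryError("mic_positions must be finite")
        if np.any(mics[:, 2] <= 0):
            raise GeometryError("all microphones must lie above the platform (z > 0)")
        d = np.linalg.norm(mics[:, None, :] - mics[None, :, :], axis=-1)
        if np.any(d[np.triu_indices(len(mics), k=1)] < 1e-9):
            raise GeometryError("two microphones coincide")
        if self.speed_of_sound <= 0:
            raise GeometryError("speed_of_sound must be positive")
        if self.sampling_rate <= 0:
            raise GeometryError("sampling_rate must be positive")
        object.__setattr__(self, "mic_positions", mics)

    @property
    def n_mics(self) -> int:
        return len(self.mic_positions)

    def pairs(self) -> list[tuple[int, int]]:
        """All microphone pairs (i < j); 6 pairs for 4 mics, 3 pairs for 3 mics."""
        n = self.n_mics
        return [(i, j) for i in range(n) for j in range(i + 1, n)]

    def bounds(self) -> tuple[float, float]:
        """Half-extents of the platform + margin rectangle (x, y), mm."""
        hx, hy = self.platform_half_extent
        return hx + self.margin, hy + self.margin

    def max_delay_s(self, i: int, j: int) -> float:
        """Largest physically possible |arrival-time difference| for pair (i, j)."""
        d = float(np.linalg.norm(self.mic_positions[i] - self.mic_positions[j]))
        return d / self.speed_of_sound


@dataclass(frozen=True)
class PairFrame:
    """Local 2D frame of one microphone pair.

    The frame origin is the horizontal projection of the midpoint between the two
    microphones; the x-axis points from mic ``i`` toward mic ``j`` (horizontal
    projection). ``D`` is the full 3D inter-microphone distance; ``H_effective`` is
    the mean microphone height above the snout plane.
    """

    pair_ids: tuple[int, int]
    midpoint: tuple[float, float]
    axis_angle: float
    D: float
    H_effective: float

    def to_pair(self, points: np.ndarray) -> np.ndarray:
        """Platform-frame 2D points -> pair-frame points (isometry)."""
        p = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(self.midpoint)
        c, s = math.cos(-self.axis_angle), math.sin(-self.axis_angle)
        rot = np.array([[c, -s], [s, c]])
        out = p @ rot.T
        return out if np.ndim(points) == 2 else out[0]

    def from_pair(self, points: np.ndarray) -> np.ndarray:
        """Pair-frame 2D points -> platform-frame points (inverse of :meth:`to_pair`)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        c, s = math.cos(self.axis_angle), math.sin(self.axis_angle)
        rot = np.array([[c, -s], [s, c]])
        out = p @ rot.T + np.asarray(self.midpoint)
        return out if np.ndim(points) == 2 else out[0]


def pair_frame(geometry: MicArrayGeometry, i: int, j: int) -> PairFrame:
    """Build the local frame of microphone pair ``(i, j)``.

    The rotation angle is the angle of the horizontal projection of the line
    connecting the microphones with respect to the platform x-axis. ``D`` is the
    3D inter-microphone distance (the candidate-surface computation happens in the
    pair's own 3D frame before intersecting with the snout plane).
    """
    n = geometry.n_mics
    if i == j:
        raise InvalidPairError(f"identical microphone indices ({i}, {j})")
    if not (0 <= i < n and 0 <= j < n):
        raise InvalidPairError(f"pair ({i}, {j}) out of range for {n} microphones")
    mi, mj = geometry.mic_positions[i], geometry.mic_positions[j]
    mid = (mi[:2] + mj[:2]) / 2.0
    dvec = mj[:2] - mi[:2]
    angle = math.atan2(dvec[1], dvec[0])
    if angle <= -math.pi:  # normalize to (-pi, pi]
        angle += 2 * math.pi
    d3 = float(np.linalg.norm(mj - mi))
    h_eff = float((mi[2] + mj[2]) / 2.0 - geometry.snout_plane_z)
    return PairFrame(
        pair_ids=(i, j),
        midpoint=(float(mid[0]), float(mid[1])),
        axis_angle=angle,
        D=d3,
        H_effective=h_eff,
    )


def project_to_bounds(p, geometry: MicArrayGeometry) -> np.ndarray:
    """Project a 2D point onto the platform + margin rectangle.

    Interior points are returned unchanged; outside points map to the nearest
    (Euclidean) point of the solid rectangle, which for an axis-aligned rectangle
    is per-coordinate clamping. Idempotent.
    """
    bx, by = geometry.bounds()
    p = np.asarray(p, dtype=float)
    return np.clip(p, [-bx, -by], [bx, by])


# ---------------------------------------------------------------------------
# reference layouts and config I/O


def four_mic_geometry(**overrides) -> MicArrayGeometry:
    """The 4-microphone rectangle layout around the 40 x 30 cm platform.

    Microphones sit outside the platform corners, displaced 50 mm along the long
    side and 60 mm along the short side, 121 mm above the platform, aimed at the
    center.
    """
    hx, hy = 200.0, 150.0
    dx, dy, h = 50.0, 60.0, 121.0
    mics = [
        (-(hx + dx), -(hy + dy), h),
        ((hx + dx), -(hy + dy), h),
        ((hx + dx), (hy + dy), h),
        (-(hx + dx), (hy + dy), h),
    ]
    kw = dict(mic_positions=np.array(mics), platform_half_extent=(hx, hy))
    kw.update(overrides)
    return MicArrayGeometry(**kw)


def three_mic_geometry(**overrides) -> MicArrayGeometry:
    """The 3-microphone triangle layout (microphones 133 mm above the platform)."""
    h = 133.0
    mics = [(0.0, 270.0, h), (-290.0, -210.0, h), (290.0, -210.0, h)]
    kw = dict(mic_positions=np.array(mics), platform_half_extent=(200.0, 150.0))
    kw.update(overrides)
    return MicArrayGeometry(**kw)


def save_geometry(geometry: MicArrayGeometry, path) -> None:
    """Write a geometry config as flat JSON (units: mm, Hz, mm/s; z up)."""
    d = asdict(geometry)
    d["mic_positions"] = np.asarray(geometry.mic_positions).tolist()
    d["platform_half_extent"] = list(geometry.platform_half_extent)
    d["_units"] = "positions/extents/margin mm; sampling_rate Hz; speed_of_sound mm/s"
    Path(path).write_text(json.dumps(d, indent=2))


def load_geometry(path) -> MicArrayGeometry:
    """Read a geometry config written by :func:`save_geometry`."""
    d = json.loads(Path(path).read_text())
    d.pop("_units", None)
    d["mic_positions"] = np.asarray(d["mic_positions"], dtype=float)
    d["platform_half_extent"] = tuple(d["platform_half_extent"])
    return MicArrayGeometry(**d)
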