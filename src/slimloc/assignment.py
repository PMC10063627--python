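"""Assignment of localized vocalizations to animals via the mouse probability index.

Each animal's likelihood of having emitted a localized USV is modeled as a
Gaussian centered on a reference point near its snout; the mouse probability
index (MPI) is the normalized likelihood, and a USV is reliably assignable when
the larger MPI exceeds 0.95 and the estimate lies within 100 mm of at least one
animal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidAccuracyError, MissingTrackError, ValidationError
from .slim import LocalizationResult

MPI_THRESHOLD = 0.95
MAX_DISTANCE_MM = 100.0

#: fraction of the snout-to-head-center line at which the acoustic source sits
OFFSET_AUTO = 0.4  # automatically tracked recordings
OFFSET_HAND = 0.1  # hand-tracked recordings


@dataclass(frozen=True)
class TrackFrame:
    """Per-video-frame marker positions for the two animals.

    ``markers`` maps animal id -> dict with 2D points (mm) for ``"snout"`` and
    ``"head_center"``.
    """

    frame_index: int
    timestamp: float
    markers: dict[str, dict[str, np.ndarray]]

    def animals(self) -> list[str]:
        return list(self.markers)


@dataclass
class MPIAssignment:
    """Per-animal probabilities and the assignment decision for one USV."""

    usv_id: int | str
    p_by_animal: dict[str, float]
    mpi_by_animal: dict[str, float]
    assigned_id: str | None
    exclusion_reason: str | None  # None | mpi_below_threshold | too_far_from_both | unlocalized
    underflow: bool = False


def snout_reference(
    frame: TrackFrame, animal: str, offset_fraction: float = OFFSET_AUTO
) -> np.ndarray:
    """Reference acoustic-source point on the snout-to-head-center line.

    ``offset_fraction`` = 0 is the snout marker itself; 1 is the head center.
    """
    if not 0 <= offset_fraction <= 1:
        raise ValidationError("offset_fraction must lie in [0, 1]")
    try:
        m = frame.markers[animal]
        snout = np.asarray(m["snout"], dtype=float)
        head = np.asarray(m["head_center"], dtype=float)
    except KeyError as e:
        raise MissingTrackError(f"missing marker for animal {animal!r}: {e}")
    if not (np.all(np.isfinite(snout)) and np.all(np.isfinite(head))):
        raise MissingTrackError(f"non-finite markers for animal {animal!r}")
    return snout + offset_fraction * (head - snout)


def mpi(
    estimate,
    la: float,
    ref_points: dict[str, np.ndarray],
    variance_mode: str = "as_printed",
) -> tuple[dict[str, float], dict[str, float], bool]:
    """Gaussian likelihoods and normalized mouse probability indices.

    ``P_k = exp(-|x_est - x_ref,k|^2 / (2 LA)^2)`` (``variance_mode="as_printed"``;
    ``"gaussian"`` uses the conventional ``2 LA^2`` denominator instead).
    Normalization constants cancel in ``MPI_k = P_k / sum(P)``. The MPI is
    evaluated in log space, so it stays exact when both raw likelihoods
    underflow; the returned flag marks that case.
    """
    if la is None or la <= 0:
        raise InvalidAccuracyError("LA must be positive")
    if len(ref_points) < 2:
        raise ValidationError("need reference points for two animals")
    denom = (2.0 * la) ** 2 if variance_mode == "as_printed" else 2.0 * la**2
    est = np.asarray(estimate, dtype=float)
    ids = list(ref_points)
    log_p = {
        k: -float(np.sum((est - np.asarray(ref_points[k], dtype=float)) ** 2)) / denom
        for k in ids
    }
    p = {k: float(np.exp(v)) for k, v in log_p.items()}
    underflow = all(v == 0.0 for v in p.values())
    mx = max(log_p.values())
    expd = {k: float(np.exp(v - mx)) for k, v in log_p.items()}
    tot = sum(expd.values())
    m = {k: expd[k] / tot for k in ids}
    return p, m, underflow


def assign(
    loc: LocalizationResult,
    frame: TrackFrame,
    offset_fraction: float = OFFSET_AUTO,
    mpi_threshold: float = MPI_THRESHOLD,
    max_distance_mm: float = MAX_DISTANCE_MM,
    variance_mode: str = "as_printed",
) -> MPIAssignment:
    """Assign one localized USV to an animal of ``frame``.

    Assignment requires max MPI > ``mpi_threshold`` and the estimate within
    ``max_distance_mm`` of at least one animal's reference point; otherwise the
    exclusion reason is recorded. ``frame`` should be the video frame nearest the
    USV's temporal midpoint (see :func:`nearest_frame`).
    """
    if not loc.localized:
        return MPIAssignment(loc.usv_id, {}, {}, None, "unlocalized")
    refs = {a: snout_reference(frame, a, offset_fraction) for a in frame.animals()}
    dists = {a: float(np.linalg.norm(np.asarray(loc.position) - r)) for a, r in refs.items()}
    p, m, underflow = mpi(loc.position, loc.la, refs, variance_mode)
    if min(dists.values()) > max_distance_mm:
        return MPIAssignment(loc.usv_id, p, m, None, "too_far_from_both", underflow)
    best = max(m, key=m.get)
    if m[best] <= mpi_threshold:
        return MPIAssignment(loc.usv_id, p, m, None, "mpi_below_threshold", underflow)
    return MPIAssignment(loc.usv_id, p, m, best, None, underflow)


def nearest_frame(frames: list[TrackFrame], t: float) -> TrackFrame:
    """The track frame whose timestamp is nearest ``t`` (seconds)."""
    if not frames:
        raise MissingTrackError("no track frames available")
    ts = np.array([f.timestamp for f in frames])
    return frames[int(np.argmin(np.abs(ts - t)))]
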