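"""Readers and writers for the pipeline's file formats.

Audio is WAV (PCM or float, multichannel or one file per channel). Tables are
UTF-8 CSV with a commented header line naming units; coordinates are
platform-centered millimeters, z up, timestamps seconds from recording start.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .acoustics import AudioRecording, USVSegment
from .assignment import MPIAssignment, TrackFrame
from .errors import AudioFormatError
from .slim import LocalizationResult
from .spatial_maps import PolarMap

_HEADER = "# units: mm (platform-centered, z up), seconds, Hz\n"


def _to_float(data: np.ndarray) -> np.ndarray:
    if np.issubdtype(data.dtype, np.floating):
        return data.astype(float)
    info = np.iinfo(data.dtype)
    scale = max(abs(info.min), info.max)
    return data.astype(float) / scale


def read_audio(path, channel_paths: list | None = None) -> AudioRecording:
    """Read a multichannel WAV, or several mono WAVs as one recording.

    ``channel_paths`` (if given) lists one mono WAV per channel, in channel
    order, and ``path`` is ignored. Integer PCM is scaled to [-1, 1].
    """
    try:
        if channel_paths:
            rates, chans = [], []
            for p in channel_paths:
                fs, data = wavfile.read(p)
                if np.ndim(data) != 1:
                    raise AudioFormatError(f"{p}: expected a mono file")
                rates.append(fs)
                chans.append(_to_float(np.asarray(data)))
            if len(set(rates)) != 1:
                raise AudioFormatError(f"sampling rates differ across files: {rates}")
            lens = {len(c) for c in chans}
            if len(lens) != 1:
                raise AudioFormatError(
                    f"channel lengths differ: {[len(c) for c in chans]}"
                )
            return AudioRecording(np.vstack(chans), float(rates[0]))
        fs, data = wavfile.read(path)
    except AudioFormatError:
        raise
    except Exception as e:  # scipy raises ValueError on truncated/invalid files
        raise AudioFormatError(f"cannot read {path}: {e}") from e
    data = np.asarray(data)
    if data.ndim == 1:
        data = data[:, None]
    return AudioRecording(_to_float(data).T, float(fs))


def write_audio(rec: AudioRecording, path) -> None:
    """Write a recording as a float32 multichannel WAV."""
    wavfile.write(path, int(rec.sampling_rate), rec.samples.T.astype(np.float32))


# ---------------------------------------------------------------------------
# tables


def _write_csv(df: pd.DataFrame, path) -> None:
    with open(path, "w") as f:
        f.write(_HEADER)
        df.to_csv(f, index=False)


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_segments(segments: list[USVSegment], path) -> None:
    df = pd.DataFrame(
        {
            "onset_s": [s.onset for s in segments],
            "offset_s": [s.offset for s in segments],
            "band_low_hz": [s.band[0] for s in segments],
            "band_high_hz": [s.band[1] for s in segments],
            "channel": [s.detection_channel for s in segments],
        }
    )
    _write_csv(df, path)


def read_segments(path) -> list[USVSegment]:
    df = _read_csv(path)
    return [
        USVSegment(r.onset_s, r.offset_s, (r.band_low_hz, r.band_high_hz),
                   int(r.channel))
        for r in df.itertuples()
    ]


def write_localizations(results: list[LocalizationResult], path) -> None:
    rows = []
    for r in results:
        rows.append(
            {
                "usv_id": r.usv_id,
                "x_mm": r.position[0] if r.localized else np.nan,
                "y_mm": r.position[1] if r.localized else np.nan,
                "la_mm": r.la if r.localized else np.nan,
                "n_windows_total": r.n_windows_total,
                "n_windows_used": r.n_windows_used,
                "flags": "" if r.localized else "unlocalized",
            }
        )
    _write_csv(pd.DataFrame(rows), path)


def read_localizations(path) -> list[LocalizationResult]:
    out = []
    for r in _read_csv(path).itertuples():
        localized = r.flags != "unlocalized" if isinstance(r.flags, str) else not np.isnan(r.x_mm)
        out.append(
            LocalizationResult(
                usv_id=r.usv_id,
                position=np.array([r.x_mm, r.y_mm]) if localized else None,
                la=r.la_mm if localized else None,
                n_windows_total=int(r.n_windows_total),
                n_windows_used=int(r.n_windows_used),
            )
        )
    return out


def write_tracks(frames: list[TrackFrame], path) -> None:
    rows = []
    for f in frames:
        for a, m in f.markers.items():
            rows.append(
                {
                    "frame": f.frame_index,
                    "t_s": f.timestamp,
                    "animal_id": a,
                    "snout_x_mm": m["snout"][0],
                    "snout_y_mm": m["snout"][1],
                    "head_x_mm": m["head_center"][0],
                    "head_y_mm": m["head_center"][1],
                }
            )
    _write_csv(pd.DataFrame(rows), path)


def read_tracks(path) -> list[TrackFrame]:
    df = _read_csv(path)
    frames = []
    for (idx, t), grp in df.groupby(["frame", "t_s"], sort=True):
        markers = {
            r.animal_id: {
                "snout": np.array([r.snout_x_mm, r.snout_y_mm]),
                "head_center": np.array([r.head_x_mm, r.head_y_mm]),
            }
            for r in grp.itertuples()
        }
        frames.append(TrackFrame(int(idx), float(t), markers))
    return frames


def write_assignments(assignments: list[MPIAssignment], path) -> None:
    rows = []
    for a in assignments:
        rows.append(
            {
                "usv_id": a.usv_id,
                "assigned_id": a.assigned_id or "",
                "mpi": max(a.mpi_by_animal.values()) if a.mpi_by_animal else np.nan,
                "exclusion_reason": a.exclusion_reason or "",
            }
        )
    _write_csv(pd.DataFrame(rows), path)


def write_polar_map(pmap: PolarMap, path_prefix) -> None:
    """Write a polar map as delimited matrices + a JSON sidecar with the edges."""
    prefix = Path(path_prefix)
    np.savetxt(prefix.with_suffix(".counts.csv"), pmap.counts, delimiter=",")
    for name in ("density", "p_values", "signs", "values", "weights"):
        arr = getattr(pmap, name)
        if arr is not None:
            np.savetxt(prefix.with_suffix(f".{name}.csv"), arr, delimiter=",")
    sidecar = {
        "angle_edges_deg": pmap.angle_edges.tolist(),
        "radius_edges_mm": pmap.radius_edges.tolist(),
        "n_events": pmap.n_events,
        "n_dropped": pmap.n_dropped,
        "flags": pmap.flags,
    }
    prefix.with_suffix(".edges.json").write_text(json.dumps(sidecar, indent=2))


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def write_manifest(path, config: dict, seed: int | None, outputs: list[str]) -> None:
    import slimloc

    manifest = {
        "slimloc_version": slimloc.__version__,
        "config_hash": config_hash(config),
        "seed": seed,
        "outputs": outputs,
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
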