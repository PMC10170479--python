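"""Bead detection and trajectory linking for multiple-particle tracking.

Tracking follows the classic two-step scheme: beads are first detected in
each frame as connected regions above an intensity threshold, localized
to sub-pixel precision by their intensity-weighted centroid; detections
in successive frames are then linked by the proximity principle — the
closest positions in consecutive frames belong to the same particle.
Linking is greedy in ascending pair distance with a hard displacement
gate; an unmatched detection starts a new track and an unmatched track
terminates (no gap closing).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage import measure

from .containers import VideoStack, TrajectorySet

DETECTION_COLUMNS = ["frame", "x_um", "y_um", "intensity", "spot_area_px"]

#: Default minimum trajectory length (frames) admitted to MSD analysis.
MIN_TRACK_LENGTH = 10


def detect_spots(
    frame_image: np.ndarray,
    intensity_threshold: float | None = None,
    min_size_px: int = 4,
    max_size_px: int = 400,
    pixel_size_um: float = 1.0,
) -> pd.DataFrame:
    """Detect bright spots in one frame.

    Connected pixels above the threshold are grouped; regions outside
    [min_size, max_size] are rejected; each surviving region is localized
    by its intensity-weighted centroid (sub-pixel, in um, x rightward /
    y downward, pixel centers at integers).

    When no threshold is given, a robust background rule is used:
    median + 5 sigma with sigma estimated from the median absolute
    deviation, appropriate for sparse bright spots on a noisy background.

    An all-zero frame yields an empty table; a frame saturated above
    threshold everywhere raises, since no spots are separable.
    """
    img = np.asarray(frame_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if np.any(img < 0):
        raise ValueError("image must be non-negative")
    empty = pd.DataFrame(columns=DETECTION_COLUMNS)
    if not np.any(img > 0):
        return empty
    if intensity_threshold is None:
        med = float(np.median(img))
        sigma = 1.4826 * float(np.median(np.abs(img - med)))
        thr = med + 5.0 * sigma
    else:
        thr = float(intensity_threshold)
    mask = img > thr
    if mask.all():
        raise ValueError("image saturated above threshold everywhere; "
                         "no spots are separable")
    if not mask.any():
        return empty
    labels = measure.label(mask, connectivity=2)
    rows = []
    for region in measure.regionprops(labels, intensity_image=img):
        if not (min_size_px <= region.area <= max_size_px):
            continue
        cy, cx = region.centroid_weighted
        rows.append(
            {
                "frame": 0,
                "x_um": cx * pixel_size_um,
                "y_um": cy * pixel_size_um,
                "intensity": float(region.intensity_mean * region.area),
                "spot_area_px": int(region.area),
            }
        )
    if not rows:
        return empty
    return pd.DataFrame(rows)[DETECTION_COLUMNS]


def detect_video(
    video: VideoStack | np.ndarray,
    intensity_threshold: float | None = None,
    min_size_px: int = 4,
    max_size_px: int = 400,
    pixel_size_um: float | None = None,
) -> pd.DataFrame:
    """Run :func:`detect_spots` on every frame; returns one detection table
    with the ``frame`` column filled in."""
    if isinstance(video, VideoStack):
        frames = video.frames
        px = video.pixel_size_um if pixel_size_um is None else pixel_size_um
    else:
        frames = np.asarray(video)
        px = 1.0 if pixel_size_um is None else pixel_size_um
    parts = []
    for t in range(frames.shape[0]):
        det = detect_spots(frames[t], intensity_threshold, min_size_px,
                           max_size_px, px)
        if len(det):
            det = det.assign(frame=t)
            parts.append(det)
    if not parts:
        return pd.DataFrame(columns=DETECTION_COLUMNS)
    return pd.concat(parts, ignore_index=True)[DETECTION_COLUMNS]


def _greedy_match(prev_xy: np.ndarray, new_xy: np.ndarray,
                  max_displacement_um: float) -> list[tuple[int, int]]:
    """Greedy ascending-distance assignment between two detection sets.

    Candidate pairs within the gate are sorted by (distance, prev index,
    new index) — the index order is the documented deterministic
    tie-break — and accepted while both endpoints are free.
    """
    if len(prev_xy) == 0 or len(new_xy) == 0:
        return []
    d = np.linalg.norm(prev_xy[:, None, :] - new_xy[None, :, :], axis=2)
    ip, jn = np.nonzero(d <= max_displacement_um)
    order = np.lexsort((jn, ip, d[ip, jn]))
    used_prev: set[int] = set()
    used_new: set[int] = set()
    pairs = []
    for k in order:
        i, j = int(ip[k]), int(jn[k])
        if i in used_prev or j in used_new:
            continue
        pairs.append((i, j))
        used_prev.add(i)
        used_new.add(j)
    return pairs


def link_trajectories(
    detections: pd.DataFrame,
    max_displacement_um: float,
    frame_rate_hz: float,
    pixel_size_um: float = 1.0,
    region_id: str | int = 0,
) -> TrajectorySet:
    """Link per-frame detections into trajectories by the proximity rule.

    Parameters
    ----------
    detections:
        Table with columns ``frame, x_um, y_um`` (ordered or orderable by
        frame).
    max_displacement_um:
        Hard gate on a single frame-to-frame displacement; a sensible
        default is ~5x the expected RMS Brownian step.
    """
    if max_displacement_um < 0:
        raise ValueError("max_displacement_um must be non-negative")
    det = detections.sort_values("frame", kind="stable").reset_index(drop=True)
    records: list[tuple[int, int, float, float]] = []
    next_id = 0
    active: dict[int, tuple[float, float]] = {}  # track id -> last position
    prev_frame: int | None = None
    for frame, grp in det.groupby("frame", sort=True):
        xy = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        frame = int(frame)
        if prev_frame is None or frame != prev_frame + 1 or not active:
            # a skipped frame terminates every active track
            active = {}
            assigned: dict[int, int] = {}
        else:
            track_ids = sorted(active)
            prev_xy = np.array([active[t] for t in track_ids], dtype=float)
            pairs = _greedy_match(prev_xy, xy, max_displacement_um)
            assigned = {j: track_ids[i] for i, j in pairs}
        new_active: dict[int, tuple[float, float]] = {}
        for j in range(len(xy)):
            tid = assigned.get(j)
            if tid is None:
                tid = next_id
                next_id += 1
            new_active[tid] = (float(xy[j, 0]), float(xy[j, 1]))
            records.append((tid, frame, float(xy[j, 0]), float(xy[j, 1])))
        active = new_active
        prev_frame = frame
    table = pd.DataFrame(records, columns=["particle", "frame", "x_um", "y_um"])
    table = table.sort_values(["particle", "frame"], kind="stable").reset_index(drop=True)
    return TrajectorySet(table, frame_rate_hz, pixel_size_um, region_id)


def filter_min_length(traj: TrajectorySet,
                      min_length: int = MIN_TRACK_LENGTH) -> TrajectorySet:
    """Drop trajectories shorter than ``min_length`` frames."""
    lengths = traj.table.groupby("particle")["frame"].size()
    keep = lengths[lengths >= min_length].index
    return TrajectorySet(
        traj.table[traj.table["particle"].isin(keep)].reset_index(drop=True),
        traj.frame_rate_hz,
        traj.pixel_size_um,
        traj.region_id,
    )


def track_video(
    video: VideoStack,
    max_displacement_um: float,
    intensity_threshold: float | None = None,
    min_size_px: int = 4,
    max_size_px: int = 400,
    region_id: str | int = 0,
) -> TrajectorySet:
    """Convenience two-step tracking: detect every frame, then link."""
    det = detect_video(video, intensity_threshold, min_size_px, max_size_px)
    return link_trajectories(det, max_displacement_um, video.frame_rate_hz,
                             video.pixel_size_um, region_id)
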