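"""Shared in-memory containers for image stacks and particle trajectories.

Conventions
-----------
* Images: ``frames`` arrays are indexed ``(t, y, x)`` (videos) or
  ``(z, channel, y, x)`` (confocal stacks). Pixel centers sit at integer
  coordinates, origin top-left, x rightward, y downward.
* Trajectories: long-format table with columns ``particle``, ``frame``,
  ``x_um``, ``y_um``. Within a particle, frames increase strictly with no
  gaps (a missed detection terminates the track).
* On disk: multi-page TIFF for image stacks with a JSON sidecar carrying
  the calibration; CSV for trajectory tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

TRAJECTORY_COLUMNS = ["particle", "frame", "x_um", "y_um"]


@dataclass
class TrajectorySet:
    """Linked particle trajectories with acquisition calibration.

    Parameters
    ----------
    table:
        Long-format DataFrame with columns ``particle, frame, x_um, y_um``.
    frame_rate_hz:
        Acquisition frame rate (1/s).
    pixel_size_um:
        Physical pixel pitch; coordinates in the table are already in um.
    region_id:
        Identifier of the imaged mucus region (the microrheology protocol
        records >= 8 regions per condition).
    """

    table: pd.DataFrame
    frame_rate_hz: float
    pixel_size_um: float = 1.0
    region_id: str | int = 0

    def __post_init__(self) -> None:
        missing = [c for c in TRAJECTORY_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"trajectory table lacks columns {missing}")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        self.table = self.table[TRAJECTORY_COLUMNS].copy()
        self.table["particle"] = self.table["particle"].astype(np.int64)
        self.table["frame"] = self.table["frame"].astype(np.int64)
        for pid, grp in self.table.groupby("particle"):
            frames = grp["frame"].to_numpy()
            if len(frames) > 1 and not np.all(np.diff(frames) == 1):
                raise ValueError(
                    f"particle {pid}: frames must increase by exactly 1 "
                    "(no gaps; a miss terminates the track)"
                )

    @property
    def n_particles(self) -> int:
        return int(self.table["particle"].nunique())

    @property
    def dt_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    def positions(self, particle: int) -> np.ndarray:
        """(n, 2) array of (x_um, y_um) for one particle, frame-ordered."""
        grp = self.table[self.table["particle"] == particle]
        return grp[["x_um", "y_um"]].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        frame_rate_hz: float,
        pixel_size_um: float = 1.0,
        region_id: str | int = 0,
    ) -> "TrajectorySet":
        return cls(pd.read_csv(path), frame_rate_hz, pixel_size_um, region_id)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


@dataclass
class VideoStack:
    """Time series of single-channel frames, ``(t, y, x)``."""

    frames: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("VideoStack frames must be (t, y, x)")
        if self.frame_rate_hz <= 0 or self.pixel_size_um <= 0:
            raise ValueError("frame rate and pixel size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def write_tiff(self, path: str | Path) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.frames)
        meta = {
            "frame_rate_hz": self.frame_rate_hz,
            "pixel_size_um": self.pixel_size_um,
            **self.metadata,
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=2))

    @classmethod
    def read_tiff(cls, path: str | Path, frame_rate_hz: float | None = None,
                  pixel_size_um: float | None = None) -> "VideoStack":
        path = Path(path)
        frames = tifffile.imread(path)
        meta: dict = {}
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        fr = frame_rate_hz if frame_rate_hz is not None else meta.pop("frame_rate_hz", None)
        px = pixel_size_um if pixel_size_um is not None else meta.pop("pixel_size_um", 1.0)
        if fr is None:
            raise ValueError("frame rate not given and no sidecar metadata found")
        return cls(frames, fr, px, meta)


@dataclass
class ZStack:
    """Two-channel confocal stack, ``(z, channel, y, x)``, calibrated in z."""

    planes: np.ndarray
    z_spacing_um: float
    pixel_size_um: float = 1.0
    channel_names: tuple = ("blue", "red")
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 4:
            raise ValueError("ZStack planes must be (z, channel, y, x)")
        if self.z_spacing_um <= 0:
            raise ValueError("z_spacing_um must be positive")

    @property
    def n_planes(self) -> int:
        return self.planes.shape[0]

    @property
    def z_um(self) -> np.ndarray:
        return np.arange(self.n_planes) * self.z_spacing_um

    def channel(self, name_or_index) -> np.ndarray:
        if isinstance(name_or_index, str):
            idx = self.channel_names.index(name_or_index)
        else:
            idx = int(name_or_index)
        return self.planes[:, idx]

    def write_tiff(self, path: str | Path) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.planes)
        meta = {
            "z_spacing_um": self.z_spacing_um,
            "pixel_size_um": self.pixel_size_um,
            "channel_names": list(self.channel_names),
            **self.metadata,
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=2))

    @classmethod
    def read_tiff(cls, path: str | Path) -> "ZStack":
        path = Path(path)
        planes = tifffile.imread(path)
        meta = json.loads(_sidecar_path(path).read_text())
        return cls(
            planes,
            meta.pop("z_spacing_um"),
            meta.pop("pixel_size_um", 1.0),
            tuple(meta.pop("channel_names", ("blue", "red"))),
            meta,
        )
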