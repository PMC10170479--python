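"""Fluorescence morphometry: marker abundance, cell shape, mucus thickness.

Quantifications mirror the standard confocal image-analysis workflow:

* marker abundance — thresholded marker area (um^2) divided by the
  number of DAPI-stained nuclei in the same field;
* cell shape — area, aspect ratio (major/minor axis of the best-fit
  ellipse) and circularity 4*pi*area/perimeter^2 per labeled cell;
* mucus thickness — from a two-channel z-stack, the gap between the top
  of the nuclear (blue) slab and the bottom of the aerosolized-bead
  (red) layer, each located as the extreme plane whose in-plane coverage
  exceeds a threshold fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed
import scipy.ndimage as ndi

from .containers import ZStack

#: Fraction of in-plane pixels that must exceed threshold for a z plane
#: to count as part of a fluorescent layer.
DEFAULT_COVERAGE_FRACTION = 0.01


@dataclass
class MorphometryResult:
    marker_area_um2: float
    n_nuclei: int
    marker_area_per_nucleus_um2: float

    def to_dict(self) -> dict:
        return {
            "marker_area_um2": self.marker_area_um2,
            "n_nuclei": self.n_nuclei,
            "marker_area_per_nucleus_um2": self.marker_area_per_nucleus_um2,
        }


@dataclass
class ThicknessResult:
    thickness_um: float
    particle_layer_z_um: float
    cell_layer_top_z_um: float

    def to_dict(self) -> dict:
        return {
            "thickness_um": self.thickness_um,
            "particle_layer_z_um": self.particle_layer_z_um,
            "cell_layer_top_z_um": self.cell_layer_top_z_um,
        }


def _threshold(img: np.ndarray, threshold: float | None) -> float:
    if threshold is not None:
        return float(threshold)
    return float(threshold_otsu(img))


def count_nuclei(
    nuclei_img: np.ndarray,
    threshold: float | None = None,
    min_area_px: int = 9,
    split_touching: bool = False,
) -> int:
    """Count nuclei as connected components above threshold and min area.

    ``split_touching`` enables a distance-transform watershed to separate
    touching nuclei (off by default, as in simple particle analysis).
    """
    img = np.asarray(nuclei_img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel nuclei image")
    if not np.any(img > 0):
        return 0
    mask = img > _threshold(img, threshold)
    if not mask.any():
        return 0
    if split_touching:
        distance = ndi.distance_transform_edt(mask)
        smoothed = ndi.gaussian_filter(distance, sigma=1.0)
        peaks = (smoothed == ndi.maximum_filter(smoothed, size=5)) & mask
        peaks &= smoothed > 0.5 * smoothed.max()
        markers, _ = ndi.label(peaks)
        labels = watershed(-distance, markers, mask=mask)
    else:
        labels = measure.label(mask, connectivity=2)
    count = 0
    for region in measure.regionprops(labels):
        if region.area >= min_area_px:
            count += 1
    return count


def marker_area_per_cell(
    marker_img: np.ndarray,
    nuclei_img: np.ndarray,
    marker_threshold: float | None = None,
    pixel_size_um: float = 1.0,
    nuclei_threshold: float | None = None,
    min_nucleus_area_px: int = 9,
) -> MorphometryResult:
    """Thresholded marker area in um^2 per nucleus of the same field."""
    marker = np.asarray(marker_img, dtype=float)
    if marker.shape != np.asarray(nuclei_img).shape:
        raise ValueError("marker and nuclei images must be the same field")
    n_nuclei = count_nuclei(nuclei_img, nuclei_threshold, min_nucleus_area_px)
    if n_nuclei == 0:
        raise ValueError("no nuclei detected; marker-per-cell ratio undefined")
    if np.any(marker > 0):
        thr = _threshold(marker, marker_threshold)
        area_px = int(np.count_nonzero(marker > thr))
    else:
        area_px = 0
    area_um2 = area_px * pixel_size_um**2
    return MorphometryResult(area_um2, n_nuclei, area_um2 / n_nuclei)


def cell_shape_metrics(label_img: np.ndarray,
                       pixel_size_um: float = 1.0) -> pd.DataFrame:
    """Per-cell area, aspect ratio and circularity from a label mask.

    The label mask stands in for manual single-cell selection. Aspect
    ratio is major/minor axis of the moment-matched ellipse; circularity
    is 4*pi*area/perimeter^2 (clipped to 1, where digitized perimeters of
    small discs can overshoot). Degenerate regions (minor axis ~ 0 or
    zero perimeter) are skipped with a warning.
    """
    labels = np.asarray(label_img)
    if labels.ndim != 2:
        raise ValueError("expected a 2D label image")
    rows = []
    for region in measure.regionprops(labels):
        if region.axis_minor_length == 0 or region.perimeter == 0:
            warnings.warn(f"skipping degenerate region {region.label} "
                          f"({region.area} px)")
            continue
        area_um2 = region.area * pixel_size_um**2
        circ = 4.0 * np.pi * region.area / region.perimeter**2
        rows.append(
            {
                "label": region.label,
                "area_um2": area_um2,
                "aspect_ratio": region.axis_major_length / region.axis_minor_length,
                "circularity": min(float(circ), 1.0),
            }
        )
    return pd.DataFrame(rows, columns=["label", "area_um2", "aspect_ratio",
                                       "circularity"])


def _layer_coverage(channel_planes: np.ndarray, threshold: float | None) -> np.ndarray:
    """Fraction of in-plane pixels above threshold, per z plane."""
    flat = channel_planes.reshape(channel_planes.shape[0], -1)
    if threshold is None:
        if flat.max() <= flat.min():  # constant channel: nothing to segment
            return np.zeros(flat.shape[0])
        threshold = float(threshold_otsu(flat))
    return np.mean(flat > threshold, axis=1)


def mucus_thickness(
    zstack: ZStack,
    red_threshold: float | None = None,
    blue_threshold: float | None = None,
    coverage_fraction: float = DEFAULT_COVERAGE_FRACTION,
) -> ThicknessResult:
    """Mucus thickness as the gap between the nuclear slab and bead layer.

    cell_layer_top = highest z whose blue coverage exceeds
    ``coverage_fraction``; particle_layer = lowest such z in red;
    thickness = particle_layer - cell_layer_top, floored at 0.
    """
    blue = zstack.channel("blue")
    red = zstack.channel("red")
    z = zstack.z_um
    blue_cov = _layer_coverage(blue, blue_threshold)
    red_cov = _layer_coverage(red, red_threshold)
    blue_hit = np.nonzero(blue_cov > coverage_fraction)[0]
    red_hit = np.nonzero(red_cov > coverage_fraction)[0]
    if blue_hit.size == 0:
        raise ValueError("blue (nuclei) channel never crosses the coverage threshold")
    if red_hit.size == 0:
        raise ValueError("red (bead) channel never crosses the coverage threshold")
    cell_top = float(z[blue_hit[-1]])
    particle_z = float(z[red_hit[0]])
    return ThicknessResult(max(particle_z - cell_top, 0.0), particle_z, cell_top)
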