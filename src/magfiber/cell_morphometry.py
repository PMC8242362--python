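"""Per-cell orientation statistics and viability quantification.

Encapsulated tendon fibroblasts adopt uniaxial, high-aspect-ratio shapes in
aligned fibrous gels; the degree of cell co-alignment is summarized by the
full width at half maximum (FWHM) of the axial orientation histogram and by
angular stratification (fractions within 0-30, 30-60 and 60-90 degrees of
the alignment axis). Cell death is quantified as the percentage of
Hoechst-segmented nuclei that are positive for propidium iodide (PI).
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation

from .circstats import axial_difference, wrap_axial

logger = logging.getLogger(__name__)

__all__ = [
    "CellOrientationSet", "OrientationHistogram", "ViabilityResult",
    "segment_cells", "orientation_histogram", "angular_stratification",
    "viability", "split_nuclei",
]


@dataclass
class CellOrientationSet:
    """Per-cell morphometry: orientation (deg, axial; NaN when the cell is
    too round for the axis to be defined), aspect ratio, area (um^2)."""
    table: pd.DataFrame
    pixel_size_um: float
    min_aspect_ratio: float

    @property
    def angles_deg(self) -> np.ndarray:
        """Orientations of cells with a defined axis."""
        a = self.table["orientation_deg"].to_numpy()
        return a[~np.isnan(a)]


def _moments_orientation(coords_yx: np.ndarray):
    """Orientation (deg from +x toward +y) and aspect ratio from second
    central moments (equivalent-ellipse fit)."""
    y = coords_yx[:, 0].astype(float)
    x = coords_yx[:, 1].astype(float)
    mu20 = np.var(x)
    mu02 = np.var(y)
    mu11 = np.mean((x - x.mean()) * (y - y.mean()))
    theta = 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)
    common = np.hypot(mu20 - mu02, 2.0 * mu11)
    lam1 = (mu20 + mu02 + common) / 2.0
    lam2 = (mu20 + mu02 - common) / 2.0
    aspect = np.sqrt(lam1 / lam2) if lam2 > 1e-12 else np.inf
    return float(wrap_axial(np.rad2deg(theta))), float(aspect)


def segment_cells(image, pixel_size_um: float,
                  min_area_um2: float = 100.0,
                  min_aspect_ratio: float = 1.2) -> CellOrientationSet:
    """Threshold (Otsu), size-filter and label cells; fit each one's
    equivalent ellipse for orientation and aspect ratio.

    Orientation is reported only for cells with aspect ratio >=
    ``min_aspect_ratio``; rounder cells are kept in the table with NaN
    orientation. An image with no objects yields an empty table (logged).
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    t = filters.threshold_otsu(img)
    binary = img > t
    min_px = max(int(min_area_um2 / pixel_size_um ** 2), 1)
    binary = morphology.remove_small_objects(binary, max_size=min_px - 1)
    labels = measure.label(binary, connectivity=2)
    rows = []
    for region in measure.regionprops(labels):
        theta, aspect = _moments_orientation(region.coords)
        rows.append({
            "label": region.label,
            "x_px": region.centroid[1],
            "y_px": region.centroid[0],
            "area_um2": region.area * pixel_size_um ** 2,
            "aspect_ratio": aspect,
            "orientation_deg": theta if aspect >= min_aspect_ratio else np.nan,
        })
    if not rows:
        logger.info("segment_cells: no objects after filtering")
    table = pd.DataFrame(rows, columns=["label", "x_px", "y_px", "area_um2",
                                        "aspect_ratio", "orientation_deg"])
    return CellOrientationSet(table=table, pixel_size_um=pixel_size_um,
                              min_aspect_ratio=min_aspect_ratio)


@dataclass
class OrientationHistogram:
    """Axial orientation histogram with FWHM and band fractions.

    bin_edges span (-90, 90] degrees relative to the reference axis;
    band_fractions are the fractions of cells within 0-30, 30-60 and
    60-90 degrees (axial distance) of the axis and sum to 1.
    """
    bin_edges_deg: np.ndarray
    counts: np.ndarray
    fwhm_deg: float
    band_fractions: np.ndarray
    reference_axis_deg: float


def _histogram_fwhm(centers: np.ndarray, counts: np.ndarray,
                    bin_width: float) -> float:
    """FWHM (deg) of a wrapped axial histogram by linear interpolation
    between bin centers around the modal peak; 180 if no bin drops below
    half max."""
    n = counts.size
    peak = int(np.argmax(counts))
    half = counts[peak] / 2.0
    if not np.any(counts < half):
        return 180.0

    def cross(direction: int) -> float:
        """Offset (deg, > 0) from the peak center to the half-max crossing."""
        prev = peak
        for step in range(1, n + 1):
            idx = (peak + direction * step) % n
            if counts[idx] < half:
                frac = (counts[prev] - half) / (counts[prev] - counts[idx])
                return (step - 1 + frac) * bin_width
            prev = idx
        return n * bin_width / 2.0

    return float(min(cross(+1) + cross(-1), 180.0))


def orientation_histogram(angles_deg, bin_width_deg: float = 10.0,
                          reference_axis_deg: float = 0.0
                          ) -> OrientationHistogram:
    """Axial histogram of orientations centered on a reference axis.

    Requires at least 10 angles (the FWHM of smaller samples is
    unstable). The FWHM follows the modal peak with wrap-around at +/-90
    degrees; a distribution that never falls below half max has FWHM 180
    by convention.
    """
    angles = np.asarray(angles_deg, dtype=float)
    angles = angles[~np.isnan(angles)]
    if angles.size < 10:
        raise ValueError(
            f"need >= 10 angles for a stable FWHM, got {angles.size}")
    if not np.isclose(180.0 / bin_width_deg, round(180.0 / bin_width_deg)):
        raise ValueError("bin width must divide 180 degrees")
    rel = wrap_axial(angles - reference_axis_deg)
    edges = np.arange(-90.0, 90.0 + bin_width_deg / 2.0, bin_width_deg)
    counts, _ = np.histogram(rel, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    fwhm = _histogram_fwhm(centers, counts.astype(float), bin_width_deg)
    bands = angular_stratification(angles, reference_axis_deg)
    return OrientationHistogram(bin_edges_deg=edges, counts=counts,
                                fwhm_deg=fwhm, band_fractions=bands,
                                reference_axis_deg=reference_axis_deg)


def angular_stratification(angles_deg, reference_axis_deg: float = 0.0
                           ) -> np.ndarray:
    """Fractions of cells within [0, 30), [30, 60) and [60, 90] degrees
    (axial distance) of the reference axis; sums to 1 exactly."""
    angles = np.asarray(angles_deg, dtype=float)
    angles = angles[~np.isnan(angles)]
    if angles.size == 0:
        raise ValueError("need at least one angle")
    d = axial_difference(angles, reference_axis_deg)
    f1 = np.count_nonzero(d < 30.0)
    f2 = np.count_nonzero((d >= 30.0) & (d < 60.0))
    f3 = angles.size - f1 - f2
    return np.array([f1, f2, f3], dtype=float) / angles.size


def split_nuclei(mask: np.ndarray, nucleus_radius_px: float,
                 h_fraction: float = 0.3) -> np.ndarray:
    """Watershed-split touching nuclei in a binary mask.

    Markers are the h-maxima (h = ``h_fraction`` x nucleus radius) of the
    Euclidean distance transform; the watershed of the inverted transform
    then separates overlapping nuclei. Returns a label image.
    """
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    edt = ndimage.distance_transform_edt(mask)
    h = max(h_fraction * nucleus_radius_px, 1.0)
    hmax = morphology.h_maxima(edt, h)
    markers = measure.label(hmax)
    if markers.max() == 0:
        markers = measure.label(mask)
    return segmentation.watershed(-edt, markers, mask=mask).astype(np.int32)


@dataclass(frozen=True)
class ViabilityResult:
    n_total: int
    n_pi_positive: int

    @property
    def percent_dead(self) -> float:
        return 100.0 * self.n_pi_positive / self.n_total


def viability(hoechst, pi, pixel_size_um: float = 0.5,
              nucleus_radius_um: float = 5.0,
              min_area_um2: float = 20.0,
              pi_sd_factor: float = 3.0) -> ViabilityResult:
    """Percent PI-positive nuclei from co-registered Hoechst / PI channels.

    Nuclei are segmented on the Hoechst channel (Otsu threshold, size
    filter, watershed split of touching nuclei); a nucleus is called
    PI-positive when its mean PI intensity exceeds the PI background mean
    by ``pi_sd_factor`` background standard deviations. Raises if the two
    channels differ in shape or no nuclei are found.
    """
    hoechst = np.asarray(hoechst, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if hoechst.shape != pi.shape:
        raise ValueError("Hoechst and PI channels must have the same shape")
    if hoechst.max() == hoechst.min():
        raise ValueError("no nuclei detected in the Hoechst channel")
    t = filters.threshold_otsu(hoechst)
    mask = hoechst > t
    min_px = max(int(min_area_um2 / pixel_size_um ** 2), 1)
    mask = morphology.remove_small_objects(mask, max_size=min_px - 1)
    labels = split_nuclei(mask, nucleus_radius_um / pixel_size_um)
    n = int(labels.max())
    if n == 0:
        raise ValueError("no nuclei detected in the Hoechst channel")

    background = pi[~ndimage.binary_dilation(mask, morphology.disk(3))]
    thresh = background.mean() + pi_sd_factor * background.std()
    means = ndimage.mean(pi, labels=labels, index=np.arange(1, n + 1))
    n_pos = int(np.count_nonzero(means > thresh))
    return ViabilityResult(n_total=n, n_pi_positive=n_pos)
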