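"""Spheroid outgrowth segmentation, classification and migration metrics.

The pipeline mirrors the standard spheroid-invasion workflow for
fiber-reinforced hydrogels: maximum-project the nuclei and F-actin
channels, threshold and size-filter each, delimit the spheroid body with an
ellipsoidal ROI (automatic moment fit, or a user-supplied ellipse),
partition the remaining actin into connected outgrowths, flag each as
contiguous (touching the body) or disconnected, split and count nuclei
within outgrowths, and classify disconnected outgrowths as multicellular
clusters or single cells. Migration distance is the Euclidean distance of
each migratory nucleus from the body periphery; maximum invasion depth is
the deepest point of an outgrowth's mask. Populations of spheroids are
aggregated into body-centered occupancy heatmaps and rose histograms of
migratory-nucleus angular positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import filters, measure, morphology

from .cell_morphometry import split_nuclei
from .ellipse import Ellipse

logger = logging.getLogger(__name__)

__all__ = [
    "Outgrowth", "SpheroidResult", "PopulationAggregate",
    "project_stack", "preprocess_channel", "segment_body",
    "segment_outgrowths", "segment_nuclei", "classify_outgrowths",
    "migration_metrics", "analyze_scene", "aggregate_population",
    "export_results", "read_results",
]

# default inflation of the body ellipse when masking it out: approximates a
# generously drawn covering ROI without moving the measured periphery
BODY_INFLATION = 1.05
CONTIG_TOL_PX = 2.0


def project_stack(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection over Z.

    stack: (C, Z, Y, X) or (C, Y, X); returns (C, Y, X). A single-plane
    stack projects to itself.
    """
    a = np.asarray(stack)
    if a.ndim == 3:
        return a
    if a.ndim != 4:
        raise ValueError(f"expected (C, Z, Y, X) or (C, Y, X), got {a.shape}")
    return a.max(axis=1)


def preprocess_channel(image, pixel_size_um: float,
                       min_object_area_um2: float = 50.0,
                       threshold: float = None) -> np.ndarray:
    """Otsu-threshold and size-filter one channel into a binary mask."""
    img = np.asarray(image, dtype=float)
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=bool)
    t = filters.threshold_otsu(img) if threshold is None else threshold
    mask = img > t
    min_px = max(int(min_object_area_um2 / pixel_size_um ** 2), 1)
    return morphology.remove_small_objects(mask, max_size=min_px - 1)


def segment_body(actin_mask: np.ndarray, pixel_size_um: float,
                 user_roi: Optional[Ellipse] = None,
                 min_body_area_um2: float = 5000.0,
                 opening_radius_um: float = 8.0) -> Ellipse:
    """Spheroid-body ellipse: user ROI verbatim, or automatic moment fit.

    The automatic path opens the mask with a disk sized to erase
    strand-scale protrusions, takes the largest remaining component and
    fits its second-moment equivalent ellipse — replacing the original
    hand-drawn ROI with a reproducible equivalent. Raises when no
    body-scale component exists.
    """
    if user_roi is not None:
        return user_roi
    r = max(int(round(opening_radius_um / pixel_size_um)), 1)
    opened = ndimage.binary_opening(actin_mask, morphology.disk(r))
    labels = measure.label(opened)
    regions = measure.regionprops(labels)
    min_px = min_body_area_um2 / pixel_size_um ** 2
    regions = [rg for rg in regions if rg.area >= min_px]
    if not regions:
        raise ValueError("no spheroid detected (no body-scale component)")
    if len(regions) > 1:
        logger.warning("multiple body-scale components; using the largest")
    region = max(regions, key=lambda rg: rg.area)
    ys, xs = region.coords[:, 0].astype(float), region.coords[:, 1].astype(float)
    cx, cy = xs.mean(), ys.mean()
    mu20, mu02 = np.var(xs), np.var(ys)
    mu11 = np.mean((xs - cx) * (ys - cy))
    common = np.hypot(mu20 - mu02, 2.0 * mu11)
    lam1 = (mu20 + mu02 + common) / 2.0
    lam2 = (mu20 + mu02 - common) / 2.0
    theta = 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)
    # second-moment equivalent ellipse: semi-axis = 2 sqrt(lambda)
    return Ellipse(cx, cy, 2.0 * np.sqrt(lam1), 2.0 * np.sqrt(max(lam2, 1e-6)),
                   np.rad2deg(theta))


def segment_outgrowths(actin_mask: np.ndarray, body: Ellipse,
                       inflation: float = BODY_INFLATION,
                       contiguity_tol_px: float = CONTIG_TOL_PX):
    """Partition extra-body actin into labeled outgrowths with contiguity.

    The (inflated) body-ellipse interior is subtracted; 8-connected
    components of the remainder are outgrowths. An outgrowth is contiguous
    when its mask, dilated by the contiguity tolerance, reaches back into
    the inflated body ellipse — bridging single-pixel segmentation gaps
    without merging genuinely disconnected objects.

    Returns (labels, contiguous) where contiguous maps label -> bool.
    """
    interior = body.interior_mask(actin_mask.shape, scale=inflation)
    outside = actin_mask & ~interior
    labels = measure.label(outside, connectivity=2)
    selem = morphology.disk(max(int(round(contiguity_tol_px)), 1))
    contiguous = {}
    for region in measure.regionprops(labels):
        y0, x0, y1, x1 = region.bbox
        pad = selem.shape[0] // 2
        ys = slice(max(y0 - pad, 0), min(y1 + pad, actin_mask.shape[0]))
        xs = slice(max(x0 - pad, 0), min(x1 + pad, actin_mask.shape[1]))
        local = labels[ys, xs] == region.label
        dil = ndimage.binary_dilation(local, selem)
        contiguous[region.label] = bool((dil & interior[ys, xs]).any())
    return labels, contiguous


def segment_nuclei(nuclei_mask: np.ndarray, nucleus_radius_px: float
                   ) -> np.ndarray:
    """Centroids (x, y) of watershed-split nuclei; empty (0, 2) if blank."""
    labels = split_nuclei(nuclei_mask, nucleus_radius_px)
    n = int(labels.max())
    if n == 0:
        return np.empty((0, 2))
    cyx = ndimage.center_of_mass(nuclei_mask, labels, np.arange(1, n + 1))
    cyx = np.atleast_2d(np.asarray(cyx, dtype=float))
    return cyx[:, ::-1]          # -> (x, y)


@dataclass
class Outgrowth:
    """One classified outgrowth with its migratory nuclei."""
    index: int
    label: int
    contiguous: bool
    phenotype: str               # strand | cluster | single
    nuclei_xy: np.ndarray        # (n, 2) centroids, px
    n_nuclei: int
    area_um2: float
    nucleus_distances_um: np.ndarray
    max_depth_um: float


def classify_outgrowths(labels: np.ndarray, contiguous: dict,
                        centroids_xy: np.ndarray, body: Ellipse,
                        inflation: float = BODY_INFLATION
                        ) -> tuple:
    """Assign nuclei to outgrowths and call migration phenotypes.

    Nuclei inside the (inflated) body ellipse are body nuclei; every other
    nucleus is assigned to the outgrowth with the nearest mask pixel (the
    nearer mask wins when a nucleus is within reach of two outgrowths).
    Phenotypes: contiguous -> strand; disconnected with one nucleus ->
    single, with two or more -> cluster.

    Returns (outgrowth records without metrics, body_nuclei_xy).
    """
    centroids_xy = np.asarray(centroids_xy, dtype=float).reshape(-1, 2)
    in_body = body.contains(centroids_xy, scale=inflation) \
        if centroids_xy.size else np.zeros(0, dtype=bool)
    body_nuclei = centroids_xy[in_body]
    free = centroids_xy[~in_body]

    label_ids = sorted(contiguous)
    assigned = {lab: [] for lab in label_ids}
    if free.size and label_ids:
        ys, xs = np.nonzero(labels)
        tree = cKDTree(np.column_stack([xs, ys]))
        dist, idx = tree.query(free)
        pix_labels = labels[ys[idx], xs[idx]]
        for p, lab in zip(free, pix_labels):
            assigned[int(lab)].append(p)
    elif free.size:
        # nuclei outside the body but no outgrowth mask at all: count them
        # with the body so nucleus conservation holds
        body_nuclei = centroids_xy

    records = []
    for i, lab in enumerate(label_ids):
        nuc = np.array(assigned[lab]).reshape(-1, 2)
        n = nuc.shape[0]
        if contiguous[lab]:
            phenotype = "strand"
        elif n >= 2:
            phenotype = "cluster"
        else:
            phenotype = "single"
        records.append(Outgrowth(
            index=i, label=lab, contiguous=contiguous[lab],
            phenotype=phenotype, nuclei_xy=nuc, n_nuclei=n,
            area_um2=np.nan, nucleus_distances_um=np.empty(0),
            max_depth_um=np.nan))
    return records, body_nuclei


@dataclass
class SpheroidResult:
    """Full analysis of one spheroid scene."""
    body: Ellipse
    outgrowths: list
    n_body_nuclei: int
    pixel_size_um: float
    actin_mask: np.ndarray = None
    spheroid_id: str = ""
    n_detected_nuclei: int = -1   # total nuclei found by segment_nuclei

    @property
    def n_migratory_cells(self) -> int:
        return sum(o.n_nuclei for o in self.outgrowths)

    def totals(self, contiguous: Optional[bool] = None) -> dict:
        sel = [o for o in self.outgrowths
               if contiguous is None or o.contiguous == contiguous]
        return {
            "n_outgrowths": len(sel),
            "n_migratory_cells": sum(o.n_nuclei for o in sel),
            "total_migration_distance_um":
                float(sum(o.nucleus_distances_um.sum() for o in sel)),
            "max_invasion_depth_um":
                float(max((o.max_depth_um for o in sel), default=0.0)),
        }

    def migratory_nuclei_xy(self) -> np.ndarray:
        arrs = [o.nuclei_xy for o in self.outgrowths if o.n_nuclei]
        return np.concatenate(arrs) if arrs else np.empty((0, 2))


def migration_metrics(records: Sequence[Outgrowth], body: Ellipse,
                      labels: np.ndarray, pixel_size_um: float,
                      n_body_nuclei: int = 0,
                      actin_mask: Optional[np.ndarray] = None,
                      spheroid_id: str = "",
                      n_detected_nuclei: int = -1) -> SpheroidResult:
    """Fill in distances, areas and depths; wrap into a SpheroidResult.

    Per-nucleus migration distance is the Euclidean distance from the
    nucleus centroid to the nearest point of the body ellipse (the
    spheroid periphery); an outgrowth's maximum depth is the largest such
    distance over its mask pixels; areas are mask areas in um^2.
    """
    boundary_tree = cKDTree(body.boundary())
    for o in records:
        mask_idx = labels == o.label
        ys, xs = np.nonzero(mask_idx)
        o.area_um2 = float(ys.size) * pixel_size_um ** 2
        if ys.size:
            d, _ = boundary_tree.query(np.column_stack([xs, ys]))
            o.max_depth_um = float(d.max()) * pixel_size_um
        else:
            o.max_depth_um = 0.0
        if o.n_nuclei:
            d, _ = boundary_tree.query(o.nuclei_xy)
            o.nucleus_distances_um = d * pixel_size_um
        else:
            o.nucleus_distances_um = np.empty(0)
    return SpheroidResult(body=body, outgrowths=list(records),
                          n_body_nuclei=n_body_nuclei,
                          pixel_size_um=pixel_size_um,
                          actin_mask=actin_mask, spheroid_id=spheroid_id,
                          n_detected_nuclei=n_detected_nuclei)


def analyze_scene(nuclei_image, actin_image, pixel_size_um: float,
                  user_roi: Optional[Ellipse] = None,
                  nucleus_radius_um: float = 5.0,
                  nuclei_min_area_um2: float = 20.0,
                  actin_min_area_um2: float = 50.0,
                  spheroid_id: str = "") -> SpheroidResult:
    """Run the full single-spheroid pipeline on a 2D two-channel scene."""
    nmask = preprocess_channel(nuclei_image, pixel_size_um,
                               nuclei_min_area_um2)
    amask = preprocess_channel(actin_image, pixel_size_um,
                               actin_min_area_um2)
    body = segment_body(amask, pixel_size_um, user_roi=user_roi)
    labels, contiguous = segment_outgrowths(amask, body)
    centroids = segment_nuclei(nmask, nucleus_radius_um / pixel_size_um)
    records, body_nuclei = classify_outgrowths(labels, contiguous,
                                               centroids, body)
    return migration_metrics(records, body, labels, pixel_size_um,
                             n_body_nuclei=body_nuclei.shape[0],
                             actin_mask=amask, spheroid_id=spheroid_id,
                             n_detected_nuclei=centroids.shape[0])


@dataclass
class PopulationAggregate:
    """Population summary over registered spheroids.

    heatmap: pixelwise sum of body-centered binarized actin masks (counts
    <= number of spheroids). rose_counts: counts of migratory-nucleus
    polar angles about the body center in ``rose_bin_deg``-degree bins
    over the full circle.
    """
    heatmap: np.ndarray
    rose_bin_edges_deg: np.ndarray
    rose_counts: np.ndarray
    n_spheroids: int

    def axial_fraction(self, half_width_deg: float = 30.0,
                       axis_deg: float = 0.0) -> float:
        """Fraction of migratory nuclei within +/- half_width of the axis,
        pooling both axial directions."""
        centers = (self.rose_bin_edges_deg[:-1]
                   + self.rose_bin_edges_deg[1:]) / 2.0
        d = np.abs((centers - axis_deg + 180.0) % 360.0 - 180.0)
        axial = np.minimum(d, 180.0 - d)
        total = self.rose_counts.sum()
        if total == 0:
            return float("nan")
        return float(self.rose_counts[axial <= half_width_deg].sum() / total)


def aggregate_population(results: Sequence[SpheroidResult],
                         rose_bin_deg: float = 10.0) -> PopulationAggregate:
    """Register spheroids to a common body-centered origin and aggregate.

    Registration is translation-only (the alignment axis is shared across
    a condition); binarized actin masks are summed pixelwise into an
    occupancy heatmap, and the polar angles of all migratory nuclei about
    their body centers populate the rose histogram.
    """
    if not results:
        raise ValueError("need at least one spheroid result")
    shapes = [r.actin_mask.shape for r in results]
    h = max(s[0] for s in shapes)
    w = max(s[1] for s in shapes)
    heat = np.zeros((2 * h + 1, 2 * w + 1), dtype=np.int32)
    angles = []
    for r in results:
        cy, cx = int(round(r.body.cy)), int(round(r.body.cx))
        mh, mw = r.actin_mask.shape
        y0 = h - cy
        x0 = w - cx
        heat[y0:y0 + mh, x0:x0 + mw] += r.actin_mask.astype(np.int32)
        nuc = r.migratory_nuclei_xy()
        if nuc.size:
            dx = nuc[:, 0] - r.body.cx
            dy = nuc[:, 1] - r.body.cy
            angles.append(np.rad2deg(np.arctan2(dy, dx)) % 360.0)
    angles = np.concatenate(angles) if angles else np.empty(0)
    edges = np.arange(0.0, 360.0 + rose_bin_deg / 2.0, rose_bin_deg)
    counts, _ = np.histogram(angles, bins=edges)
    return PopulationAggregate(heatmap=heat, rose_bin_edges_deg=edges,
                               rose_counts=counts, n_spheroids=len(results))


_EXPORT_COLUMNS = ["spheroid_id", "outgrowth_index", "phenotype",
                   "contiguous", "n_migratory_cells", "area_um2",
                   "total_migration_distance_um", "max_depth_um"]


def results_table(results: Sequence[SpheroidResult]) -> pd.DataFrame:
    """One row per outgrowth plus one TOTAL row per spheroid."""
    rows = []
    for r in results:
        for o in r.outgrowths:
            rows.append({
                "spheroid_id": r.spheroid_id,
                "outgrowth_index": o.index,
                "phenotype": o.phenotype,
                "contiguous": o.contiguous,
                "n_migratory_cells": o.n_nuclei,
                "area_um2": o.area_um2,
                "total_migration_distance_um":
                    float(o.nucleus_distances_um.sum()),
                "max_depth_um": o.max_depth_um,
            })
        tot = r.totals()
        rows.append({
            "spheroid_id": r.spheroid_id,
            "outgrowth_index": -1,
            "phenotype": "TOTAL",
            "contiguous": pd.NA,
            "n_migratory_cells": tot["n_migratory_cells"],
            "area_um2": float(sum(o.area_um2 for o in r.outgrowths)),
            "total_migration_distance_um": tot["total_migration_distance_um"],
            "max_depth_um": tot["max_invasion_depth_um"],
        })
    return pd.DataFrame(rows, columns=_EXPORT_COLUMNS)


def export_results(results: Sequence[SpheroidResult], path,
                   header_comments: Sequence[str] = ()) -> pd.DataFrame:
    """Write the per-outgrowth spreadsheet (CSV, '#' comment header)."""
    table = results_table(results)
    try:
        with open(path, "w", encoding="utf-8") as fh:
            for line in header_comments:
                fh.write(f"# {line}\n")
            table.to_csv(fh, index=False)
    except OSError as exc:
        raise OSError(f"could not write results to {path}: {exc}") from exc
    return table


def read_results(path) -> pd.DataFrame:
    """Round-trip reader for export_results output."""
    return pd.read_csv(path, comment="#")
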