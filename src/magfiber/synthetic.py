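"""Synthetic fluorescence scenes with exact ground truth.

The package's analyses (fiber anisotropy, cell orientation, viability,
spheroid outgrowth migration) were developed for confocal projections of
hydrogel composites containing magnetically aligned electrospun fiber
segments. No public image data exist for these experiments, so this module
generates the four scene types with known per-object truth:

* fiber fields — anti-aliased rods ~2 um in diameter with tunable length
  distributions (photomasked segments with 60-120 um means, or unmasked
  segments averaging 225 um on a 100-550 um support) and tunable axial
  orientation concentration about a mean alignment axis;
* tenocyte-like scenes — elongated spindle (capsule) cells with von Mises
  distributed axial orientations;
* viability scenes — Hoechst/PI nucleus pairs with an exact dead fraction;
* spheroid outgrowth scenes — a dense elliptical body plus contiguous
  strands, disconnected multicellular clusters and disconnected single
  cells at known directions, depths and nucleus counts.

Every generator is a pure function of its spec (identical seed => identical
arrays and truth tables). Truth tables are pandas DataFrames; scenes carry
the noise-free support masks so mask-level recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from .circstats import sample_axial_vonmises
from .ellipse import Ellipse
from . import render

__all__ = [
    "MaskedLengthModel", "UnmaskedLengthModel", "unmasked_length_model",
    "FiberFieldSpec", "FiberScene", "generate_fiber_image",
    "rasterize_fiber_support",
    "TenocyteScene", "generate_tenocyte_image",
    "ViabilityScene", "generate_viability_image",
    "BodySpec", "OutgrowthSpec", "SpheroidSceneSpec", "SceneGroundTruth",
    "SpheroidScene", "generate_spheroid_scene", "random_spheroid_spec",
]

STRAND, CLUSTER, SINGLE = "contiguous_strand", "disconnected_cluster", \
    "disconnected_single"


# ---------------------------------------------------------------------------
# fiber length models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaskedLengthModel:
    """Photomasked fiber segments: approximately normal lengths.

    Photomasking the fiber mats during photocrosslinking yields segment
    populations with means of roughly 60-120 um and low variance; modeled
    as a normal distribution truncated to mean +/- 3 sd (and > 0).
    """
    mean_um: float
    sd_um: float

    def __post_init__(self):
        if self.mean_um <= 0 or self.sd_um <= 0:
            raise ValueError("masked length model needs positive mean and sd")

    @property
    def support(self):
        lo = max(self.mean_um - 3.0 * self.sd_um, 1.0)
        return (lo, self.mean_um + 3.0 * self.sd_um)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        lo, hi = self.support
        a = (lo - self.mean_um) / self.sd_um
        b = (hi - self.mean_um) / self.sd_um
        u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b), n)
        return self.mean_um + self.sd_um * stats.norm.ppf(u)


@dataclass(frozen=True)
class UnmaskedLengthModel:
    """Unmasked fiber segments: truncated lognormal lengths.

    Breaking unmasked fiber mats into segments (vortexing) is an
    uncontrolled process producing a broad, right-skewed length
    distribution between 100 and 550 um; modeled as a lognormal truncated
    to that support.
    """
    log_mean: float
    log_sd: float
    lo_um: float = 100.0
    hi_um: float = 550.0

    def __post_init__(self):
        if not (0 < self.lo_um < self.hi_um):
            raise ValueError("invalid truncation support")
        if self.log_sd <= 0:
            raise ValueError("log_sd must be positive")

    @property
    def support(self):
        return (self.lo_um, self.hi_um)

    def _cdf_bounds(self):
        dist = stats.lognorm(s=self.log_sd, scale=np.exp(self.log_mean))
        return dist, dist.cdf(self.lo_um), dist.cdf(self.hi_um)

    def truncated_mean(self) -> float:
        dist, Flo, Fhi = self._cdf_bounds()
        # E[X | lo < X < hi] for a lognormal, via the shifted-normal CDF
        mu, s = self.log_mean, self.log_sd
        phi = stats.norm.cdf
        zhi = (np.log(self.hi_um) - mu) / s
        zlo = (np.log(self.lo_um) - mu) / s
        num = np.exp(mu + s * s / 2.0) * (phi(zhi - s) - phi(zlo - s))
        return float(num / (Fhi - Flo))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        dist, Flo, Fhi = self._cdf_bounds()
        return dist.ppf(rng.uniform(Flo, Fhi, n))


def unmasked_length_model(mean_um: float = 225.0, lo_um: float = 100.0,
                          hi_um: float = 550.0,
                          log_sd: float = 0.45) -> UnmaskedLengthModel:
    """Truncated lognormal calibrated so the truncated mean equals mean_um.

    Only the mean and range of the unmasked segment population are known;
    log_sd sets the (broad) spread and the log-location is solved
    numerically so that the mean *after truncation* hits the target.
    """
    def err(log_mean):
        m = UnmaskedLengthModel(log_mean, log_sd, lo_um, hi_um)
        return m.truncated_mean() - mean_um

    lo_guess, hi_guess = np.log(lo_um * 0.2), np.log(hi_um * 5.0)
    log_mean = optimize.brentq(err, lo_guess, hi_guess, xtol=1e-10)
    return UnmaskedLengthModel(log_mean, log_sd, lo_um, hi_um)


# ---------------------------------------------------------------------------
# fiber fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FiberFieldSpec:
    """Parameters of a synthetic fiber-field image.

    orientation_kappa is the axial von Mises concentration of fiber axes
    about mean_axis_deg (0 = isotropic); placement "random" drops fibers
    independently (overlaps allowed, as in a dense gel), "spread" uses
    rejection sampling so rendered fibers do not touch (for per-fiber
    length/width calibration scenes).
    """
    n_fibers: int
    length_model: object
    orientation_kappa: float = 0.0
    mean_axis_deg: float = 0.0
    image_shape: tuple = (1024, 1024)
    pixel_size_um: float = 0.5
    diameter_mean_um: float = 2.0
    diameter_cv: float = 0.05
    intensity: float = 1.0
    noise_sd: float = 0.05
    blur_sigma_px: float = 0.8
    placement: str = "random"
    min_gap_um: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.orientation_kappa < 0:
            raise ValueError("orientation_kappa must be >= 0")
        if self.diameter_mean_um <= 0:
            raise ValueError("diameter_mean must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if self.n_fibers < 1:
            raise ValueError("need at least one fiber")
        if self.placement not in ("random", "spread"):
            raise ValueError(f"unknown placement {self.placement!r}")
        _, hi = self.length_model.support
        needed_um = hi + 2.0 * self.diameter_mean_um + 4.0 * self.pixel_size_um
        extent = min(self.image_shape) * self.pixel_size_um
        if extent <= needed_um:
            raise ValueError(
                f"image extent {extent:.0f} um too small to hold a fiber of "
                f"max length {hi:.0f} um; enlarge image_shape")


@dataclass
class FiberScene:
    image: np.ndarray          # float32 intensity image (blurred + noise)
    support: np.ndarray        # bool noise-free support mask
    truth: pd.DataFrame        # per-fiber geometry and dimensions
    spec: FiberFieldSpec


def _place_fibers(spec: FiberFieldSpec, rng: np.random.Generator):
    px = spec.pixel_size_um
    n = spec.n_fibers
    lengths = spec.length_model.sample(rng, n)
    angles = sample_axial_vonmises(rng, spec.orientation_kappa,
                                   spec.mean_axis_deg, n)
    if spec.diameter_cv > 0:
        diam = spec.diameter_mean_um * \
            np.exp(rng.normal(0.0, spec.diameter_cv, n))
    else:
        diam = np.full(n, spec.diameter_mean_um)

    h, w = spec.image_shape
    th = np.deg2rad(angles)
    ux, uy = np.cos(th), np.sin(th)
    half_px = lengths / 2.0 / px
    rad_px = diam / 2.0 / px

    p0s = np.empty((n, 2))
    p1s = np.empty((n, 2))
    gap_px = spec.min_gap_um / px
    max_attempts = 4000
    for i in range(n):
        mx = abs(half_px[i] * ux[i]) + rad_px[i] + 1.0
        my = abs(half_px[i] * uy[i]) + rad_px[i] + 1.0
        if w - 2 * mx <= 0 or h - 2 * my <= 0:
            raise ValueError("image too small to hold a fiber of max length")
        placed = False
        for _ in range(max_attempts):
            cx = rng.uniform(mx, w - mx)
            cy = rng.uniform(my, h - my)
            p0 = (cx - half_px[i] * ux[i], cy - half_px[i] * uy[i])
            p1 = (cx + half_px[i] * ux[i], cy + half_px[i] * uy[i])
            if spec.placement == "spread" and i > 0:
                d = render.segment_segment_distance(p0, p1, p0s[:i], p1s[:i])
                if np.any(d < rad_px[i] + rad_px[:i] + gap_px):
                    continue
            p0s[i], p1s[i] = p0, p1
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place fiber {i} after {max_attempts} attempts; "
                "fiber density too high for non-overlapping placement")
    return p0s, p1s, lengths, angles, diam, rad_px


def generate_fiber_image(spec: FiberFieldSpec) -> FiberScene:
    """Render a fiber field and its per-fiber ground-truth table.

    Truth columns: x0/y0/x1/y1 (segment endpoints, px), angle_deg (axial),
    length_um (tip-to-tip), diameter_um.
    """
    rng = np.random.default_rng(spec.seed)
    p0s, p1s, lengths, angles, diam, rad_px = _place_fibers(spec, rng)

    img = np.zeros(spec.image_shape, dtype=np.float64)
    for i in range(spec.n_fibers):
        render.draw_capsule(img, p0s[i], p1s[i], rad_px[i], spec.intensity)
    support = img > 0

    if spec.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma_px)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)

    truth = pd.DataFrame({
        "fiber": np.arange(spec.n_fibers),
        "x0": p0s[:, 0], "y0": p0s[:, 1],
        "x1": p1s[:, 0], "y1": p1s[:, 1],
        "angle_deg": angles,
        # tip-to-tip extent includes the two hemispherical caps
        "length_um": lengths + diam,
        "core_length_um": lengths,
        "diameter_um": diam,
    })
    return FiberScene(image=img.astype(np.float32), support=support,
                      truth=truth, spec=spec)


def rasterize_fiber_support(truth: pd.DataFrame, image_shape,
                            pixel_size_um: float) -> np.ndarray:
    """Re-rasterize the noise-free support from a fiber truth table."""
    img = np.zeros(image_shape, dtype=np.float64)
    for row in truth.itertuples():
        rad_px = row.diameter_um / 2.0 / pixel_size_um
        render.draw_capsule(img, (row.x0, row.y0), (row.x1, row.y1), rad_px)
    return img > 0


# ---------------------------------------------------------------------------
# tenocyte scenes
# ---------------------------------------------------------------------------

@dataclass
class TenocyteScene:
    image: np.ndarray
    support: np.ndarray
    truth: pd.DataFrame
    pixel_size_um: float


def generate_tenocyte_image(n_cells: int, orientation_kappa: float,
                            aspect_ratio: float, seed: int,
                            mean_axis_deg: float = 0.0,
                            image_shape: tuple = (1600, 1600),
                            pixel_size_um: float = 0.5,
                            cell_width_um: float = 12.0,
                            intensity: float = 1.0,
                            noise_sd: float = 0.05,
                            blur_sigma_px: float = 1.0) -> TenocyteScene:
    """Non-overlapping spindle-shaped (capsule) cells with known axes.

    aspect_ratio is tip-to-tip length over width; aspect_ratio = 1 renders
    round cells whose orientation is undefined (truth flags them
    isotropic). Placement is rejection sampling; over-dense requests raise
    an error naming the density limit.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if aspect_ratio < 1:
        raise ValueError("aspect_ratio must be >= 1")
    rng = np.random.default_rng(seed)
    px = pixel_size_um
    length_um = aspect_ratio * cell_width_um
    len_px = length_um / px
    wid_px = cell_width_um / px
    rad_px = wid_px / 2.0
    h, w = image_shape

    isotropic = aspect_ratio <= 1.0 + 1e-9
    angles = sample_axial_vonmises(rng, orientation_kappa, mean_axis_deg,
                                   n_cells)
    p0s = np.empty((n_cells, 2))
    p1s = np.empty((n_cells, 2))
    centers = np.empty((n_cells, 2))
    gap_px = 2.0
    max_attempts = 400
    margin = len_px / 2.0 + 2.0
    if w - 2 * margin <= 0 or h - 2 * margin <= 0:
        raise ValueError("image too small for the requested cell length")
    for i in range(n_cells):
        for attempt in range(max_attempts):
            c = np.array([rng.uniform(margin, w - margin),
                          rng.uniform(margin, h - margin)])
            p0, p1, _ = render.capsule_from_axis(c, len_px, angles[i], wid_px)
            if i > 0:
                d = render.segment_segment_distance(p0, p1, p0s[:i], p1s[:i])
                if np.any(d < wid_px + gap_px):
                    continue
            p0s[i], p1s[i], centers[i] = p0, p1, c
            break
        else:
            area_frac = (i * length_um * cell_width_um
                         / (h * w * px * px))
            raise RuntimeError(
                f"cell packing failed at cell {i}/{n_cells} "
                f"(~{area_frac:.0%} area fraction); reduce n_cells or "
                "enlarge the image")

    img = np.zeros(image_shape, dtype=np.float64)
    for i in range(n_cells):
        render.draw_capsule(img, p0s[i], p1s[i], rad_px, intensity)
    support = img > 0
    if blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, blur_sigma_px)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)

    truth = pd.DataFrame({
        "cell": np.arange(n_cells),
        "x_px": centers[:, 0], "y_px": centers[:, 1],
        "angle_deg": np.where(isotropic, np.nan, angles),
        "aspect_ratio": aspect_ratio,
        "isotropic": isotropic,
    })
    return TenocyteScene(image=img.astype(np.float32), support=support,
                         truth=truth, pixel_size_um=px)


# ---------------------------------------------------------------------------
# viability scenes
# ---------------------------------------------------------------------------

@dataclass
class ViabilityScene:
    hoechst: np.ndarray
    pi: np.ndarray
    truth: pd.DataFrame
    pixel_size_um: float


def generate_viability_image(n_nuclei: int, dead_fraction: float, seed: int,
                             image_shape: tuple = (1024, 1024),
                             pixel_size_um: float = 0.5,
                             nucleus_radius_um: float = 5.0,
                             intensity: float = 1.0,
                             noise_sd: float = 0.05,
                             blur_sigma_px: float = 1.0) -> ViabilityScene:
    """Hoechst + PI channel pair with an exact number of dead nuclei.

    Exactly round(n_nuclei * dead_fraction) nuclei (banker's rounding)
    carry PI signal. All nuclei appear in the Hoechst channel. Nucleus
    centers keep >= 2.1 radii spacing so truth counts are recoverable.
    """
    if not 0.0 <= dead_fraction <= 1.0:
        raise ValueError("dead_fraction must be in [0, 1]")
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    rng = np.random.default_rng(seed)
    px = pixel_size_um
    r_px = nucleus_radius_um / px
    h, w = image_shape
    margin = r_px + 2.0

    centers = np.empty((n_nuclei, 2))
    min_d = 2.1 * r_px
    max_attempts = 2000
    for i in range(n_nuclei):
        for attempt in range(max_attempts):
            c = np.array([rng.uniform(margin, w - margin),
                          rng.uniform(margin, h - margin)])
            if i > 0 and np.min(np.linalg.norm(centers[:i] - c, axis=1)) < min_d:
                continue
            centers[i] = c
            break
        else:
            raise RuntimeError(
                f"nucleus packing failed at {i}/{n_nuclei}; too dense")

    n_dead = round(n_nuclei * dead_fraction)
    dead = np.zeros(n_nuclei, dtype=bool)
    dead[rng.choice(n_nuclei, size=n_dead, replace=False)] = True

    hoechst = np.zeros(image_shape, dtype=np.float64)
    pi = np.zeros(image_shape, dtype=np.float64)
    for i in range(n_nuclei):
        render.draw_disk(hoechst, centers[i], r_px, intensity)
        if dead[i]:
            render.draw_disk(pi, centers[i], r_px, intensity)
    if blur_sigma_px > 0:
        hoechst = ndimage.gaussian_filter(hoechst, blur_sigma_px)
        pi = ndimage.gaussian_filter(pi, blur_sigma_px)
    if noise_sd > 0:
        hoechst = hoechst + rng.normal(0.0, noise_sd, image_shape)
        pi = pi + rng.normal(0.0, noise_sd, image_shape)

    truth = pd.DataFrame({
        "nucleus": np.arange(n_nuclei),
        "x_px": centers[:, 0], "y_px": centers[:, 1],
        "dead": dead,
    })
    return ViabilityScene(hoechst=hoechst.astype(np.float32),
                          pi=pi.astype(np.float32), truth=truth,
                          pixel_size_um=px)


# ---------------------------------------------------------------------------
# spheroid scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BodySpec:
    """Spheroid body: ellipse (px) densely packed with nuclei."""
    cx_px: float
    cy_px: float
    a_px: float
    b_px: float
    n_nuclei: int = 60
    angle_deg: float = 0.0

    def ellipse(self) -> Ellipse:
        return Ellipse(self.cx_px, self.cy_px, self.a_px, self.b_px,
                       self.angle_deg)


@dataclass(frozen=True)
class OutgrowthSpec:
    """One outgrowth: a strand (contiguous), cluster or single cell.

    direction_deg is the polar angle of the outgrowth path about the body
    center (0-360); path_length_um the radial extent of the structure;
    gap_to_body_um the clearance between the body boundary and the nearest
    point of the structure (0 for strands, by definition).
    """
    kind: str
    direction_deg: float
    path_length_um: float
    n_nuclei: int
    gap_to_body_um: float = 0.0

    def __post_init__(self):
        if self.kind not in (STRAND, CLUSTER, SINGLE):
            raise ValueError(f"unknown outgrowth class {self.kind!r}")
        if self.n_nuclei < 1:
            raise ValueError("every outgrowth carries at least one nucleus")
        if (self.kind == SINGLE) != (self.n_nuclei == 1) and \
                self.kind != STRAND:
            raise ValueError(
                "disconnected_single must have exactly 1 nucleus and "
                "disconnected_cluster at least 2")
        if (self.gap_to_body_um == 0.0) != (self.kind == STRAND):
            raise ValueError(
                "gap_to_body must be 0 exactly for contiguous strands and "
                "positive for disconnected outgrowths")
        if self.path_length_um <= 0:
            raise ValueError("path_length must be positive")


@dataclass(frozen=True)
class SpheroidSceneSpec:
    body: BodySpec
    outgrowths: Sequence[OutgrowthSpec] = field(default_factory=tuple)
    image_shape: tuple = (768, 768)
    pixel_size_um: float = 1.0
    nucleus_radius_um: float = 5.0
    strand_width_um: float = 14.0
    direction_kappa: float = 0.0     # metadata: concentration used to draw
    psf_sigma_px: float = 1.0        # outgrowth directions, if sampled
    noise_sd: float = 0.04
    intensity: float = 1.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "outgrowths", tuple(self.outgrowths))
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")


@dataclass
class SceneGroundTruth:
    """Per-object truth for one spheroid scene.

    outgrowths: one row per outgrowth (index, class, n_nuclei, area_um2,
    max_depth_um, direction_deg). nuclei: one row per nucleus with its
    centroid (px) and distance to the body boundary (um); body nuclei have
    outgrowth = -1 and distance 0. totals: scene-level sums, stratified by
    contiguity.
    """
    outgrowths: pd.DataFrame
    nuclei: pd.DataFrame
    totals: dict
    body: Ellipse
    outgrowth_masks: dict


@dataclass
class SpheroidScene:
    nuclei: np.ndarray
    actin: np.ndarray
    support_nuclei: np.ndarray
    support_actin: np.ndarray
    truth: SceneGroundTruth
    spec: SpheroidSceneSpec


def _ray_boundary_point(body: Ellipse, direction_deg: float):
    """Boundary point of the body ellipse along a ray from its center."""
    th = np.deg2rad(direction_deg)
    u = np.array([np.cos(th), np.sin(th)])
    # works for the rotated case by transforming the ray into ellipse frame
    phi = np.deg2rad(body.angle_deg)
    ct, st = np.cos(phi), np.sin(phi)
    uu = u[0] * ct + u[1] * st
    vv = -u[0] * st + u[1] * ct
    t = 1.0 / np.sqrt((uu / body.a) ** 2 + (vv / body.b) ** 2)
    return np.array([body.cx, body.cy]) + t * u, u


def generate_spheroid_scene(spec: SpheroidSceneSpec) -> SpheroidScene:
    """Render a two-channel (nuclei, actin) spheroid scene with ground truth."""
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size_um
    body = spec.body.ellipse()
    h, w = spec.image_shape
    r_px = spec.nucleus_radius_um / px
    strand_w_px = spec.strand_width_um / px

    actin = np.zeros(spec.image_shape, dtype=np.float64)
    nucimg = np.zeros(spec.image_shape, dtype=np.float64)

    render.draw_ellipse(actin, (body.cx, body.cy), (body.a, body.b),
                        body.angle_deg, spec.intensity)

    # body nuclei: uniform in the ellipse (overlap allowed, as in projection)
    n_body = spec.body.n_nuclei
    body_pts = np.empty((n_body, 2))
    got = 0
    while got < n_body:
        cand = np.column_stack([
            rng.uniform(body.cx - body.a, body.cx + body.a, n_body),
            rng.uniform(body.cy - body.b, body.cy + body.b, n_body)])
        ok = body.contains(cand, scale=0.92)   # keep centers off the rim
        take = min(n_body - got, int(ok.sum()))
        body_pts[got:got + take] = cand[ok][:take]
        got += take
    for p in body_pts:
        render.draw_disk(nucimg, p, r_px, spec.intensity)

    out_rows = []
    nuc_rows = [{"outgrowth": -1, "x_px": p[0], "y_px": p[1],
                 "distance_um": 0.0} for p in body_pts]
    masks = {}

    for idx, og in enumerate(spec.outgrowths):
        P, u = _ray_boundary_point(body, og.direction_deg)
        gap_px = og.gap_to_body_um / px
        path_px = og.path_length_um / px
        end = P + (gap_px + path_px) * u
        if not (0 <= end[0] < w and 0 <= end[1] < h):
            raise ValueError(
                f"outgrowth {idx} exits the image bounds; use a larger canvas")

        layer = np.zeros(spec.image_shape, dtype=np.float64)
        if og.kind == STRAND:
            # start slightly inside the body so the strand is truly contiguous
            p0 = P - (strand_w_px / 2.0) * u
            p1 = P + (path_px - strand_w_px / 2.0) * u
            render.draw_capsule(layer, p0, p1, strand_w_px / 2.0,
                                spec.intensity)
        elif og.kind == CLUSTER:
            wid = strand_w_px * 1.3
            p0 = P + (gap_px + wid / 2.0) * u
            p1 = P + (gap_px + path_px - wid / 2.0) * u
            render.draw_capsule(layer, p0, p1, wid / 2.0, spec.intensity)
        else:  # single cell
            c = P + (gap_px + path_px / 2.0) * u
            semi_minor = max(strand_w_px * 0.6 / 2.0, r_px * 1.1)
            render.draw_ellipse(layer, c, (path_px / 2.0, semi_minor),
                                og.direction_deg, spec.intensity)
        mask = layer > 0
        masks[idx] = mask
        np.maximum(actin, layer, out=actin)

        # nuclei along the path, spacing >= ~2 radii so counts are recoverable
        n = og.n_nuclei
        lo_s = gap_px + 1.1 * r_px
        hi_s = gap_px + path_px - 1.1 * r_px
        if og.kind == SINGLE:
            offsets = np.array([gap_px + path_px / 2.0])
        else:
            if hi_s <= lo_s:
                raise ValueError(f"outgrowth {idx} too short for its nuclei")
            base = np.linspace(lo_s, hi_s, n)
            spacing = (hi_s - lo_s) / max(n - 1, 1)
            if n > 1 and spacing < 2.05 * r_px:
                raise ValueError(
                    f"outgrowth {idx}: {n} nuclei do not fit in "
                    f"{og.path_length_um:.0f} um at >= 1 diameter spacing")
            jit = min(0.2 * max(spacing - 2.05 * r_px, 0.0), 2.0)
            offsets = base + rng.uniform(-jit, jit, n)
        lateral_room = max(strand_w_px / 2.0 - r_px - 1.0, 0.0)
        v = np.array([-u[1], u[0]])
        for s in offsets:
            lat = rng.uniform(-lateral_room, lateral_room)
            p = P + s * u + lat * v
            render.draw_disk(nucimg, p, r_px, spec.intensity)
            nuc_rows.append({
                "outgrowth": idx, "x_px": p[0], "y_px": p[1],
                "distance_um": float(body.distance(p[None, :])[0]) * px,
            })

        ys, xs = np.nonzero(mask)
        depths = body.distance(np.column_stack([xs, ys])) * px
        out_rows.append({
            "outgrowth": idx, "cls": og.kind,
            "contiguous": og.kind == STRAND,
            "n_nuclei": og.n_nuclei,
            "area_um2": float(mask.sum()) * px * px,
            "max_depth_um": float(depths.max()),
            "direction_deg": og.direction_deg,
            "gap_to_body_um": og.gap_to_body_um,
            "path_length_um": og.path_length_um,
        })

    support_actin = actin > 0
    support_nuclei = nucimg > 0
    if spec.psf_sigma_px > 0:
        actin = ndimage.gaussian_filter(actin, spec.psf_sigma_px)
        nucimg = ndimage.gaussian_filter(nucimg, spec.psf_sigma_px)
    if spec.noise_sd > 0:
        nucimg = nucimg + rng.normal(0.0, spec.noise_sd, spec.image_shape)
        actin = actin + rng.normal(0.0, spec.noise_sd, spec.image_shape)

    out_df = pd.DataFrame(out_rows, columns=[
        "outgrowth", "cls", "contiguous", "n_nuclei", "area_um2",
        "max_depth_um", "direction_deg", "gap_to_body_um", "path_length_um"])
    nuc_df = pd.DataFrame(nuc_rows)
    mig = nuc_df[nuc_df["outgrowth"] >= 0]
    strata = {}
    contig_flags = out_df["contiguous"].astype(bool)
    for name, sel in [("contiguous", contig_flags),
                      ("disconnected", ~contig_flags)]:
        sub = out_df[sel]
        idxs = set(sub["outgrowth"])
        nucs = mig[mig["outgrowth"].isin(idxs)]
        strata[name] = {
            "n_outgrowths": int(len(sub)),
            "n_migratory_cells": int(sub["n_nuclei"].sum()),
            "total_migration_distance_um": float(nucs["distance_um"].sum()),
            "max_invasion_depth_um":
                float(sub["max_depth_um"].max()) if len(sub) else 0.0,
        }
    totals = {
        "n_outgrowths": int(len(out_df)),
        "n_migratory_cells": int(out_df["n_nuclei"].sum()) if len(out_df) else 0,
        "total_migration_distance_um": float(mig["distance_um"].sum()),
        "max_invasion_depth_um":
            float(out_df["max_depth_um"].max()) if len(out_df) else 0.0,
        "by_contiguity": strata,
    }
    truth = SceneGroundTruth(outgrowths=out_df, nuclei=nuc_df, totals=totals,
                             body=body, outgrowth_masks=masks)
    return SpheroidScene(nuclei=nucimg.astype(np.float32),
                         actin=actin.astype(np.float32),
                         support_nuclei=support_nuclei,
                         support_actin=support_actin,
                         truth=truth, spec=spec)


def random_spheroid_spec(seed: int,
                         direction_kappa: float = 0.0,
                         mean_axis_deg: float = 0.0,
                         n_strands=(1, 2),
                         n_clusters=(0, 2),
                         n_singles=(1, 2),
                         image_shape: tuple = (768, 768),
                         pixel_size_um: float = 1.0,
                         min_separation_deg: float = 15.0,
                         ) -> SpheroidSceneSpec:
    """Draw a randomized scene spec for population-level studies.

    Outgrowth directions follow the axial von Mises law about the
    alignment axis (random polarity per outgrowth, so the full circle is
    populated); a minimum angular separation keeps outgrowths from
    merging, mirroring how distinct outgrowths are scored. The separation
    is kept small (and outgrowth counts modest) so the realized direction
    distribution stays close to the requested law even at high
    concentration. Counts are drawn uniformly from the given inclusive
    ranges.
    """
    rng = np.random.default_rng(seed)
    h, w = image_shape
    a = rng.uniform(70.0, 90.0)
    b = rng.uniform(55.0, 72.0)
    body = BodySpec(cx_px=w / 2.0, cy_px=h / 2.0, a_px=a, b_px=b,
                    n_nuclei=int(rng.integers(50, 75)))

    counts = {
        STRAND: int(rng.integers(n_strands[0], n_strands[1] + 1)),
        CLUSTER: int(rng.integers(n_clusters[0], n_clusters[1] + 1)),
        SINGLE: int(rng.integers(n_singles[0], n_singles[1] + 1)),
    }
    kinds = sum([[k] * v for k, v in counts.items()], [])
    rng.shuffle(kinds)

    directions = []
    for _ in kinds:
        for attempt in range(300):
            axial = sample_axial_vonmises(rng, direction_kappa,
                                          mean_axis_deg, 1)[0]
            d = (axial + 180.0 * rng.integers(0, 2)) % 360.0
            sep = [min(abs(d - e) % 360.0, 360.0 - abs(d - e) % 360.0)
                   for e in directions]
            if not sep or min(sep) >= min_separation_deg:
                directions.append(d)
                break
        else:
            # relax: place wherever the largest gap is
            if directions:
                ds = np.sort(directions)
                gaps = np.diff(np.r_[ds, ds[0] + 360.0])
                gi = int(np.argmax(gaps))
                directions.append((ds[gi] + gaps[gi] / 2.0) % 360.0)
            else:
                directions.append(0.0)

    outgrowths = []
    for kind, d in zip(kinds, directions):
        if kind == STRAND:
            og = OutgrowthSpec(STRAND, d,
                               path_length_um=float(rng.uniform(70, 160)),
                               n_nuclei=int(rng.integers(3, 7)),
                               gap_to_body_um=0.0)
        elif kind == CLUSTER:
            og = OutgrowthSpec(CLUSTER, d,
                               path_length_um=float(rng.uniform(45, 80)),
                               n_nuclei=int(rng.integers(2, 5)),
                               gap_to_body_um=float(rng.uniform(15, 40)))
        else:
            og = OutgrowthSpec(SINGLE, d,
                               path_length_um=float(rng.uniform(18, 26)),
                               n_nuclei=1,
                               gap_to_body_um=float(rng.uniform(15, 60)))
        outgrowths.append(og)

    return SpheroidSceneSpec(body=body, outgrowths=tuple(outgrowths),
                             image_shape=image_shape,
                             pixel_size_um=pixel_size_um,
                             direction_kappa=direction_kappa,
                             seed=int(rng.integers(0, 2 ** 31 - 1)))
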