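"""ROI segmentation and the 32-feature morphometric description of an image.

The pipeline per image is fixed: a small median filter suppresses sensor
noise, an edge detector (variant and thresholds from the calibration
profile) marks cell boundaries, a morphological closing with a disk on the
length scale of a neurite fuses the edge map into regions of interest, and
components below a minimum area are discarded as artifacts. From the raw
intensities, the ROI mask and the per-segment geometry, 32 features are
computed: 12 global intensity/entropy statistics, 10 ROI-level counts and
areas, and the mean and standard deviation over segments of 5 per-segment
shape descriptors. Area features are reported in percent of the image area
(the summed convex-hull area ``caSum`` may exceed 100 because hulls of
different segments can overlap); intensity features in percent of the
maximal representable intensity.

Counts and areas are variance-stabilized before statistical use: features
bounded by the pixel total get the Anscombe arcsine-root transform for
binomial data, unbounded count-like features the square root (which maps a
Poisson variance to approximately 1/4 regardless of the mean).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import feature as skfeature
from skimage import measure, morphology
from skimage.filters import rank

from .calibration import CalibrationProfile, edge_response
from .errors import TransformStateError, ValidationError
from .io import Image, MANIFEST_COLUMNS

GLOBAL_FEATURES = ["intensity", "mean", "med", "std", "mad",
                   "Etot", "Emean", "Emed", "Estd", "aiqr", "aq68", "aq95"]
ROI_FEATURES = ["segment", "segmentConv", "skeleton", "skeletonBranch",
                "skeletonEnd", "endpoints", "Euler", "caSum", "faSum", "numObj"]
SEGMENT_FEATURES = ["solidity", "caRel", "faRel", "ecc", "ext"]
SUMMARY_FEATURES = [f"{n}{s}" for n in SEGMENT_FEATURES for s in ("Mean", "Std")]
FEATURE_NAMES = GLOBAL_FEATURES + ROI_FEATURES + SUMMARY_FEATURES

#: Features bounded by the total pixel count: binomial arcsine-root transform.
BINOMIAL_FEATURES = ("segment", "segmentConv", "faSum")
#: Unbounded count/area/intensity features: square-root transform.
SQRT_FEATURES = ("intensity", "mean", "med", "std", "mad", "aiqr", "aq68",
                 "aq95", "skeleton", "skeletonBranch", "skeletonEnd",
                 "endpoints", "caSum", "numObj")
ENTROPY_FEATURES = ("Etot", "Emean", "Emed", "Estd")

ANSCOMBE_C = 3.0 / 8.0


@dataclasses.dataclass(frozen=True)
class MorphologyParams:
    """Cell-morphology constants of the segmentation.

    ``r_s_px`` is the closing-disk radius (the length scale of a neurite; a
    radius of 6.5 px realizes a discrete disk of diameter 13), ``r_c_px`` the
    lower bound of the cell radius from which the outlier filter's one-cell
    area is derived, ``t_a_px`` the minimum segment area, and ``l_m``/``l_r``
    the square neighbourhoods of the median and range filters.
    """

    r_s_px: float = 6.5
    r_c_px: float = 32.0
    t_a_px: int = 50
    l_m: int = 3
    l_r: int = 3
    entropy_window: int = 9
    entropy_bins: int = 64

    def __post_init__(self):
        if min(self.r_s_px, self.r_c_px, self.t_a_px, self.l_m, self.l_r) <= 0:
            raise ValidationError("all morphology parameters must be positive")

    @property
    def cell_area_px(self) -> int:
        return int(round(np.pi * self.r_c_px**2))


@dataclasses.dataclass
class Segmentation:
    roi_mask: np.ndarray
    labels: np.ndarray
    segments: list  # per-segment dicts: area, filled_area, convex_area, ecc, ext, solidity

    @property
    def n_segments(self) -> int:
        return len(self.segments)


@dataclasses.dataclass(frozen=True)
class OutlierVerdict:
    is_outlier: bool
    reason: str  # under_range | over_range | no_segment | ok
    range_pixel_count: int


@dataclasses.dataclass
class FeatureVector:
    values: dict
    transform_state: str = "raw"  # raw | transformed
    total_pixels: int = 0


def _disk(radius: float) -> np.ndarray:
    """Discrete disk footprint of diameter 2*floor(radius)+1 (6.5 -> 13)."""
    r = int(np.floor(radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (yy**2 + xx**2) <= radius**2


def extract_roi(image: Image, profile: CalibrationProfile,
                params: MorphologyParams | None = None) -> Segmentation:
    """Median filter -> edge map -> closing -> artifact removal -> labels."""
    params = params or MorphologyParams()
    px = np.asarray(image.pixels, dtype=np.float64)
    med = ndimage.median_filter(px, size=params.l_m)
    norm = med / image.max_intensity
    if profile.detector == "canny":
        edges = skfeature.canny(norm, sigma=1.0,
                                low_threshold=profile.weak_threshold,
                                high_threshold=profile.t_e)
    else:
        med_img = Image(np.clip(med, 0, image.max_intensity),
                        image.bit_depth, image.pixel_size_um)
        edges = edge_response(med_img, profile.detector) >= profile.t_e
    closed = morphology.closing(edges, footprint=_disk(params.r_s_px))
    # segments of exactly t_a_px pixels survive; strictly smaller ones go
    cleaned = morphology.remove_small_objects(closed, max_size=params.t_a_px - 1,
                                              connectivity=2)
    return segmentation_from_mask(cleaned)


def segmentation_from_mask(mask: np.ndarray) -> Segmentation:
    """Label a binary ROI mask (8-connectivity) and measure its segments."""
    labels = measure.label(mask, connectivity=2)
    segments = []
    for prop in measure.regionprops(labels):
        filled = int(prop.area_filled)
        convex = int(prop.area_convex)
        bbox_area = (prop.bbox[2] - prop.bbox[0]) * (prop.bbox[3] - prop.bbox[1])
        segments.append({
            "area": int(prop.area),
            "filled_area": filled,
            "convex_area": convex,
            "ecc": float(prop.eccentricity),
            "ext": float(filled / bbox_area),
            "solidity": float(filled / convex) if convex else 0.0,
            "caRel": float(100.0 * convex / prop.area),
            "faRel": float(100.0 * filled / prop.area),
            "bbox": tuple(prop.bbox),
            "convex_image": prop.image_convex,
        })
    return Segmentation(roi_mask=mask, labels=labels, segments=segments)


def range_outlier_check(image: Image, t_r: float,
                        params: MorphologyParams | None = None,
                        segmentation: Segmentation | None = None) -> OutlierVerdict:
    """Flag empty/underexposed and saturated/overexposed images.

    Counts pixels whose local intensity range (max minus min over the
    ``l_r`` x ``l_r`` neighbourhood) exceeds ``t_r``; an image is an outlier
    when fewer than one cell area or nearly all pixels respond, or when the
    segmentation found nothing.
    """
    params = params or MorphologyParams()
    if t_r <= 0:
        raise ValidationError("t_r must be positive")
    px = np.asarray(image.pixels, dtype=np.float64)
    if min(px.shape) < params.l_r:
        raise ValidationError("image smaller than the range-filter window")
    rng_img = (ndimage.maximum_filter(px, size=params.l_r)
               - ndimage.minimum_filter(px, size=params.l_r))
    count = int((rng_img > t_r).sum())
    total = px.size
    cell = params.cell_area_px
    if count <= cell:
        return OutlierVerdict(True, "under_range", count)
    if count >= total - cell:
        return OutlierVerdict(True, "over_range", count)
    if segmentation is not None and segmentation.n_segments == 0:
        return OutlierVerdict(True, "no_segment", count)
    return OutlierVerdict(False, "ok", count)


def _skeleton_nodes(skel: np.ndarray) -> tuple[int, int]:
    """(branch points, endpoints) of a binary skeleton under 8-connectivity."""
    if not skel.any():
        return 0, 0
    neigh = ndimage.convolve(skel.astype(np.uint8), np.ones((3, 3), np.uint8),
                             mode="constant") - skel.astype(np.uint8)
    branches = int(np.sum(skel & (neigh >= 3)))
    ends = int(np.sum(skel & (neigh == 1)))
    return branches, ends


def compute_features(image: Image, seg: Segmentation,
                     params: MorphologyParams | None = None) -> FeatureVector:
    """All 32 raw features of one image given its segmentation."""
    params = params or MorphologyParams()
    px = np.asarray(image.pixels, dtype=np.float64)
    total = px.size
    pct = 100.0 * px / image.max_intensity  # percent of maximal intensity

    v = {}
    mean = pct.mean()
    med = np.median(pct)
    v["intensity"] = float(np.abs(pct - mean).mean())
    v["mean"] = float(mean)
    v["med"] = float(med)
    v["std"] = float(pct.std(ddof=1)) if total > 1 else 0.0
    v["mad"] = float(np.median(np.abs(pct - med)))
    q = np.quantile(pct.ravel(), [0.25, 0.75, 0.16, 0.84, 0.025, 0.975])
    v["aiqr"] = float(q[1] - q[0])
    v["aq68"] = float(q[3] - q[2])
    v["aq95"] = float(q[5] - q[4])

    nbin = params.entropy_bins
    binned = np.clip((px / (image.max_intensity + 1) * nbin).astype(np.uint8),
                     0, nbin - 1)
    hist = np.bincount(binned.ravel(), minlength=nbin).astype(np.float64)
    p = hist[hist > 0] / total
    v["Etot"] = float(-(p * np.log2(p)).sum())
    w = params.entropy_window
    local = rank.entropy(binned, footprint=np.ones((w, w), bool))
    v["Emean"] = float(local.mean())
    v["Emed"] = float(np.median(local))
    v["Estd"] = float(local.std(ddof=1)) if total > 1 else 0.0

    mask = seg.roi_mask
    v["segment"] = 100.0 * mask.sum() / total
    hull_union = np.zeros_like(mask)
    for s in seg.segments:
        y0, x0, y1, x1 = s["bbox"]
        hull_union[y0:y1, x0:x1] |= s["convex_image"]
    v["segmentConv"] = 100.0 * hull_union.sum() / total
    v["caSum"] = 100.0 * sum(s["convex_area"] for s in seg.segments) / total
    v["faSum"] = 100.0 * sum(s["filled_area"] for s in seg.segments) / total

    skel = morphology.skeletonize(mask)
    v["skeleton"] = 100.0 * skel.sum() / total
    branches, ends = _skeleton_nodes(skel)
    v["skeletonBranch"] = float(branches)
    v["skeletonEnd"] = float(ends)
    thinned = morphology.thin(mask)
    v["endpoints"] = float(_skeleton_nodes(thinned)[1])
    v["Euler"] = float(measure.euler_number(mask, connectivity=2)) if mask.any() else 0.0
    v["numObj"] = float(seg.n_segments)

    # per-segment summaries; 0 with segment_valid=False downstream when empty
    for name in SEGMENT_FEATURES:
        vals = np.array([s[name] for s in seg.segments], dtype=np.float64)
        v[f"{name}Mean"] = float(vals.mean()) if vals.size else 0.0
        v[f"{name}Std"] = float(vals.std(ddof=0)) if vals.size else 0.0

    return FeatureVector(values=v, transform_state="raw", total_pixels=total)


def anscombe_binomial(count: np.ndarray | float, n_total: float,
                      c: float = ANSCOMBE_C) -> np.ndarray | float:
    """Arcsine-root transform for binomial counts out of ``n_total``."""
    return np.arcsin(np.sqrt((np.asarray(count, dtype=np.float64) + c)
                             / (n_total + 2 * c)))


def apply_transforms(fv: FeatureVector, entropy_scheme: str = "identity") -> FeatureVector:
    """Variance-stabilize a raw feature vector.

    Binomial-bounded area fractions (stored in percent of ``total_pixels``)
    are converted back to counts and arcsine-root transformed; count/area/
    intensity features take the square root; entropy features follow
    ``entropy_scheme`` ('identity' or 'log'); everything else (Euler number,
    unit-free shape summaries) is left unchanged.
    """
    if fv.transform_state != "raw":
        raise TransformStateError("feature vector already transformed")
    if fv.total_pixels <= 0:
        raise ValidationError("total_pixels must be known for the binomial transform")
    out = dict(fv.values)
    n = fv.total_pixels
    for name in BINOMIAL_FEATURES:
        count = out[name] / 100.0 * n
        out[name] = float(anscombe_binomial(count, n))
    for name in SQRT_FEATURES:
        if out[name] < 0:
            raise ValidationError(f"negative value in sqrt-transformed feature {name}")
        out[name] = float(np.sqrt(out[name]))
    if entropy_scheme == "log":
        for name in ENTROPY_FEATURES:
            out[name] = float(np.log1p(out[name]))
    elif entropy_scheme != "identity":
        raise ValidationError(f"unknown entropy transform scheme {entropy_scheme!r}")
    return FeatureVector(values=out, transform_state="transformed",
                         total_pixels=fv.total_pixels)


def transform_feature_table(table: pd.DataFrame, total_pixels: int,
                            entropy_scheme: str = "identity") -> pd.DataFrame:
    """Table-level version of :func:`apply_transforms` (column ``transformed``
    guards against double application)."""
    if "transformed" in table.columns and table["transformed"].any():
        raise TransformStateError("feature table already transformed")
    out = table.copy()
    n = total_pixels
    for name in BINOMIAL_FEATURES:
        out[name] = anscombe_binomial(out[name].to_numpy() / 100.0 * n, n)
    for name in SQRT_FEATURES:
        out[name] = np.sqrt(out[name].to_numpy())
    if entropy_scheme == "log":
        for name in ENTROPY_FEATURES:
            out[name] = np.log1p(out[name].to_numpy())
    out["transformed"] = True
    return out


def extract_feature_table(images, manifest: pd.DataFrame,
                          profile: CalibrationProfile,
                          params: MorphologyParams | None = None) -> pd.DataFrame:
    """Segment every image and assemble the raw feature table.

    Outliers are flagged (``is_outlier``, ``outlier_reason``), never dropped;
    ``segment_valid`` marks rows whose per-segment summaries are defined.
    """
    params = params or MorphologyParams()
    rows = []
    for img, (_, meta) in zip(images, manifest.iterrows()):
        seg = extract_roi(img, profile, params)
        verdict = range_outlier_check(img, profile.t_r, params, seg)
        fv = compute_features(img, seg, params)
        row = {k: meta[k] for k in MANIFEST_COLUMNS}
        row.update({
            "is_outlier": verdict.is_outlier,
            "outlier_reason": verdict.reason,
            "segment_valid": seg.n_segments > 0,
            "total_px": int(np.asarray(img.pixels).size),
        })
        row.update(fv.values)
        rows.append(row)
    return pd.DataFrame(rows)


class RoiFeatureExtractor:
    """Transformer-style front end: images + manifest -> feature table.

    Stateless apart from its parameters; ``fit`` exists for pipeline
    compatibility. ``transform`` returns the raw table, optionally
    variance-stabilized when ``stabilize=True``.
    """

    def __init__(self, profile: CalibrationProfile | None = None,
                 params: MorphologyParams | None = None, stabilize: bool = False,
                 entropy_scheme: str = "identity"):
        self.profile = profile
        self.params = params
        self.stabilize = stabilize
        self.entropy_scheme = entropy_scheme

    def fit(self, images=None, manifest=None):
        if self.profile is None:
            raise ValidationError("RoiFeatureExtractor requires a calibration profile")
        self.n_features_ = len(FEATURE_NAMES)
        return self

    def transform(self, images, manifest: pd.DataFrame) -> pd.DataFrame:
        self.fit()
        table = extract_feature_table(images, manifest, self.profile, self.params)
        if self.stabilize:
            total = int(np.asarray(images[0].pixels).size)
            table = transform_feature_table(table, total, self.entropy_scheme)
        return table

    def fit_transform(self, images, manifest: pd.DataFrame) -> pd.DataFrame:
        return self.fit(images, manifest).transform(images, manifest)

    def get_params(self, deep: bool = True) -> dict:
        return {"profile": self.profile, "params": self.params,
                "stabilize": self.stabilize, "entropy_scheme": self.entropy_scheme}

    def set_params(self, **kw):
        for k, v in kw.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self
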