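"""Synthetic phase-contrast micrograph and feature-table generators.

Real long-term live-cell experiments come with two families of structure that
the pipeline must cope with: biological structure (colonies of cells that
grow over days, and — in the differentiated phenotype — thin neurites that
physically connect neighbouring colonies) and technical structure (radial
vignetting of the illumination, a periodic drift of the mean intensity along
the scan order of the wells, and sensor noise). The generators here emulate
exactly those ingredients so that every downstream stage — calibration,
feature extraction, autocorrelation screening, classification and the
population statistics — can be exercised end to end with known ground truth.

Colonies are rendered as overlapping soft-edged ellipses with a dark body and
a bright halo rim, mimicking the phase-contrast appearance of dense cell
areas; the ROI operators respond to this local contrast, not to absolute
polarity. Neurites are anti-aliased curvilinear bridges between colony
centres. Nothing here attempts photorealism: the point is controlled,
reproducible structure, not pretty pictures.

All generators are pure functions of their spec plus a seed.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit, logit

from .errors import InvalidSpecError
from .io import Image, MANIFEST_COLUMNS, write_image, save_json


@dataclasses.dataclass(frozen=True)
class AcquisitionSpec:
    """Optical and scan parameters of the simulated acquisition.

    ``radial_vignette_amplitude`` and ``periodic_drift_amplitude`` are
    fractions of the background intensity; the drift advances one phase step
    per acquired image in scan order with the given period (in images).
    """

    image_shape_px: tuple[int, int] = (256, 256)
    bit_depth: int = 12
    pixel_size_um: float = 0.078
    radial_vignette_amplitude: float = 0.10
    periodic_drift_amplitude: float = 0.05
    periodic_drift_period: float = 10.0
    noise_sd: float = 15.0
    background_level: float = 0.45
    substrate_texture_amplitude: float = 0.08
    substrate_texture_scale_px: float = 2.5
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_shape_px
        if h <= 0 or w <= 0 or self.bit_depth <= 0 or self.pixel_size_um <= 0:
            raise InvalidSpecError("image shape, bit depth and pixel size must be positive")
        for a in (self.radial_vignette_amplitude, self.periodic_drift_amplitude,
                  self.substrate_texture_amplitude):
            if not 0 <= a < 1:
                raise InvalidSpecError("amplitudes must lie in [0, 1)")
        if self.periodic_drift_period < 1:
            raise InvalidSpecError("drift period must be >= 1 image")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be non-negative")

    @property
    def max_intensity(self) -> int:
        return 2**self.bit_depth - 1


@dataclasses.dataclass(frozen=True)
class PhenotypeSpec:
    """Growth and morphology parameters of one experimental condition.

    ``growth_rate`` is the per-day increase of the log-odds of the covered
    area fraction (the scale on which confluency kinetics are linear).
    ``neurite_probability`` is the per-colony probability of extending a
    neurite bridge to its nearest neighbour; ``neurite_day_profile`` is an
    optional per-day multiplier on that probability (last entry carried
    forward), emulating differentiation that sets in progressively over the
    first days. ``clumping_rate`` shrinks the minimum colony gap per day,
    increasing colony contact and overlap at later days.
    """

    condition_label: str
    colony_count_day0: int = 12
    growth_rate: float = 0.382
    neurite_probability: float = 0.0
    neurite_width_px: int = 3
    clumping_rate: float = 0.10
    colony_radius_px: float = 13.0
    coverage_jitter_sd: float = 0.15
    neurite_day_profile: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.colony_count_day0 < 1:
            raise InvalidSpecError("colony_count_day0 must be >= 1")
        if self.growth_rate < 0:
            raise InvalidSpecError("growth_rate must be >= 0")
        if not 0 <= self.neurite_probability <= 1:
            raise InvalidSpecError("neurite_probability must lie in [0, 1]")
        if self.neurite_width_px < 1:
            raise InvalidSpecError("neurite_width_px must be >= 1")
        if self.clumping_rate < 0 or self.colony_radius_px <= 0:
            raise InvalidSpecError("clumping_rate and colony_radius_px must be non-negative")

    @property
    def differentiated(self) -> bool:
        return self.neurite_probability > 0

    def neurite_probability_on(self, day: int) -> float:
        if self.neurite_day_profile:
            prof = self.neurite_day_profile
            mult = prof[min(day - 1, len(prof) - 1)] if day >= 1 else prof[0]
            return self.neurite_probability * float(mult)
        return self.neurite_probability

    def baseline_coverage(self, shape: tuple[int, int]) -> float:
        """Expected covered fraction extrapolated to day 0."""
        area = shape[0] * shape[1]
        p0 = self.colony_count_day0 * math.pi * self.colony_radius_px**2 / area
        return float(np.clip(p0, 1e-3, 0.90))


def default_phenotype_specs() -> list[PhenotypeSpec]:
    """The two training conditions of a differentiation experiment.

    CTL proliferates without differentiating; NGF shows the mixed phenotype:
    it proliferates at a comparable rate while growing neurite bridges, with
    differentiation setting in progressively and saturating at day 4 — the
    constructed peak of separability, since colony crowding erodes the
    morphological signal on the last days.
    """
    return [
        PhenotypeSpec(condition_label="CTL", growth_rate=0.382,
                      neurite_probability=0.0),
        PhenotypeSpec(condition_label="NGF", growth_rate=0.358,
                      neurite_probability=0.95, neurite_width_px=3,
                      neurite_day_profile=(0.55, 0.75, 1.0, 1.0)),
    ]


# ---------------------------------------------------------------------------
# rendering primitives


def _technical_field(acq: AcquisitionSpec, scan_counter: int) -> np.ndarray:
    """Vignette x drift multiplicative field (no noise), unit background."""
    h, w = acq.image_shape_px
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (cy**2 + cx**2)
    vignette = 1.0 - acq.radial_vignette_amplitude * r2
    drift = 1.0 + acq.periodic_drift_amplitude * math.sin(
        2.0 * math.pi * scan_counter / acq.periodic_drift_period
    )
    return vignette * drift


def _substrate_texture(acq: AcquisitionSpec, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative collagen-coating texture visible in cell-free wells.

    A correlated random field with micro-contrast well above the sensor
    noise: in an empty well the coating is in focus, so edge thresholds
    calibrated on these images sit above the noise floor of later cell
    images (where the cells, not the substrate, dominate the focal plane).
    """
    if acq.substrate_texture_amplitude == 0:
        return np.ones(acq.image_shape_px)
    field = rng.normal(size=acq.image_shape_px)
    field = ndimage.gaussian_filter(field, acq.substrate_texture_scale_px)
    field /= field.std()
    return 1.0 + acq.substrate_texture_amplitude * field


def _quantize(field: np.ndarray, acq: AcquisitionSpec, rng: np.random.Generator) -> np.ndarray:
    if acq.noise_sd > 0:
        field = field + rng.normal(0.0, acq.noise_sd, size=field.shape)
    return np.clip(np.rint(field), 0, acq.max_intensity).astype(np.uint16)


def _paint_ellipses(shape, colonies, scale: float) -> np.ndarray:
    """Boolean union mask of ellipses; each colony is (cy, cx, a, b, theta)."""
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    for cy, cx, a, b, theta in colonies:
        a_s, b_s = a * scale, b * scale
        rmax = max(a_s, b_s)
        y0, y1 = int(max(0, cy - rmax - 1)), int(min(h, cy + rmax + 2))
        x0, x1 = int(max(0, cx - rmax - 1)), int(min(w, cx + rmax + 2))
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = yy - cy, xx - cx
        ct, st = math.cos(theta), math.sin(theta)
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        mask[y0:y1, x0:x1] |= (u / a_s) ** 2 + (v / b_s) ** 2 <= 1.0
    return mask


#: Boundary gap between freshly seeded colonies, px; chosen above the
#: closing-disk diameter so that undifferentiated colonies segment apart.
BASE_COLONY_GAP_PX = 20.0


def _sample_colonies(spec: PhenotypeSpec, shape, day: int, target: float,
                     rng: np.random.Generator):
    """Colony geometry for one image on a given day.

    Radii are set analytically so the summed area meets the coverage target;
    centres are placed by rejection sampling with a minimum boundary gap that
    shrinks with day at ``clumping_rate``, so colonies stay disconnected
    early and increasingly touch and overlap as the culture grows dense.
    """
    h, w = shape
    n = spec.colony_count_day0
    gap = BASE_COLONY_GAP_PX * math.exp(-spec.clumping_rate * (day - 1))
    r_target = math.sqrt(target * h * w / (n * math.pi))
    radii = r_target * rng.uniform(0.85, 1.15, size=n)
    radii *= math.sqrt(n * r_target**2 / np.sum(radii**2))
    margin = 6.0
    centers = []
    for r in radii:
        placed = False
        g = gap
        for attempt in range(400):
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            ok = all((cy - py) ** 2 + (cx - px) ** 2 >= (r + pr + g) ** 2
                     for py, px, pr in centers)
            if ok:
                centers.append((cy, cx, r))
                placed = True
                break
            if attempt % 80 == 79:  # dense late-day cultures: relax the gap
                g = max(g - 6.0, -0.6 * r)
        if not placed:
            centers.append((rng.uniform(margin, h - margin),
                            rng.uniform(margin, w - margin), r))
    colonies = []
    for cy, cx, r in centers:
        u = rng.uniform(0.85, 1.2)
        colonies.append((cy, cx, r * u, r / u, rng.uniform(0, math.pi)))
    return colonies


def _fit_coverage_scale(shape, colonies, target: float) -> tuple[float, np.ndarray]:
    """Bisect a global radius scale so the union mask covers ``target``."""
    lo, hi = 0.15, 6.0
    total = shape[0] * shape[1]
    mask = None
    for _ in range(14):
        mid = 0.5 * (lo + hi)
        mask = _paint_ellipses(shape, colonies, mid)
        frac = mask.sum() / total
        if frac < target:
            lo = mid
        else:
            hi = mid
    final = 0.5 * (lo + hi)
    mask = _paint_ellipses(shape, colonies, final)
    return final, mask


def _bezier_points(p0, p1, ctrl, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return ((1 - t) ** 2) * p0 + 2 * (1 - t) * t * ctrl + (t**2) * p1


def _draw_neurites(shape, colonies, p_connect, width_px, rng):
    """Rasterize curvilinear bridges between nearest colony centres.

    Returns the neurite mask and the list of endpoint pairs actually drawn.
    """
    mask = np.zeros(shape, dtype=bool)
    endpoints = []
    centers = np.array([(c[0], c[1]) for c in colonies])
    if len(centers) < 2 or p_connect <= 0:
        return mask, endpoints
    d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    radius = max(0.5, width_px / 2.0)
    h, w = shape
    for i, c in enumerate(centers):
        if rng.uniform() >= p_connect:
            continue
        j = int(np.argmin(d2[i]))
        dist = math.sqrt(d2[i, j])
        if dist < 6 or dist > 0.6 * min(h, w):
            continue
        p0, p1 = centers[i], centers[j]
        mid = 0.5 * (p0 + p1)
        tangent = (p1 - p0) / dist
        normal = np.array([-tangent[1], tangent[0]])
        ctrl = mid + normal * rng.normal(0.0, 0.12 * dist)
        pts = _bezier_points(p0, p1, ctrl, max(8, int(2 * dist)))
        for py, px in pts:
            y0, y1 = int(max(0, py - radius - 1)), int(min(h, py + radius + 2))
            x0, x1 = int(max(0, px - radius - 1)), int(min(w, px + radius + 2))
            if y0 >= y1 or x0 >= x1:
                continue
            yy, xx = np.mgrid[y0:y1, x0:x1]
            mask[y0:y1, x0:x1] |= (yy - py) ** 2 + (xx - px) ** 2 <= radius**2
        endpoints.append([float(p0[0]), float(p0[1]), float(p1[0]), float(p1[1])])
    return mask, endpoints


def _render_cell_image(spec: PhenotypeSpec, acq: AcquisitionSpec, day: int,
                       scan_counter: int, rng: np.random.Generator):
    """Render one micrograph; returns (uint16 pixels, ground-truth dict)."""
    shape = acq.image_shape_px
    p0 = spec.baseline_coverage(shape)
    jitter = rng.normal(0.0, spec.coverage_jitter_sd)
    target = float(expit(logit(p0) + spec.growth_rate * day + jitter))
    target = float(np.clip(target, 0.01, 0.92))

    colonies = _sample_colonies(spec, shape, day, target, rng)
    _, body = _fit_coverage_scale(shape, colonies, target)
    covered = body.sum() / body.size

    p_conn = spec.neurite_probability_on(day)
    neurites, endpoints = _draw_neurites(shape, colonies, p_conn,
                                         spec.neurite_width_px, rng)
    neurites &= ~body

    rim = ndimage.binary_dilation(body, iterations=3) & ~ndimage.binary_erosion(body, iterations=2)
    modulation = np.ones(shape, dtype=np.float64)
    modulation[body] = 0.82
    modulation[rim] = 1.35
    modulation[neurites] = 1.30
    modulation = ndimage.gaussian_filter(modulation, 1.2)

    base = acq.background_level * acq.max_intensity
    field = base * _technical_field(acq, scan_counter) * modulation
    pixels = _quantize(field, acq, rng)
    truth = {
        "differentiated": bool(spec.differentiated),
        "covered_fraction": float(covered),
        "neurite_endpoints": endpoints,
    }
    return pixels, truth


# ---------------------------------------------------------------------------
# public generators


def generate_empty_well_images(acq: AcquisitionSpec, n_images: int, n_wells: int,
                               n_days: int = 1):
    """Simulate the empty-well calibration acquisition.

    ``n_images`` images are taken per well and day, wells scanned in turn
    within each pass, so the manifest order is the scan order and the drift
    phase advances one step per acquired image.

    Returns ``(images, manifest)`` where ``images`` is a list of
    :class:`~neurodiff.io.Image` aligned with the manifest rows.
    """
    if n_images < 1 or n_wells < 1 or n_days < 1:
        raise InvalidSpecError("n_images, n_wells and n_days must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(acq.seed))
    rows, images = [], []
    counter = 0
    for day in range(1, n_days + 1):
        per_well_idx = dict.fromkeys(range(n_wells), 0)
        for _pass in range(n_images):
            for wi in range(n_wells):
                base = acq.background_level * acq.max_intensity
                field = base * _technical_field(acq, counter) \
                    * _substrate_texture(acq, rng)
                pixels = _quantize(field, acq, rng)
                images.append(Image(pixels, acq.bit_depth, acq.pixel_size_um))
                rows.append({
                    "image_path": f"calib_w{wi}_d{day}_{per_well_idx[wi]:03d}.tif",
                    "well": f"W{wi}",
                    "day": day,
                    "condition": "EMPTY",
                    "replicate": f"W{wi}",
                    "scan_index": per_well_idx[wi],
                })
                per_well_idx[wi] += 1
                counter += 1
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return images, manifest


def generate_experiment(specs: list[PhenotypeSpec], acq: AcquisitionSpec,
                        days: int = 6, wells_per_condition: int = 2,
                        images_per_well_day: int = 30):
    """Simulate a multi-day mixed-phenotype experiment.

    Covered area grows per day on the log-odds scale at each condition's
    ``growth_rate``; differentiated conditions additionally grow thin neurite
    bridges between colonies. Per day, the microscope passes over all wells
    repeatedly, so the manifest order is the simulated scan order.

    Returns ``(images, manifest, ground_truth)`` with ``ground_truth`` a list
    of per-image dicts aligned with the manifest rows.
    """
    if not specs:
        raise InvalidSpecError("at least one phenotype spec is required")
    if days < 1 or wells_per_condition < 1 or images_per_well_day < 1:
        raise InvalidSpecError("days, wells and images per well-day must be >= 1")
    rows, images, truths = [], [], []
    image_counter = 0
    for day in range(1, days + 1):
        counter = 0
        scan_idx = {}
        for _pass in range(images_per_well_day):
            for spec in specs:
                for wi in range(wells_per_condition):
                    well = f"{spec.condition_label}-W{wi}"
                    rng = np.random.default_rng(
                        np.random.SeedSequence([acq.seed & 0x7FFFFFFF, image_counter])
                    )
                    pixels, truth = _render_cell_image(spec, acq, day, counter, rng)
                    images.append(Image(pixels, acq.bit_depth, acq.pixel_size_um))
                    si = scan_idx.get((well, day), 0)
                    rows.append({
                        "image_path": f"{spec.condition_label}_w{wi}_d{day}_{si:03d}.tif",
                        "well": well,
                        "day": day,
                        "condition": spec.condition_label,
                        "replicate": f"W{wi}",
                        "scan_index": si,
                    })
                    scan_idx[(well, day)] = si + 1
                    truths.append(truth)
                    counter += 1
                    image_counter += 1
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return images, manifest, truths


def write_experiment(out_dir, images, manifest, ground_truth=None) -> pd.DataFrame:
    """Write images as 16-bit TIFFs plus CSV manifest and JSON ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    for i, row in manifest.iterrows():
        write_image(out_dir / row["image_path"], images[i])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    if ground_truth is not None:
        save_json(out_dir / "ground_truth.json", {"images": ground_truth})
    return manifest


def generate_coverage_series(growth_rate: float, days: int, n_per_day: int,
                             baseline_coverage: float = 0.15,
                             noise_sd_logit: float = 0.15, seed: int = 0):
    """Ground-truth covered-area fractions for proliferation-kinetics tests.

    Returns a DataFrame with columns ``day`` and ``covered_fraction`` whose
    logit is linear in day with slope ``growth_rate`` plus Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    day = np.repeat(np.arange(1, days + 1), n_per_day)
    lo = logit(baseline_coverage) + growth_rate * day
    lo = lo + rng.normal(0.0, noise_sd_logit, size=day.size)
    return pd.DataFrame({"day": day, "covered_fraction": expit(lo)})


def generate_feature_table(n_per_class: int, n_features: int, n_informative: int,
                           effect_size: float, seed: int = 0) -> pd.DataFrame:
    """Abstract two-class feature table for classifier unit tests.

    The first ``n_informative`` features are shifted by ``effect_size``
    standard deviations in the positive class; the rest are exchangeable
    standard-normal noise. Rows carry the metadata columns the classification
    machinery expects (condition ``neg``/``pos``, single day, single well).
    """
    if not 1 <= n_informative <= n_features:
        raise InvalidSpecError("need 1 <= n_informative <= n_features")
    if n_per_class < 2:
        raise InvalidSpecError("n_per_class must be >= 2")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.normal(0.0, 1.0, size=(n, n_features))
    y = np.repeat([0, 1], n_per_class)
    X[y == 1, :n_informative] += effect_size
    names = [f"feat{i:02d}" for i in range(n_features)]
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "image_path", [f"synthetic_{i:04d}" for i in range(n)])
    df.insert(1, "well", "W0")
    df.insert(2, "day", 1)
    df.insert(3, "condition", np.where(y == 1, "pos", "neg"))
    df.insert(4, "replicate", "W0")
    df.insert(5, "scan_index", np.arange(n))
    df.insert(6, "is_outlier", False)
    df.insert(7, "outlier_reason", "ok")
    df.insert(8, "segment_valid", True)
    # interleave classes so stratified folds stay balanced under any split
    order = np.argsort(np.tile(np.arange(n_per_class), 2), kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    df["scan_index"] = np.arange(n)
    return df


def generate_day_effect_table(n_per_class_day: int, n_features: int,
                              n_informative: int, effect_by_day,
                              seed: int = 0) -> pd.DataFrame:
    """Multi-day two-class feature table with day-dependent effect size.

    Emulates a time course in which population separability rises as
    differentiation sets in and falls again as crowding erodes the signal:
    on day ``d`` the informative features of the positive class are shifted
    by ``effect_by_day[d-1]`` standard deviations. The day with the largest
    effect is the constructed optimum for training-day selection.
    """
    effect_by_day = list(effect_by_day)
    if not effect_by_day:
        raise InvalidSpecError("effect_by_day must not be empty")
    rng = np.random.default_rng(seed)
    parts = []
    for day, es in enumerate(effect_by_day, start=1):
        df = generate_feature_table(n_per_class_day, n_features, n_informative,
                                    es, seed=int(rng.integers(2**31)))
        df["day"] = day
        parts.append(df)
    out = pd.concat(parts, ignore_index=True)
    out["scan_index"] = np.arange(len(out))
    return out
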