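"""Automatic calibration of the ROI thresholds from empty-well images.

Two thresholds are derived from a calibration acquisition of cell-free wells:

* ``t_r`` — the range-filter threshold of the outlier detector, set from the
  width of the central intensity quantile (the intensity-spread feature)
  averaged per well, taking the more conservative (larger) of the well means.
* ``t_e`` — the strong edge threshold, chosen per image so that the edge
  response marks a given fraction of pixels, then averaged per well and again
  taking the larger well mean.

The edge-detector variant (four Canny variants differing in their weak
threshold fraction, plus Prewitt, Sobel, Roberts and Laplacian-of-Gaussian)
is selected by requiring its per-image threshold to be as stable as possible
over measurement days within a well: a two-way ANOVA (well, day, interaction)
quantifies the factor influence, and the candidate with the smallest
within-well across-day standardized mean difference wins. ``t_r`` lives on
the raw intensity scale of the acquisition (a.u. of the bit depth), ``t_e``
on intensities normalized to [0, 1] — the profile records both scales.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters

from .errors import DegenerateInputError, ValidationError
from .io import Image

PLAIN_DETECTORS = ("prewitt", "sobel", "roberts", "log")


@dataclasses.dataclass(frozen=True)
class CalibrationConfig:
    spread_quantile: float = 0.68
    roi_fraction: float = 0.05
    weak_fraction_grid: tuple[float, ...] = (0.05, 0.025, 0.10, 0.20)
    detector_candidates: tuple[str, ...] | None = None
    anova_alpha: float = 0.05

    def __post_init__(self):
        for v in (self.spread_quantile, self.roi_fraction, *self.weak_fraction_grid):
            if not 0 < v < 1:
                raise ValidationError("quantiles and fractions must lie in (0, 1)")

    def candidates(self) -> list[str]:
        """Ordered candidate list; Canny variants first (tie-break preference)."""
        if self.detector_candidates is not None:
            return list(self.detector_candidates)
        canny = [f"canny@{wf:g}" for wf in self.weak_fraction_grid]
        return canny + list(PLAIN_DETECTORS)


@dataclasses.dataclass
class CalibrationProfile:
    """All automatically calibrated parameters plus the selection report."""

    t_r: float
    detector: str
    t_e: float
    weak_fraction: float
    per_well_means: dict
    anova_report: dict
    version: int = 1

    def __post_init__(self):
        if not 0 < self.t_e < 1:
            raise ValidationError("t_e must lie in (0, 1) on the normalized scale")

    @property
    def weak_threshold(self) -> float:
        return self.weak_fraction * self.t_e

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationProfile":
        d = {k: d[k] for k in ("t_r", "detector", "t_e", "weak_fraction",
                               "per_well_means", "anova_report", "version")}
        return cls(**d)


def intensity_spread(image: Image, q: float) -> float:
    """Width of the central ``q`` probability mass of the pixel intensities.

    Symmetric tails: the upper (1+q)/2 quantile minus the lower (1-q)/2
    quantile, in raw intensity units.
    """
    if not 0 < q < 1:
        raise ValidationError("q must lie in (0, 1)")
    px = np.asarray(image.pixels, dtype=np.float64).ravel()
    if px.size == 0:
        raise ValidationError("empty image")
    lo, hi = np.quantile(px, [(1 - q) / 2, (1 + q) / 2])
    return float(hi - lo)


def compute_range_threshold(images_by_well: dict, q: float = 0.68) -> float:
    """Per-well mean intensity spread; returns the larger (conservative) mean."""
    if not images_by_well or any(len(v) == 0 for v in images_by_well.values()):
        raise ValidationError("calibration set needs at least one image per well")
    means = {w: float(np.mean([intensity_spread(im, q) for im in ims]))
             for w, ims in images_by_well.items()}
    t_r = max(means.values())
    if t_r == 0:
        warnings.warn("degenerate calibration set: all images constant, t_r = 0",
                      stacklevel=2)
    return t_r


def edge_response(image: Image, detector: str) -> np.ndarray:
    """Magnitude of the detector response on [0, 1]-normalized intensities.

    Canny variants share the response of their first stage: the gradient
    magnitude of the Gaussian-smoothed image (sigma 1), which is the quantity
    the strong/weak hysteresis thresholds are applied to.
    """
    img = image.normalized()
    if detector.startswith("canny"):
        sm = ndimage.gaussian_filter(img, 1.0)
        gy, gx = np.gradient(sm)
        return np.hypot(gy, gx)
    if detector == "prewitt":
        return np.abs(filters.prewitt(img))
    if detector == "sobel":
        return np.abs(filters.sobel(img))
    if detector == "roberts":
        return np.abs(filters.roberts(img))
    if detector == "log":
        return np.abs(ndimage.gaussian_laplace(img, 2.0))
    raise ValidationError(f"unknown edge detector {detector!r}")


def edge_threshold_for_fraction(image: Image, detector: str, f: float) -> float:
    """Threshold marking a fraction ``f`` of pixels as edge response >= it."""
    if not 0 < f < 1:
        raise ValidationError("f must lie in (0, 1)")
    resp = edge_response(image, detector)
    if resp.max() == 0:
        raise DegenerateInputError("constant image: zero edge response everywhere")
    return float(np.quantile(resp.ravel(), 1 - f))


def _scaled_pairwise_differences(tbl: pd.DataFrame) -> tuple[float, float]:
    """Cohen's-d style mean differences: (intra-well across days, inter-well).

    For each well, each pair of days contributes |mean difference| divided by
    the pooled standard deviation of the two day groups; the intra score is
    the mean over all such pairs. The inter score does the same for well
    pairs within each day.
    """
    def cohens_d(a, b):
        na, nb = len(a), len(b)
        sp2 = (((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1))
               / max(na + nb - 2, 1))
        sp = np.sqrt(sp2)
        if sp == 0:
            return 0.0 if np.mean(a) == np.mean(b) else np.inf
        return abs(np.mean(a) - np.mean(b)) / sp

    intra = []
    for _, g in tbl.groupby("well"):
        days = sorted(g["day"].unique())
        for d1, d2 in itertools.combinations(days, 2):
            intra.append(cohens_d(g.loc[g["day"] == d1, "threshold"].to_numpy(),
                                  g.loc[g["day"] == d2, "threshold"].to_numpy()))
    inter = []
    for _, g in tbl.groupby("day"):
        wells = sorted(g["well"].unique())
        for w1, w2 in itertools.combinations(wells, 2):
            inter.append(cohens_d(g.loc[g["well"] == w1, "threshold"].to_numpy(),
                                  g.loc[g["well"] == w2, "threshold"].to_numpy()))
    return float(np.mean(intra)), float(np.mean(inter))


def two_way_anova(tbl: pd.DataFrame) -> dict:
    """Two-way ANOVA of threshold on well, day and their interaction."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    model = smf.ols("threshold ~ C(well) * C(day)", data=tbl).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = anova_lm(model, typ=2)
    return {
        "p_well": float(aov.loc["C(well)", "PR(>F)"]),
        "p_day": float(aov.loc["C(day)", "PR(>F)"]),
        "p_interaction": float(aov.loc["C(well):C(day)", "PR(>F)"]),
    }


def threshold_table(images, manifest: pd.DataFrame, detector: str,
                    roi_fraction: float) -> pd.DataFrame:
    """Per-image edge thresholds with well/day labels for one candidate."""
    rows = []
    for img, (_, meta) in zip(images, manifest.iterrows()):
        rows.append({
            "well": meta["well"], "day": int(meta["day"]),
            "threshold": edge_threshold_for_fraction(img, detector, roi_fraction),
        })
    return pd.DataFrame(rows)


def select_edge_detector(images, manifest: pd.DataFrame,
                         cfg: CalibrationConfig | None = None,
                         precomputed_tables: dict | None = None) -> CalibrationProfile:
    """Choose the edge-detector variant most stable over days within wells.

    ``precomputed_tables`` (candidate name -> threshold table) bypasses the
    response computation; used for testing the selection rule on constructed
    factor effects.
    """
    cfg = cfg or CalibrationConfig()
    if precomputed_tables is None:
        if manifest["well"].nunique() < 2 or manifest["day"].nunique() < 2:
            raise ValidationError("detector selection needs >= 2 wells and >= 2 days")
        tables = {cand: threshold_table(images, manifest, cand, cfg.roi_fraction)
                  for cand in cfg.candidates()}
    else:
        tables = precomputed_tables
        first = next(iter(tables.values()))
        if first["well"].nunique() < 2 or first["day"].nunique() < 2:
            raise ValidationError("detector selection needs >= 2 wells and >= 2 days")

    report = {}
    best, best_score = None, np.inf
    for cand, tbl in tables.items():
        intra, inter = _scaled_pairwise_differences(tbl)
        entry = {"intra_well_scaled_diff": intra, "inter_well_scaled_diff": inter}
        try:
            entry.update(two_way_anova(tbl))
        except Exception:  # degenerate constructed tables may defeat the ANOVA
            entry.update({"p_well": np.nan, "p_day": np.nan, "p_interaction": np.nan})
        report[cand] = entry
        if intra < best_score:  # strict: ties keep the earlier candidate
            best, best_score = cand, intra

    tbl = tables[best]
    per_well = tbl.groupby("well")["threshold"].mean().to_dict()
    t_e = float(max(per_well.values()))
    weak_fraction = float(best.split("@")[1]) if "@" in best else 1.0
    t_r = np.nan
    if images is not None:
        by_well = {}
        for img, (_, meta) in zip(images, manifest.iterrows()):
            by_well.setdefault(meta["well"], []).append(img)
        t_r = compute_range_threshold(by_well, cfg.spread_quantile)
    return CalibrationProfile(
        t_r=float(t_r), detector=best.split("@")[0], t_e=t_e,
        weak_fraction=weak_fraction,
        per_well_means={str(k): float(v) for k, v in per_well.items()},
        anova_report=report,
    )


class EdgeDetectorCalibrator:
    """Estimator-style front end for the calibration step.

    ``fit`` consumes the calibration images plus their manifest and exposes
    the profile through fitted attributes (``t_r_``, ``detector_``, ``t_e_``,
    ``profile_``).
    """

    def __init__(self, spread_quantile: float = 0.68, roi_fraction: float = 0.05,
                 weak_fraction_grid: tuple[float, ...] = (0.05, 0.025, 0.10, 0.20),
                 detector_candidates: tuple[str, ...] | None = None,
                 anova_alpha: float = 0.05):
        self.spread_quantile = spread_quantile
        self.roi_fraction = roi_fraction
        self.weak_fraction_grid = weak_fraction_grid
        self.detector_candidates = detector_candidates
        self.anova_alpha = anova_alpha

    def _config(self) -> CalibrationConfig:
        return CalibrationConfig(
            spread_quantile=self.spread_quantile, roi_fraction=self.roi_fraction,
            weak_fraction_grid=tuple(self.weak_fraction_grid),
            detector_candidates=self.detector_candidates,
            anova_alpha=self.anova_alpha,
        )

    def fit(self, images, manifest: pd.DataFrame):
        profile = select_edge_detector(images, manifest, self._config())
        self.profile_ = profile
        self.t_r_ = profile.t_r
        self.detector_ = profile.detector
        self.t_e_ = profile.t_e
        self.weak_fraction_ = profile.weak_fraction
        return self

    def get_params(self, deep: bool = True) -> dict:
        return {
            "spread_quantile": self.spread_quantile,
            "roi_fraction": self.roi_fraction,
            "weak_fraction_grid": self.weak_fraction_grid,
            "detector_candidates": self.detector_candidates,
            "anova_alpha": self.anova_alpha,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self
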