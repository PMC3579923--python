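"""Downstream population statistics of a differentiation experiment.

Covers proliferation kinetics (logit-linear regression of the covered-area
fraction against day), classifier performance (sensitivity/specificity with
exact binomial confidence intervals), normal-approximation sample-size
planning driven by the standardized effect size, the correspondence between
the classifier score and the classical neurite-length criterion, and the
specific DNA-fragmentation formula used for apoptosis assays.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logit
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

from .errors import DegenerateInputError, ValidationError


@dataclasses.dataclass(frozen=True)
class ProliferationFit:
    condition: str
    slope: float
    slope_se: float
    intercept: float
    n_points: int


def proliferation_slope(table: pd.DataFrame, condition: str | None = None,
                        value_column: str = "faSum", clip_eps: float = 1e-4) -> ProliferationFit:
    """OLS of logit(covered fraction) on day: the proliferation rate.

    ``value_column`` may hold fractions in (0, 1) or percentages (detected by
    values above 1 and rescaled); on a variance-stabilized table the
    arcsine-root transform is inverted exactly using the stored pixel total.
    Exact 0/1 values are clipped to ``clip_eps`` with a warning.
    Outlier-flagged rows are excluded.
    """
    df = table
    if "is_outlier" in df.columns:
        df = df[~df["is_outlier"]]
    if condition is not None:
        df = df[df["condition"] == condition]
    if df["day"].nunique() < 2:
        raise ValidationError("proliferation fit needs at least two distinct days")
    vals = df[value_column].to_numpy(dtype=np.float64)
    if "transformed" in df.columns and df["transformed"].any():
        if "total_px" not in df.columns:
            raise ValidationError(
                "stabilized table lacks total_px; cannot invert the "
                "arcsine-root transform — fit the slope on the raw table")
        from .features import ANSCOMBE_C
        n_px = df["total_px"].to_numpy(dtype=np.float64)
        counts = np.sin(vals) ** 2 * (n_px + 2 * ANSCOMBE_C) - ANSCOMBE_C
        vals = np.clip(counts, 0.0, n_px) / n_px
    elif np.nanmax(vals) > 1.0:
        vals = vals / 100.0
    if ((vals <= 0) | (vals >= 1)).any():
        warnings.warn("covered fractions at 0 or 1 clipped before logit", stacklevel=2)
        vals = np.clip(vals, clip_eps, 1 - clip_eps)
    y = logit(vals)
    X = sm.add_constant(df["day"].to_numpy(dtype=np.float64))
    fit = sm.OLS(y, X).fit()
    return ProliferationFit(condition=condition or "all",
                            slope=float(fit.params[1]),
                            slope_se=float(fit.bse[1]),
                            intercept=float(fit.params[0]),
                            n_points=int(len(y)))


def sensitivity_specificity(z, labels, threshold: float = 0.0,
                            ci_method: str = "beta", alpha: float = 0.05):
    """Sensitivity/specificity at a score threshold with binomial CIs.

    Positives are counted as detected when z > threshold, negatives when
    z <= threshold; intervals are Clopper-Pearson by default.
    """
    z = np.asarray(z, dtype=np.float64)
    y = np.asarray(labels)
    pos = y == np.max(y) if y.dtype != bool else y
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("both classes must be present")
    tp = int((z[pos] > threshold).sum())
    tn = int((z[~pos] <= threshold).sum())
    sens, spec = tp / n1, tn / n0
    sens_ci = proportion_confint(tp, n1, alpha=alpha, method=ci_method)
    spec_ci = proportion_confint(tn, n0, alpha=alpha, method=ci_method)
    return {"sensitivity": sens, "specificity": spec,
            "sensitivity_ci": tuple(map(float, sens_ci)),
            "specificity_ci": tuple(map(float, spec_ci)),
            "n_pos": n1, "n_neg": n0}


def effect_size(z) -> float:
    """Standardized distance of the mean score from the decision boundary:
    mean(z) / sd(z)."""
    z = np.asarray(z, dtype=np.float64)
    if z.size < 2:
        raise ValidationError("effect size needs at least two scores")
    sd = z.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero score variance: effect size undefined")
    return float(z.mean() / sd)


def required_sample_size(es: float, alpha: float = 0.05, power: float = 0.90):
    """Images needed to detect a mean score shifted from the boundary.

    One-sided normal approximation: n = ((z_{1-alpha} + z_{power}) / ES)^2,
    rounded up. Returns (n, n_raw); n_raw scales exactly as 1/ES^2, so
    halving the effect size quadruples the requirement.
    """
    if es <= 0:
        raise ValidationError("effect size must be positive")
    if not (0 < alpha < 0.5 < power < 1):
        raise ValidationError("need 0 < alpha < 0.5 < power < 1")
    n_raw = float(((sps.norm.ppf(1 - alpha) + sps.norm.ppf(power)) / es) ** 2)
    return max(1, int(np.ceil(n_raw))), n_raw


@dataclasses.dataclass(frozen=True)
class CorrespondenceResult:
    pearson_r: float
    r_ci: tuple
    slope: float
    intercept: float
    mapped_threshold: float
    ratio_threshold: float
    n_images: int


def neurite_correspondence(z_scores, neurite_ratios, ratio_threshold: float = 1.0,
                           alpha: float = 0.05) -> CorrespondenceResult:
    """Relate classifier scores to the neurite-length criterion.

    ``neurite_ratios`` holds the per-image mean ratio m of longest neurite
    length to mean cell diameter; the regression uses m - ratio_threshold so
    that zero marks the biological criterion boundary. ``mapped_threshold``
    is the fitted line at that boundary (its intercept): the classifier
    threshold equivalent to the biological criterion. The Pearson CI uses
    the Fisher z-transform.
    """
    z = np.asarray(z_scores, dtype=np.float64)
    m = np.asarray(neurite_ratios, dtype=np.float64)
    if ratio_threshold <= 0:
        raise ValidationError("ratio_threshold must be positive")
    if z.size != m.size or z.size < 3:
        raise ValidationError("need >= 3 paired (score, ratio) images")
    r = float(np.corrcoef(z, m)[0, 1])
    zr = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(z.size - 3)
    crit = sps.norm.ppf(1 - alpha / 2)
    r_ci = (float(np.tanh(zr - crit * se)), float(np.tanh(zr + crit * se)))
    x = m - ratio_threshold
    X = sm.add_constant(x)
    fit = sm.OLS(z, X).fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    return CorrespondenceResult(pearson_r=r, r_ci=r_ci, slope=slope,
                                intercept=intercept, mapped_threshold=intercept,
                                ratio_threshold=float(ratio_threshold),
                                n_images=int(z.size))


def specific_apoptosis(experimental_pct: float, spontaneous_pct: float) -> float:
    """Specific DNA fragmentation in percent:
    (experimental - spontaneous) / (100 - spontaneous) x 100."""
    if not 0 <= experimental_pct <= 100 or not 0 <= spontaneous_pct < 100:
        raise ValidationError(
            "percentages must satisfy 0 <= experimental <= 100, 0 <= spontaneous < 100")
    return float((experimental_pct - spontaneous_pct)
                 / (100.0 - spontaneous_pct) * 100.0)
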