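# neurodiff

Label-free detection of neuronal differentiation in live cell populations
from phase-contrast micrographs.

PC12-like cultures stimulated with NGF show a *mixed phenotype*: the
population keeps proliferating while individual cells differentiate and grow
neurites. Deciding whether a culture is differentiating — without staining,
over many days, across thousands of images — is tedious by eye and noisy by
single-cell tracing. `neurodiff` takes the population view: every micrograph
is reduced to 32 morphometric features computed from a calibrated
region-of-interest (ROI) segmentation, and an ensemble of five Fisher linear
discriminants, trained by nested stratified cross-validation, scores each
image. The standardized score

> zᵢ = (sᵢ − θᵢ) / dispersionᵢ,  verdict = median over the 5 members, z > 0 ⇒ differentiated

has its decision threshold θᵢ set where sensitivity equals specificity, and
can be mapped onto the classical biological criterion (longest neurite ≥ one
cell diameter) by linear regression. The package is aimed at groups running
long-term live-cell imaging who want a calibrate-once, train-once classifier
plus the surrounding statistics: proliferation kinetics from the logit-linear
growth of confluency, per-day sensitivity/specificity with exact binomial
intervals, and sample-size planning from the effect size ES = mean(z)/sd(z)
via n = ⌈((z₁₋α + z_power)/ES)²⌉.

Because the original micrographs of such studies are rarely deposited, the
package ships a synthetic study generator (`neurodiff.synthetic`) that
emulates the relevant structure — radial vignetting, periodic intensity
drift along the scan order, colonies growing on a logistic confluency curve,
thin neurite bridges in the differentiated phenotype, and crowding that
erodes late-day detection — so the entire pipeline is testable end to end
with known ground truth.

## Worked example

```python
import neurodiff as nd

# 1. calibrate on empty (cell-free) wells
acq = nd.AcquisitionSpec(image_shape_px=(256, 256), seed=7)
cal_images, cal_manifest = nd.generate_empty_well_images(acq, n_images=5,
                                                         n_wells=2, n_days=3)
profile = nd.select_edge_detector(cal_images, cal_manifest)
print(f"detector={profile.detector}  t_e={profile.t_e:.4f}  t_r={profile.t_r:.0f} a.u.")

# 2. a six-day, two-condition study (CTL proliferates, NGF differentiates)
images, manifest, truth = nd.generate_experiment(
    nd.default_phenotype_specs(), acq, days=6, wells_per_condition=2,
    images_per_well_day=10)
table = nd.transform_feature_table(
    nd.extract_feature_table(images, manifest, profile), images[0].pixels.size)

# 3. screen out scan-order-autocorrelated features, train the ensemble
screening = nd.rank_features_by_autocorrelation(table, order=1, k=20)
clf = nd.FDAEnsembleClassifier(neg_condition="CTL", pos_condition="NGF",
                               candidate_features=screening.selected_features,
                               seed=0).fit(table)
print("selected features:", ", ".join(clf.selected_features_))
gini = nd.holdout_gini_per_day(clf.ensemble_, table, "CTL", "NGF")
print("held-out Gini by day:", {d: round(g, 2) for d, g in gini.items()})

# 4. population statistics
ctl = nd.proliferation_slope(table, "CTL")
print(f"CTL proliferation slope: {ctl.slope:.3f} +/- {ctl.slope_se:.3f} per day")
scored = clf.score_table(table)
z4 = scored[(scored["condition"] == "NGF") & (scored["day"] == 4)]["z_median"]
es = nd.effect_size(z4)
n_req, _ = nd.required_sample_size(es, alpha=0.05, power=0.90)
print(f"day-4 NGF effect size: {es:.2f}  ->  {n_req} images needed")
```

Output:

```
detector=canny  t_e=0.0202  t_r=294 a.u.
selected features: solidityMean
held-out Gini by day: {1: 1.0, 2: 1.0, 3: 1.0, 4: 0.97, 5: 0.84, 6: 0.66}
CTL proliferation slope: 0.416 +/- 0.012 per day
day-4 NGF effect size: 2.09  ->  2 images needed
```

Reading this: calibration picked a Canny variant with the strong threshold at
the 5 % response quantile of the empty wells; the classifier separates the
conditions perfectly on days 1–3 (Gini = 2·AUC − 1 = 1) and degrades on days
5–6 as colonies crowd into clumps — the expected failure mode. The selected
feature, mean segment solidity, directly measures whether cell growth areas
are compact (undifferentiated colonies) or connected by thin bridges
(neurites). The fitted confluency growth of 0.416/day on the log-odds scale
is close to the generator's input rate of 0.382/day (the feature measures
segmented area, which slightly amplifies the rendered coverage), and at a
day-4 effect size of ~2 score-SDs, two images per well already suffice for a
one-sided test at α = 0.05 with 90 % power.

The same pipeline is available from the shell for study-scale runs:

```
neurodiff simulate --calibration --out calib/ --seed 5
neurodiff calibrate --manifest calib/manifest.csv --out profile.json
neurodiff extract  --manifest study/manifest.csv --profile profile.json --out features.tsv
neurodiff screen   --features features.tsv --k 20 --out screening.json
neurodiff train    --features features.tsv --screening screening.json --out model.json
neurodiff score    --features features.tsv --model model.json --out scores.tsv
neurodiff report   --features features.tsv --scores scores.tsv --model model.json --out report.json
```

Models and calibration profiles are versioned JSON, so a calibrated and
trained system can be reloaded to score later experiments without
recalibration.

See `docs/methods.md` for the model, its assumptions, parameter defaults and
known limitations.

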