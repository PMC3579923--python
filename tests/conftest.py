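"""Shared fixtures: a small rendered study reused across module tests.

Unit-test images are 128 px wide with few colonies so the whole suite stays
fast; the acceptance tests build their own full-size experiment.
"""

import numpy as np
import pytest

import neurodiff as nd
from neurodiff.calibration import CalibrationProfile


def small_specs():
    return [
        nd.PhenotypeSpec(condition_label="CTL", colony_count_day0=5,
                         colony_radius_px=8.0, growth_rate=0.382,
                         neurite_probability=0.0),
        nd.PhenotypeSpec(condition_label="NGF", colony_count_day0=5,
                         colony_radius_px=8.0, growth_rate=0.358,
                         neurite_probability=0.95),
    ]


@pytest.fixture(scope="session")
def small_acq():
    return nd.AcquisitionSpec(image_shape_px=(128, 128), seed=11)


@pytest.fixture(scope="session")
def calibration_set(small_acq):
    return nd.generate_empty_well_images(small_acq, n_images=4, n_wells=2, n_days=2)


@pytest.fixture(scope="session")
def profile(calibration_set):
    images, manifest = calibration_set
    return nd.select_edge_detector(images, manifest)


@pytest.fixture(scope="session")
def synthetic_profile():
    """Hand-built profile for constructed-fixture segmentation tests."""
    return CalibrationProfile(t_r=100.0, detector="canny", t_e=0.08,
                              weak_fraction=0.5, per_well_means={},
                              anova_report={})


@pytest.fixture(scope="session")
def experiment(small_acq):
    images, manifest, truth = nd.generate_experiment(
        small_specs(), small_acq, days=6, wells_per_condition=2,
        images_per_well_day=4)
    return images, manifest, truth


@pytest.fixture(scope="session")
def feature_table(experiment, profile):
    images, manifest, _ = experiment
    return nd.extract_feature_table(images, manifest, profile)


@pytest.fixture(scope="session")
def stabilized_table(feature_table, experiment):
    images = experiment[0]
    return nd.transform_feature_table(feature_table, images[0].pixels.size)


def make_image(pixels, bit_depth=12):
    return nd.Image(np.asarray(pixels), bit_depth=bit_depth)
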