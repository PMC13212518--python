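import numpy as np
import pytest

from caulipheno.series import GrowthSeries
from caulipheno.synthetic import (AcquisitionSchedule, PlantTruth,
                                  simulate_curd_series, simulate_leaf_series)

RICHARDS_TRUTH = {"a": 12000.0, "k": 0.12, "tc": 55.0, "d": 1.5}
SINE_TRUTH = {"y0": 450.0, "A": 448.0, "tc": 95.0, "w": 50.0}


def make_truth(noise_cv=0.0, plant_id="T-1", tca=70.0, harvest=85.0):
    return PlantTruth(
        plant_id=plant_id, germplasm_id="T", replicate=1,
        leaf_params=dict(RICHARDS_TRUTH), curd_params=dict(SINE_TRUTH),
        tca_true=tca, harvest_day=harvest, noise_cv=noise_cv,
    )


@pytest.fixture(scope="session")
def schedule():
    return AcquisitionSchedule()


@pytest.fixture(scope="session")
def clean_leaf_series(schedule):
    """Noise-free Richards leaf trajectory on the acquisition calendar."""
    return simulate_leaf_series(make_truth(0.0), schedule, seed=0)


@pytest.fixture(scope="session")
def clean_curd_series(schedule):
    """Noise-free sine curd trajectory from appearance to harvest."""
    return simulate_curd_series(make_truth(0.0), schedule, seed=0)


@pytest.fixture(scope="session")
def cohort_bundle():
    """Default 141-plant cohort with Richards + sine fits (shared: slow)."""
    from caulipheno.experiments import fit_cohort

    return fit_cohort(seed=0)


def series_from(days, values, plant_id="p", trait="LA"):
    return GrowthSeries(plant_id, trait, np.asarray(days, float),
                        np.asarray(values, float))
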