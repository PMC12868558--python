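import numpy as np
import pytest

import hetconn as hc


@pytest.fixture(scope="session")
def small_bold_cohort():
    """Noisy standardized cohort: 8 subjects, 30 regions, 60 timepoints."""
    subjects, truth = hc.gen_bold_cohort(
        8, 30, 60, rank_shared=4, rank_specific=2,
        noise_fraction=0.02, seed=11)
    return subjects, truth


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Exact planted low-rank cohort (no noise, no standardization)."""
    subjects, truth = hc.gen_bold_cohort(
        6, 40, 50, rank_shared=5, rank_specific=3,
        noise_sd=0.0, standardize=False, seed=5)
    return subjects, truth


@pytest.fixture(scope="session")
def closed_cohort():
    """Cohort with the closed three-disorder deviation geometry (-0.9)."""
    gram, mags = hc.synth.closed_deviation_geometry(
        -0.9, n_per_disorder=(150, 150, 150))
    cohort, clinical, truth = hc.gen_cohort_fc(
        {"HC": 150, "ASD": 150, "ADHD": 150, "SCZ": 150},
        deviation_gram=gram,
        deviation_magnitudes={"ASD": mags[0], "ADHD": mags[1],
                              "SCZ": mags[2]},
        seed=21)
    return cohort, clinical, truth


@pytest.fixture(scope="session")
def spatial_profiles():
    profiles, coords = hc.gen_spatial_profiles(
        60, 300, decay_amplitude=0.8, decay_offset=0.05,
        decay_scale=20.0, seed=13)
    return hc.RegionProfileMatrix.from_frames(profiles, coords)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
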