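"""Shared phantom fixtures.

Everything is generated programmatically and seeded; session scope keeps the
more expensive cohort/pattern fixtures to one construction per run.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

import ssmpet as sp

logging.getLogger("ssmpet").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def atlas_and_mask():
    return sp.make_phantom_atlas((16, 16, 16), n_regions=6, seed=1)


@pytest.fixture(scope="session")
def atlas(atlas_and_mask):
    return atlas_and_mask[0]


@pytest.fixture(scope="session")
def mask(atlas_and_mask):
    return atlas_and_mask[1]


@pytest.fixture(scope="session")
def template(atlas, mask):
    return sp.make_pattern_template(
        atlas, mask, {"parietal": -1.0, "temporal": -0.6, "frontal": -0.4}
    )


@pytest.fixture(scope="session")
def baseline(mask):
    return sp.make_baseline(mask, seed=1)


@pytest.fixture(scope="session")
def static_cohort(template, baseline):
    cohort, truth = sp.simulate_static_cohort(
        template, baseline, sp.SimulationConfig(seed=11)
    )
    return cohort, truth


@pytest.fixture(scope="session")
def trained(static_cohort):
    """Full-cohort DP + LOOCV Z-score table on the AD/HC training subset."""
    cohort, _ = static_cohort
    return sp.derive_pattern_with_loocv(cohort)


@pytest.fixture(scope="session")
def ref_curve():
    return sp.simulate_reference_curve(3600.0)


@pytest.fixture(scope="session")
def schedule():
    return sp.default_frame_schedule(3600.0)


@pytest.fixture(scope="session")
def dynamic_phantom(atlas, mask, ref_curve, schedule):
    kinetics_by_region, k2_prime = sp.default_region_kinetics(atlas, seed=2)
    scans, truth = sp.simulate_dynamic_cohort(
        atlas, kinetics_by_region, ref_curve, schedule, noise_sd=0.0, seed=0
    )
    return {
        "scan": scans[0],
        "truth": truth,
        "k2_prime": k2_prime,
        "kinetics": kinetics_by_region,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
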