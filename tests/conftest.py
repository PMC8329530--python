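"""Shared fixtures: phantoms and cohorts generated at session scope."""

import warnings

import numpy as np
import pytest

from ctedema import (CohortSpec, PhantomSpec, estimate_symmetry,
                     generate_cohort, generate_phantom, segment_intracranial)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, untilted phantom with w = 0.2."""
    return generate_phantom(PhantomSpec(water_uptake=0.2, seed=1))


@pytest.fixture(scope="session")
def clean_pipeline(clean_phantom):
    """Clean phantom plus its segmented intracranial mask and estimated plane."""
    vol, lesions, truth = clean_phantom
    icm = segment_intracranial(vol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        plane = estimate_symmetry(vol, icm, exclude=lesions.lesion)
    return vol, lesions, truth, icm, plane


@pytest.fixture(scope="session")
def symmetric_phantom():
    """Noise-free, untilted phantom with no density lesion (w = 0)."""
    return generate_phantom(PhantomSpec(water_uptake=0.0, seed=2))


@pytest.fixture(scope="session")
def cohort_2000():
    return generate_cohort(CohortSpec(n_patients=2000, seed=11))


def plane_errors(plane, truth):
    """(offset mm, angle deg) of an estimated plane vs the generator's truth."""
    ang = np.degrees(np.arccos(np.clip(abs(plane.normal @ truth.plane.normal),
                                       0.0, 1.0)))
    off = abs((plane.point - truth.plane.point) @ truth.plane.normal)
    return off, ang
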