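"""Shared fixtures.

The identification runs take a few seconds each, so fitted models for the
representative subjects are session-scoped and reused across test modules.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from aortastress import mechanics, preprocessing, synthetic
from aortastress.identification import HGOWallModel


@pytest.fixture(autouse=True)
def _quiet_fiber_warning():
    # the I < 1 advisory fires constantly during multistart exploration
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="fiber invariant")
        yield


@pytest.fixture(scope="session")
def rep_spec():
    """Noise-free representative male subject (tabulated mean parameters,
    elderly mean pressures, radii from model inversion)."""
    return synthetic.representative_subject("male")


@pytest.fixture(scope="session")
def rep_series(rep_spec):
    return synthetic.generate_subject_series(rep_spec)


@pytest.fixture(scope="session")
def rep_loop(rep_series):
    return preprocessing.LoopPreprocessor().transform(rep_series)


@pytest.fixture(scope="session")
def rep_area(rep_spec):
    return mechanics.area_from_age(rep_spec.age, rep_spec.sex)


@pytest.fixture(scope="session")
def rep_fit(rep_loop):
    """Representative subject fitted with the population gamma = 0.59."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="fiber invariant")
        return HGOWallModel().fit(rep_loop)


@pytest.fixture(scope="session")
def physiological_kappa():
    """Table-mean male parameter vector (clinical units converted to SI)."""
    from aortastress.parameters import ModelParameters

    return ModelParameters.from_clinical(
        c_kpa=131.50, k1_kpa=14.18, k2=196.76, beta_deg=42.38,
        r0_mm=7.80, lambda_z=1.03,
    )


def random_admissible_states(n, seed=0):
    """Random admissible (params, stretch-defining radius, area) triples.

    Keeps the fiber exponent moderate so the exponential stays finite and
    the states resemble physiological loading.
    """
    from aortastress.parameters import ModelParameters

    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        r0u = rng.uniform(5e-3, 11e-3)
        params = ModelParameters(
            c=10 ** rng.uniform(3.5, 5.5),
            k1=10 ** rng.uniform(2.0, 4.5),
            k2=10 ** rng.uniform(0.0, 2.0),
            beta_deg=rng.uniform(10.0, 80.0),
            r0_unloaded=r0u,
            lambda_z=rng.uniform(1.0, 1.1),
        )
        r = r0u * rng.uniform(1.0, 1.12)
        area = rng.uniform(30e-6, 90e-6)
        out.append((params, r, area))
    return out
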