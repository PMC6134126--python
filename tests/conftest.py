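"""Shared fixtures.

Everything is generated in-process; the heavier ground-truth curves are
session-scoped because several test modules score reconstructions against
them.
"""

import numpy as np
import pytest

from prcinfer import (NoiseConfig, ParametricPRC, SectionSpec, TimeGrid,
                      generate_ou, l2_norm, morris_lecar_model,
                      true_prc_perturbation, van_der_pol_model)

TWO_PI = 2.0 * np.pi


@pytest.fixture(scope="session")
def ml_true_prc():
    """Ground-truth Morris-Lecar PRC at the spike threshold section."""
    return true_prc_perturbation(morris_lecar_model(),
                                 section=SectionSpec(theta=0.9))


@pytest.fixture(scope="session")
def vdp_true_prc():
    """Ground-truth van der Pol PRC at the theta = 0.7 section."""
    return true_prc_perturbation(van_der_pol_model(),
                                 section=SectionSpec(theta=0.7))


@pytest.fixture(scope="session")
def type2_prc():
    return ParametricPRC.type2()


@pytest.fixture()
def ou_driver_short():
    """A 50-time-unit OU driver at the standard sampling step."""
    grid = TimeGrid.from_duration(50.0, 0.001)
    return generate_ou(NoiseConfig(epsilon=1.0, tau=0.1, seed=42), grid)


def drive_epsilon(prc, strength):
    """epsilon realizing a requested eps*||Z|| for a given PRC."""
    return strength / l2_norm(prc)
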