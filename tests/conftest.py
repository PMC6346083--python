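"""Shared fixtures.

The expensive 128^3 simulation set (phantoms, field map, CT, the full SE
bandwidth and GRE echo-time sweeps for the implanted and implant-free
phantoms) is built once per session and shared by the acceptance tests.
"""

import numpy as np
import pytest

from oralphan.ct_sim import simulate_ct
from oralphan.mr_sim import compute_field_map, simulate_sweep
from oralphan.phantom import PhantomGeometry, build_phantom

STUDY_SPACING = 1.875  # mm -> 128^3 over the 240 mm FOV


@pytest.fixture(scope="session")
def phantom_left():
    return build_phantom(
        PhantomGeometry(implant_config="left_single"), spacing=STUDY_SPACING
    )


@pytest.fixture(scope="session")
def phantom_none():
    return build_phantom(
        PhantomGeometry(implant_config="none"), spacing=STUDY_SPACING
    )


@pytest.fixture(scope="session")
def field_left(phantom_left):
    return compute_field_map(phantom_left)


@pytest.fixture(scope="session")
def ct_left_clean(phantom_left):
    """Artifact-free CT of the implanted phantom (FBP round trip only)."""
    return simulate_ct(phantom_left, beam_hardening=0.0,
                       photon_fluence=np.inf)


@pytest.fixture(scope="session")
def sweeps(phantom_left, phantom_none, field_left):
    """Full SE and GRE sweeps for the implanted phantom plus the matched
    implant-free references (independent noise realizations, as for a
    physical rescan)."""
    return {
        "se": simulate_sweep(phantom_left, field_left, "SE", seed=11),
        "se_ref": simulate_sweep(phantom_none, None, "SE", seed=12),
        "gre": simulate_sweep(phantom_left, field_left, "GRE", seed=13),
        "gre_ref": simulate_sweep(phantom_none, None, "GRE", seed=14),
    }


@pytest.fixture(scope="session")
def phantom_left_small():
    """Coarse 64^3 phantom for fast unit tests."""
    return build_phantom(
        PhantomGeometry(implant_config="left_single"), spacing=3.75
    )


@pytest.fixture(scope="session")
def phantom_none_small():
    return build_phantom(PhantomGeometry(implant_config="none"), spacing=3.75)
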