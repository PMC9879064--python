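import numpy as np
import pytest

import oxcycle as ox
from oxcycle.sensor import HYDROGEL, MEMBRANE_THICKNESS, PDMS


@pytest.fixture(scope="session")
def hydrogel_medium():
    return HYDROGEL


@pytest.fixture(scope="session")
def gel_500_stack():
    """165 um PDMS membrane + 500 um acellular hydrogel, sealed top."""
    return ox.Stack(layers=(
        ox.Layer("membrane", MEMBRANE_THICKNESS, PDMS, kind="membrane"),
        ox.Layer("hydrogel", 0.05, HYDROGEL, kind="scaffold"),
    ))


@pytest.fixture(scope="session")
def gel_800_stack():
    return ox.Stack(layers=(
        ox.Layer("membrane", MEMBRANE_THICKNESS, PDMS, kind="membrane"),
        ox.Layer("hydrogel", 0.08, HYDROGEL, kind="scaffold"),
    ))


@pytest.fixture(scope="session")
def single_gel_stack():
    """Bare 500 um hydrogel slab (no membrane), for closed-form comparisons."""
    return ox.Stack(layers=(ox.Layer("hydrogel", 0.05, HYDROGEL),))


@pytest.fixture(scope="session")
def osa_schedule():
    """Severe-OSA driving: 60 events/h, 30 s at 20% then 30 s at 0% O2."""
    return ox.schedule_from_events_per_hour(60, 0.20, 0.0, duration=180.0)


@pytest.fixture(scope="session")
def pss_gel_500(gel_500_stack, osa_schedule):
    """Converged periodic cycle for the 500 um scenario (shared, read-only)."""
    return ox.run_to_periodic_steady_state(gel_500_stack, osa_schedule)
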