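"""Shared fixtures: small phantoms and their processed results.

Expensive artifacts (generated phantoms, full pipeline runs) are
session-scoped so multiple tests can interrogate the same run.
"""

import pytest
from hypothesis import settings

import lymphmap as lm
from lymphmap import phantom as ph
from lymphmap import pipeline as pl

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def small_arm_spec(seed: int = 0, noise_fraction: float = 0.0) -> ph.PhantomSpec:
    """A 60-slice arm with one sector and one blob fluid pocket."""
    spec = ph.PhantomSpec(
        n_slices=60, in_plane_size=64, arm_radius=(18.0, 24.0),
        muscle_radius=(11.0, 15.0), seed=seed,
        fluid_pockets=[
            ph.FluidPocket(center_slice=30, extent_mm=16, shape="annulus-sector",
                           width_deg=90, angle_deg=270, layer="external"),
            ph.FluidPocket(center_slice=15, extent_mm=8, shape="blob",
                           angle_deg=90, layer="internal"),
        ])
    if noise_fraction:
        spec.noise_sigma = spec.sigma_for_fraction(noise_fraction)
    return spec


@pytest.fixture(scope="session")
def noise_free_arm():
    return ph.generate_arm(small_arm_spec())


@pytest.fixture(scope="session")
def noise_free_result(noise_free_arm):
    stack, gt = noise_free_arm
    return lm.run_arm(stack, gt.landmarks), gt


@pytest.fixture(scope="session")
def small_pair():
    """A 100-slice pair with 40 mL fat / 20 mL fluid injected excess."""
    spec = ph.PhantomSpec(
        n_slices=100, in_plane_size=96, arm_radius=(24.0, 32.0),
        muscle_radius=(15.0, 20.0), seed=11,
        fluid_pockets=[ph.FluidPocket(center_slice=60, extent_mm=60,
                                      shape="annulus-sector", width_deg=140,
                                      angle_deg=45, layer="external")])
    spec.noise_sigma = spec.sigma_for_fraction(0.1)
    excess = ph.ExcessSpec(fat_excess_ml=40.0, fluid_excess_ml=20.0,
                           fluid_span_mm=40.0)
    return ph.generate_pair(spec, excess), excess


@pytest.fixture(scope="session")
def small_pair_result(small_pair):
    ((sa, ga), (su, gu)), _ = small_pair
    return pl.run_pair(sa, ga.landmarks, su, gu.landmarks)
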