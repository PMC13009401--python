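"""Shared fixtures: small geometries and run configurations.

Everything is generated programmatically; no data files. The wedge fixture
(a 0.5 x 0.5 x 0.25 cm slab activated through a single Purkinje cable
terminal) is the workhorse for coupling and calibration tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from purkmyo.io_formats import RunConfig, StimulusBlock
from purkmyo.mesh import build_cuboid_grid


ISO_SIGMA = (1.334, 0.176, 0.176)  # transversely anisotropic benchmark values


def make_wedge_config(**overrides) -> RunConfig:
    """Wedge slab + single-terminal Purkinje cable entering from below."""
    base = dict(
        t_max=50.0,
        grid_extent=(0.5, 0.5, 0.25),
        grid_h=0.025,
        grid_sigma=ISO_SIGMA,
        purkinje_branch_length=0.5,
        purkinje_h=0.025,
        purkinje_sigma=2.0,
        purkinje_start=(0.25, 0.25, -0.5),
        purkinje_direction=(0.0, 0.0, 1.0),
        r_pmj=600.0,
        n_pmj=10,
        stimuli=(
            StimulusBlock(
                "his", ((0.2, 0.2, -0.51), (0.3, 0.3, -0.45)), 0.0, 2.0, 53.0, "purkinje"
            ),
        ),
        output_every=10 ** 9,  # traces every PDE step; no bulk snapshots needed
    )
    base.update(overrides)
    return RunConfig(**base)


def make_cable_config(sigma: float, h: float = 0.025, length: float = 0.5,
                      t_max: float = 40.0, **overrides) -> RunConfig:
    """1-D myocardial cable (one voxel cross-section), stimulated at x=0."""
    base = dict(
        t_max=t_max,
        grid_extent=(length, h, h),
        grid_h=h,
        grid_sigma=(sigma, sigma, sigma),
        stimuli=(
            StimulusBlock(
                "s0", ((0.0, 0.0, 0.0), (2 * h, 2 * h, 2 * h)), 0.0, 2.0, 53.0, "myocardium"
            ),
        ),
        output_every=10 ** 9,
    )
    base.update(overrides)
    return RunConfig(**base)


@pytest.fixture
def small_grid():
    """4x4x4 isotropic grid, h = 0.1 cm."""
    return build_cuboid_grid((0.4, 0.4, 0.4), 0.1, (1.0, 1.0, 1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
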