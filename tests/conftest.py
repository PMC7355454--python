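"""Shared fixtures: reduced-resolution phantoms reused across the suite.

Phantoms keep the clinical field of view (240 mm) and slice spacing but use a
coarser in-plane matrix than the acquisition default so that whole-pipeline
tests stay fast; geometry-sensitive tests build full-resolution cases
themselves.
"""

from __future__ import annotations

import pytest

from tissuefate import phantom, pipeline

SMALL_SHAPE = (16, 128, 128)
SMALL_PIXEL_MM = 1.875        # 240 mm FOV at 128 pixels


def small_config(**overrides) -> phantom.PhantomConfig:
    base = dict(shape=SMALL_SHAPE, pixel_spacing_mm=SMALL_PIXEL_MM, seed=11)
    base.update(overrides)
    return phantom.PhantomConfig(**base)


@pytest.fixture(scope="session")
def noiseless_case():
    """A clean phantom: no signal noise, spatially constant 6 s delay."""
    cfg = small_config(noise_sd=0.0, delay_jitter_sd_s=0.0)
    return phantom.generate_case(cfg, "clean"), cfg


@pytest.fixture(scope="session")
def noisy_case():
    """A phantom at the generator's default (moderate) noise settings."""
    cfg = small_config(seed=21)
    return phantom.generate_case(cfg, "noisy"), cfg


@pytest.fixture(scope="session")
def prepared_noiseless(noiseless_case):
    (case, gt), cfg = noiseless_case
    return pipeline.prepare_case(case), case, gt, cfg


@pytest.fixture(scope="session")
def prepared_noisy(noisy_case):
    (case, gt), cfg = noisy_case
    return pipeline.prepare_case(case), case, gt, cfg
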