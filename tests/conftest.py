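"""Shared fixtures.

The expensive end-to-end run on the default 256³ phantom is
session-scoped and shared between the acceptance tests; unit tests use
small, fast phantoms with adapted geometry.
"""

from __future__ import annotations

import time

import numpy as np
import pytest

import purkinje3d as pk
from purkinje3d import pipeline


@pytest.fixture(scope="session")
def small_phantom_cfg() -> pk.PhantomConfig:
    """128³ phantom: same physics as the default, geometry scaled to fit."""
    return pk.PhantomConfig(shape=(128, 128, 128),
                            layer_amplitude_um=18.0,
                            layer_wavelengths_um=(224.0, 224.0),
                            rng_seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_phantom_cfg):
    return pk.generate(small_phantom_cfg)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline on the default 256³ phantom, seed 42; wall time recorded."""
    outdir = tmp_path_factory.mktemp("default_run")
    cfg = pipeline.PipelineConfig(seed=42)
    t0 = time.time()
    res = pipeline.run_all(cfg, outdir)
    res["wall_time_s"] = time.time() - t0
    res["outdir"] = outdir
    res["cfg"] = cfg
    return res


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
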