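"""Shared fixtures: cohorts are generated once per session and reused."""

from __future__ import annotations

import numpy as np
import pytest

from ichmap.config import RunConfig
from ichmap.pipeline import annotate_cohort, simulate_spot_cohort


@pytest.fixture(scope="session")
def default_cfg() -> RunConfig:
    return RunConfig(seed=1)


@pytest.fixture(scope="session")
def spot_cohort(default_cfg):
    """The default transcriptomics cohort (6 samples, ~3000 spots)."""
    return simulate_spot_cohort(default_cfg)


@pytest.fixture(scope="session")
def annotated(default_cfg, spot_cohort):
    """(expr, scores, assignment) of the default cohort."""
    return annotate_cohort(spot_cohort.samples, default_cfg)


@pytest.fixture(scope="session")
def histology_cfg() -> RunConfig:
    """Histology runs on a half-resolution raster of the same physical
    field (256 px at 40 um/px) with two animals per time point."""
    return RunConfig(seed=2, histology_layout_px=256, px_size_um=40.0,
                     animals_per_timepoint_histology=2)


@pytest.fixture(scope="session")
def temporal_results(histology_cfg):
    """Temporal imaging series at the test raster (shared, ~10 s)."""
    from ichmap.pipeline import run_histology_temporal

    return run_histology_temporal(
        histology_cfg, markers=("dextran70", "CD45", "ICAM1"),
        with_maps=True,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
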