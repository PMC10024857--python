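"""Shared fixtures: one fully rendered small scene (plus its pipeline run)
reused across test modules, and larger geometry-only scenes for statistical
recovery checks."""

from __future__ import annotations

import numpy as np
import pytest

from cycihc.pipeline import PipelineConfig, run_pipeline
from cycihc.scenes import PANEL, Scene, SceneConfig


@pytest.fixture(scope="session")
def small_scene() -> Scene:
    """A compact nine-round scene with every object type present."""
    cfg = SceneConfig(
        seed=11, field_size_um=480.0, n_cells=55, n_extra_nuclei=60,
        shift_max_px=10.0, rot_max_deg=2.0, gfap_conflict_fraction=0.06,
    )
    return Scene(cfg)


@pytest.fixture(scope="session")
def small_truth(small_scene):
    return small_scene.ground_truth()


@pytest.fixture(scope="session")
def small_round_images(small_scene):
    return [small_scene.render_round(i) for i in range(len(PANEL))]


@pytest.fixture(scope="session")
def small_result(small_round_images):
    cfg = PipelineConfig(panel=PANEL, seed=11)
    return run_pipeline(cfg, small_round_images)


@pytest.fixture(scope="session")
def proportion_scene() -> Scene:
    """Geometry-only scene large enough for binomial recovery checks."""
    cfg = SceneConfig(
        seed=21, field_size_um=2200.0, n_cells=800, n_extra_nuclei=0,
        n_diffuse_speckles=0, n_process_fragments=0,
        min_separation_um=8.0, gfap_conflict_fraction=0.0,
    )
    return Scene(cfg)


@pytest.fixture(scope="session")
def touching_scene() -> Scene:
    """Dense plaque-contact scene for association-fraction recovery."""
    cfg = SceneConfig(
        seed=5, n_cells=700, field_size_um=2000.0, n_plaques=8,
        plaque_radius_um=90.0, n_tangles=0, n_diffuse_speckles=0,
        n_process_fragments=0, n_extra_nuclei=0, min_separation_um=6.0,
        phenotype_proportions={
            "IBA1+P2Y12+": 0.0, "IBA1-only": 0.0, "IBA1+Ferritin+": 0.0,
            "IBA1+Ferritin+CD68+": 0.5, "IBA1+CD68+": 0.5,
        },
        touching_fractions={"IBA1+Ferritin+CD68+": 0.76, "IBA1+CD68+": 0.40},
    )
    return Scene(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
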