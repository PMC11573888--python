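"""Shared fixtures: synthetic slides and one end-to-end pipeline run.

Everything is generated at test time from seeds; nothing is read from disk
fixtures. Expensive artifacts are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest

import wsidriver as w
from wsidriver.synthetic_slide import full_tissue_polygon


@pytest.fixture(scope="session")
def braf_slide():
    """Clean BRAF-phenotype slide, full tissue, nuclei kept clear of the
    512 px tile grid so per-patch ground-truth counts are unambiguous."""
    spec = w.SyntheticSlideSpec(
        width_px=2048,
        height_px=2048,
        phenotype=w.BRAF_PRESET,
        seed=11,
        tissue_polygons=(full_tissue_polygon(2048, 2048, 0),),
        nucleus_grid_margin_px=14.0,
    )
    pyramid, gt = w.generate_slide(spec)
    return spec, pyramid, gt


@pytest.fixture(scope="session")
def ras_slide():
    spec = w.SyntheticSlideSpec(
        width_px=2048,
        height_px=2048,
        phenotype=w.RAS_PRESET,
        seed=12,
        tissue_polygons=(full_tissue_polygon(2048, 2048, 0),),
        nucleus_grid_margin_px=14.0,
    )
    pyramid, gt = w.generate_slide(spec)
    return spec, pyramid, gt


@pytest.fixture(scope="session")
def artifact_slide():
    """Slide carrying one instance of each artifact kind."""
    spec = w.SyntheticSlideSpec(
        width_px=2048,
        height_px=2048,
        phenotype=w.BRAF_PRESET,
        seed=3,
        tissue_polygons=(full_tissue_polygon(2048, 2048),),
        artifacts=(
            ("pen", (100, 100, 400, 400)),
            ("blur", (1200, 1200, 500, 500)),
            ("blood", (1300, 200, 300, 300)),
            ("bubble", (300, 1400, 300, 300)),
        ),
    )
    pyramid, gt = w.generate_slide(spec)
    return spec, pyramid, gt


def _tiles(pyramid, n):
    coords = list(w.enumerate_candidates(pyramid))[:n]
    return np.stack([w.read_region(pyramid, c) for c in coords])


@pytest.fixture(scope="session")
def separable_tiles(braf_slide, ras_slide):
    """Train/held-out tile sets from the two clean slides (12 + 4 tiles per
    class; each 2048 px slide has 16 candidates)."""
    braf = _tiles(braf_slide[1], 16)
    ras = _tiles(ras_slide[1], 16)
    x_train = np.concatenate([braf[:12], ras[:12]])
    y_train = np.array([0] * 12 + [1] * 12)
    x_test = np.concatenate([braf[12:], ras[12:]])
    y_test = np.array([0] * 4 + [1] * 4)
    return x_train, y_train, x_test, y_test


@pytest.fixture(scope="session")
def trained_small_model(separable_tiles):
    """Small model trained to saturation on the separable tile set."""
    x, y, _, _ = separable_tiles
    cfg = w.ModelConfig(epochs=20, seed=0)
    model = w.build_model(cfg)
    best, log = w.train(model, (x, y), (x, y), cfg)
    return best, log, (x, y)


@pytest.fixture(scope="session")
def e2e_run(tmp_path_factory):
    """Full pipeline on a 20-sample fully separable cohort (small slides,
    small model); returns (config, run manifest data, workdir)."""
    from wsidriver.workflow import config_from_dict, run_pipeline

    workdir = tmp_path_factory.mktemp("e2e")
    cfg = config_from_dict(
        {
            "workdir": str(workdir),
            "seed": 5,
            "synth": {"n_braf": 10, "n_ras": 10, "separability": 1.0, "slide_px": 1536},
            "sampler": {"per_sample_train": 8, "per_slide_cap": 300},
            "model": {"epochs": 25},
        }
    )
    manifest = run_pipeline(cfg)
    return cfg, manifest, workdir
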