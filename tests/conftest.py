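"""Shared fixtures: small synthetic fields and desk-scale plate simulations."""

import numpy as np
import pytest

import aggscreen as ag

@pytest.fixture(scope="session")
def mutant_field():
    """One full-scale mutant-like field (400 cells, 85% positive)."""
    return ag.generate_field(ag.FieldSpec.mutant_like(), seed=7)


@pytest.fixture(scope="session")
def clean_field():
    """Noise- and gradient-free field: detection should be exact."""
    spec = ag.FieldSpec(n_cells=120, image_shape=(400, 400), noise_sd=0.0,
                        illumination_gradient_amplitude=0.0)
    return ag.generate_field(spec, seed=5)


@pytest.fixture(scope="session")
def tiny_layout():
    """Small plate: 10 genes x 3 replicates + 12 control wells."""
    return ag.build_plate_layout(10, 12, 3, seed=3)


def make_tiny_simulation(layout, seed=3, effects=None, n_fields=2):
    spec = ag.FieldSpec(n_cells=40, image_shape=(224, 224))
    return ag.generate_screen(layout, ag.DoseTimeModel(),
                              effects or ag.EffectTable(), n_fields, seed,
                              base_spec=spec)


def draw_null_well_values(rng, n_cells=180):
    """Per-cell intensity values under the null, without rendering images.

    Mimics the structure of screen data: a mixture of near-zero negative
    cells and bright positive cells, with a per-well intensity scale factor
    standing in for field-level illumination variation.
    """
    scale = rng.uniform(0.9, 1.1)
    positive = rng.random(n_cells) < 0.85
    vals = np.where(positive,
                    rng.normal(12.0, 3.0, n_cells),
                    rng.normal(0.5, 0.3, n_cells))
    return np.clip(vals * scale, 0.0, None)
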