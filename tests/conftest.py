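"""Shared fixtures: small rendered scenes reused across imaging tests."""

import numpy as np
import pytest

from stochexpr.synthetic import (GeneratorConfig, render_spot_image,
                                 render_stack, sample_scene)


@pytest.fixture(scope="session")
def protein_scene():
    """40 well-separated rods with known protein counts, rendered stack."""
    cfg = GeneratorConfig(n_cells=40)
    scene = sample_scene(cfg, seed=5)
    return render_stack(scene, seed=6)


@pytest.fixture(scope="session")
def control_scene():
    """Autofluorescence-only scene (zero protein) for background fitting."""
    cfg = GeneratorConfig(n_cells=40)
    scene = sample_scene(cfg, seed=15,
                         protein_counts=np.zeros(40, dtype=int))
    return render_stack(scene, seed=16)


@pytest.fixture(scope="session")
def spot_scene():
    """MS2-GFP spot image with true counts 1..8, three cells each."""
    counts = np.repeat(np.arange(1, 9), 3)
    cfg = GeneratorConfig(n_cells=len(counts))
    scene = sample_scene(cfg, seed=31, rna_counts=counts)
    return render_spot_image(scene, seed=32)
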