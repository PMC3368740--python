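"""Shared fixtures: phantoms and the expensive segmentation/rotation runs.

Session-scoped so the acceptance tests and unit tests reuse one
computation. All randomness is seeded; everything is generated in memory.
"""

from __future__ import annotations

import numpy as np
import pytest

from ccdtiseg.phantom import PhantomSpec, generate_cc_phantom
from ccdtiseg.rotation_sim import rotation_reproducibility_experiment
from ccdtiseg.segmentation import segment_corpus_callosum
from ccdtiseg.speed import SpeedParams

SMALL_SHAPE = (48, 72, 48)
ROTATION_ANGLES = [0.0, 10.0, 30.0]
ROTATION_SEEDS = (1, 2, 3)
NOISE_SD = 5e-5


@pytest.fixture(scope="session")
def default_truth():
    """Noise-free phantom at the default working-grid size."""
    return generate_cc_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def small_truth():
    """Noise-free phantom at the reduced size used for sweeps."""
    return generate_cc_phantom(PhantomSpec(grid_shape=SMALL_SHAPE))


@pytest.fixture(scope="session")
def default_segmentation(default_truth):
    """Full segmentation of the default noise-free phantom."""
    return segment_corpus_callosum(
        default_truth.tensors,
        default_truth.seeds_suggested,
        SpeedParams(),
        max_iters=1000,
    )


@pytest.fixture(scope="session")
def small_segmentation(small_truth):
    return segment_corpus_callosum(
        small_truth.tensors,
        small_truth.seeds_suggested,
        SpeedParams(),
        max_iters=800,
    )


@pytest.fixture(scope="session")
def rotation_report():
    """Rotation-reproducibility experiment over noisy phantom replicates.

    Reference masks are each replicate's own baseline segmentation, so the
    zero-angle cells compare a deterministic pipeline against itself.
    """
    volumes, masks, seed_sets = [], [], []
    for s in ROTATION_SEEDS:
        truth = generate_cc_phantom(
            PhantomSpec(grid_shape=SMALL_SHAPE, noise_sd=NOISE_SD, seed=s)
        )
        base = segment_corpus_callosum(
            truth.tensors, truth.seeds_suggested, SpeedParams(), max_iters=800
        )
        volumes.append(truth.tensors)
        masks.append(base.mask)
        seed_sets.append(truth.seeds_suggested)
    with np.errstate(all="ignore"):
        return rotation_reproducibility_experiment(
            volumes,
            masks,
            seed_sets,
            SpeedParams(),
            ROTATION_ANGLES,
            max_iters=800,
        )
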