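"""Shared fixtures.

The expensive session fixture ``scaled_training`` runs the scaled-down
end-to-end experiment once (phantom corpus, orthogonal-scan simulation at
x2, 500 iterations of L1 training) and is shared by every test that needs
a trained model, so the suite pays the training cost a single time.
"""

import numpy as np
import pytest

import isorecon as ir

# scaled-down study conditions: 32^3 phantoms, x2 scaling, 2-block/16-channel
# model, 500 iterations of batch 8 (12^3 cubes), 8 training + 1 held-out
SCALED = dict(
    n_phantoms=9,
    phantom=dict(size=(32, 32, 32), n_structures=6, lesion_count=0,
                 smoothness=0.6),
    scale=2.0,
    model=dict(n_blocks=2, base_channels=16, expansion=4),
    train=dict(batch_size=8, total_iters=500, cube_size=14, seed=0,
               lr_init=5e-4),
)


@pytest.fixture(scope="session")
def phantom_corpus():
    """Nine 32^3 phantoms plus their x2 orthogonal-scan simulations."""
    spec = ir.PhantomSpec(**SCALED["phantom"])
    phantoms = ir.make_phantom_set(SCALED["n_phantoms"], spec, base_seed=0)
    r = SCALED["scale"]
    entries = []
    for hr in phantoms:
        scans = ir.simulate_orthogonal_scans(hr, r)
        entries.append(dict(hr=ir.crop_to_factor(hr, r),
                            scans=scans, fused=ir.fuse_scans(scans)))
    return entries


@pytest.fixture(scope="session")
def scaled_training(phantom_corpus):
    """Train the toy model once on the first eight phantoms; the ninth is
    held out for evaluation."""
    model = ir.SRNetwork(ir.ModelConfig(**SCALED["model"]),
                         seed=SCALED["train"]["seed"])
    cfg = ir.TrainConfig(**SCALED["train"])
    source = [(e["fused"], e["hr"]) for e in phantom_corpus[:-1]]
    model, log = ir.train_model(model, source, cfg)
    held_out = phantom_corpus[-1]
    return dict(model=model, log=log, held_out=held_out,
                scale=SCALED["scale"])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_phantom():
    return ir.make_phantom(ir.PhantomSpec(size=(24, 24, 24), n_structures=5,
                                          smoothness=0.6, seed=3))
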