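import numpy as np
import pytest

from mcseg.hessianblob import hessian_dog_segment
from mcseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def standard_phantom():
    """One phantom image under the standard study conditions."""
    return generate_phantom(PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def phantom_bench():
    """20 phantom images with their blob-branch segmentations.

    Standard study conditions: 10 spots per 256x256 image, amplitude 0.4,
    width 1.5-2.5 px, pixel noise 0.01. Shared across detection and FROC
    tests because the blob branch is the expensive stage.
    """
    bench = []
    for seed in range(20):
        img, ann, truth, objs = generate_phantom(PhantomSpec(seed=seed))
        objects, blobs = hessian_dog_segment(img)
        bench.append(
            {"image": img, "annotations": ann, "truth": truth,
             "planted": objs, "objects": objects, "blobs": blobs}
        )
    return bench


@pytest.fixture(scope="session")
def trained_tiny():
    """Tiny regressor trained 50 epochs on 20 phantom patches.

    Returns the trained model, its training patches, the untrained
    baseline IoU, and the training history. Session-scoped: training is the
    most expensive fixture in the suite.
    """
    from mcseg.regressor import (
        RegressorSpec,
        build_regressor,
        mean_patch_iou,
        phantom_training_patches,
        train_regressor,
    )

    pairs = phantom_training_patches(20, size=64, n_spots=2, seed=5)
    spec = RegressorSpec.tiny(seed=0, epochs=50)
    model = build_regressor(spec)
    untrained_iou, _ = mean_patch_iou(model, pairs)
    model, history = train_regressor(model, pairs, pairs, spec)
    return {"model": model, "pairs": pairs, "untrained_iou": untrained_iou,
            "history": history}
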