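import numpy as np
import pytest

from fedseg.fingerprint import DatasetFingerprint
from fedseg.planner import ResourceBudget, TrainingPlan, make_plan


def fp_of_shapes(shapes, spacings=None, dim=2):
    """Fingerprint with the given case shapes (no intensity payload)."""
    shapes = [tuple(s) for s in shapes]
    if spacings is None:
        spacings = [(1.0,) * dim] * len(shapes)
    spacings = [tuple(s) for s in spacings]
    return DatasetFingerprint(
        shapes_after_crop=shapes,
        spacings=spacings,
        intensity_summary=None,
        n_cases=len(shapes),
        dimensionality=dim,
    )


def plan_for_patch(patch: int, base_features: int = 32, max_stages=None) -> TrainingPlan:
    """Plan whose patch size resolves to ``patch`` x ``patch``."""
    fp = fp_of_shapes([(patch, patch)] * 3, [(0.7, 0.7)] * 3)
    budget = ResourceBudget(
        max_patch_voxels=patch * patch, max_batch=12,
        max_stages=max_stages, base_features=base_features,
    )
    return make_plan(fp, budget)


@pytest.fixture
def tiny_plan() -> TrainingPlan:
    """A 3-stage 16x16 plan; cheap enough for forward/backward tests."""
    return TrainingPlan(
        target_spacing=(1.0, 1.0),
        median_shape=(16, 16),
        patch_size=(16, 16),
        batch_size=2,
        n_stages=3,
        features_per_stage=(4, 8, 16),
        n_poolings_per_axis=(2, 2),
        dimensionality=2,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
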