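import numpy as np
import pytest

from kinesia import synthetic


@pytest.fixture(scope="session")
def toy_atlas():
    return synthetic.generate_toy_atlas(seed=7)


@pytest.fixture(scope="session")
def small_atlas():
    """A few-region atlas small enough for brute-force voxel scans."""
    return synthetic.generate_toy_atlas(
        shape_voxels=(40, 60, 20), n_regions=3, seed=3
    )


@pytest.fixture(scope="session")
def small_cohort(toy_atlas):
    spec = synthetic.CohortSpec(
        n_control=3,
        n_deficient=3,
        neurons_per_larva=60,
        duration_s=200.0,
        seed=11,
    )
    larvae, truth, _ = synthetic.generate_calcium_cohort(spec, toy_atlas)
    return spec, larvae, truth


def planted_event_plan(rng, duration_s=1440.0, noise_sd=1.5):
    """Standard recovery plan: 30 events at >= 4x the realized noise floor,
    >= 3-s spacing, straddling every classifier threshold."""
    kinds = ["swim"] * 12 + ["left_flip"] * 6 + ["right_flip"] * 6 + ["struggle"] * 6
    rng.shuffle(kinds)
    plan, t = [], 8.0
    for k in kinds:
        dur = 1.2 if k == "struggle" else 1.0
        amp = (18.0 if k == "struggle" else 6.0) * noise_sd
        plan.append((k, float(t), dur, amp))
        t += dur + float(rng.uniform(4.0, 45.0))
    return [p for p in plan if p[1] + p[2] < duration_s - 5]
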