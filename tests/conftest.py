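import numpy as np
import pytest

import tmasking as tm
from tmasking.nn import CnnConfig, TrainingSchedule
from tmasking.experiments import run_configuration


def make_stack(volumes, labels, voxel_mm=1.0):
    volumes = np.asarray(volumes, dtype=float)
    n = volumes.shape[0]
    affine = np.diag([voxel_mm] * 3 + [1.0])
    return tm.VolumeStack(
        volumes=volumes,
        labels=np.asarray(labels),
        subject_ids=tuple(f"s{i:03d}" for i in range(n)),
        affine=affine,
        voxel_sizes_mm=np.array([voxel_mm] * 3),
    )


def full_mask(shape):
    return tm.BinaryMask(np.ones(shape, dtype=np.uint8))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_cohort(rng):
    """20 random 8^3 volumes, 10 per group."""
    vols = rng.normal(size=(20, 8, 8, 8))
    labels = np.r_[np.zeros(10, int), np.ones(10, int)]
    return make_stack(vols, labels), full_mask((8, 8, 8))


@pytest.fixture(scope="session")
def recovery_phantom():
    """Default recovery phantom: 32^3, Cohen's d 1.2, 40 per group."""
    spec = tm.PhantomSpec(seed=11)
    stack, brain, region = tm.generate_cohort(spec)
    return spec, stack, brain, region


DESK_SPEC = dict(
    grid_dims=(24, 24, 24),
    brain_semiaxes_vox=(10.0, 9.0, 8.0),
    effect_size=1.0,
    n_per_group=40,
)

FS_THRESHOLDS = (0.0, 3.2, 4.8)
RANDOM_P = 0.9
N_PERMUTATIONS = 5
MAX_EPOCHS = 30


@pytest.fixture(scope="session")
def desk_phantom():
    """24^3 phantom cohort for CNN experiments (d = 1.0, 40 per group)."""
    spec = tm.PhantomSpec(seed=5, **DESK_SPEC)
    stack, brain, region = tm.generate_cohort(spec)
    return stack, brain, region


@pytest.fixture(scope="session")
def fs_benefit_run(desk_phantom):
    """The feature-selection benefit experiment: fs_cnn swept over a coarse
    threshold grid (0 = whole brain) and the random-mask baseline at p = 0.9,
    5 split permutations each.  Shared across tests because CNN training
    dominates the suite's runtime."""
    stack, brain, region = desk_phantom
    cfg = CnnConfig.preset("desk")
    sched = TrainingSchedule(max_epochs=MAX_EPOCHS)
    fs_curve = run_configuration(
        "fs_cnn",
        stack,
        brain,
        grid=np.array(FS_THRESHOLDS),
        n_permutations=N_PERMUTATIONS,
        master_seed=123,
        model_config=cfg,
        schedule=sched,
        keep_models=True,
    )
    rnd_curve = run_configuration(
        "fs_random",
        stack,
        brain,
        grid=np.array([RANDOM_P]),
        n_permutations=N_PERMUTATIONS,
        master_seed=123,
        model_config=cfg,
        schedule=sched,
    )
    return fs_curve, rnd_curve
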