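import numpy as np
import pytest

from peptogrid import (
    DockingBox,
    PoseSet,
    SynthSpec,
    assign_types,
    build_frequency_grid,
    generate_pose_set,
    load_default_table,
)


@pytest.fixture(scope="session")
def table():
    return load_default_table()


@pytest.fixture()
def small_box():
    """10 Angstrom cube at 0.5 Angstrom step: 21^3 vertices."""
    return DockingBox(center=np.zeros(3), edges=np.full(3, 10.0), step=0.5)


@pytest.fixture(scope="session")
def typed_ensemble(table):
    """A typed 40-pose two-sequence synthetic ensemble in a 12 A box."""
    box = DockingBox(center=np.zeros(3), edges=np.full(3, 12.0), step=0.5)
    spec = SynthSpec(
        box=box, n_poses=40, sequences=("GFG", "AWA"),
        site_centers=((0.0, 0.0, 0.0),), site_fraction=0.5,
        jitter_sd=0.5, seed=11,
    )
    generated = generate_pose_set(spec)
    typed = PoseSet(
        poses=[assign_types(p, table) for p in generated.pose_set],
        box=box,
    )
    return typed, generated.site_labels


@pytest.fixture(scope="session")
def small_grid(typed_ensemble):
    typed, _ = typed_ensemble
    return build_frequency_grid(typed)


def type_pose_set(pose_set, table, box=None):
    return PoseSet(
        poses=[assign_types(p, table) for p in pose_set],
        box=box if box is not None else pose_set.box,
    )
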