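import numpy as np
import pytest

from surgtrack.scene import (
    InstrumentSpec,
    Scene,
    SceneConfig,
    default_scene_config,
)


def straight_instrument(
    n_frames: int,
    start=(100.0, 180.0),
    end=None,
    entry_side="left",
    entry_y=180.0,
    hue=0.02,
):
    """A single instrument moving linearly from start to end."""
    if end is None:
        end = start
    return InstrumentSpec(
        waypoint_frames=(0, n_frames - 1),
        waypoints=(tuple(start), tuple(end)),
        entry_side=entry_side,
        entry_y=entry_y,
        base_hue=hue,
    )


def single_instrument_config(n_frames=10, start=(100.0, 180.0), end=None, **kw):
    return SceneConfig(
        n_frames=n_frames,
        n_instruments=1,
        instruments=(straight_instrument(n_frames, start, end),),
        **kw,
    )


@pytest.fixture(scope="session")
def small_scene():
    """120-frame two-instrument scene with one crossing, exits and a pan."""
    return Scene(default_scene_config(n_frames=120, n_instruments=2, seed=42))


@pytest.fixture(scope="session")
def quiet_scene():
    """Event-free two-instrument scene (no crossings/exits/camera)."""
    return Scene(
        default_scene_config(
            n_frames=100,
            n_instruments=2,
            seed=7,
            with_occlusions=False,
            with_exits=False,
            with_camera_motion=False,
        )
    )


@pytest.fixture(scope="session")
def three_scene():
    """200-frame three-instrument scene with all event kinds."""
    return Scene(default_scene_config(n_frames=200, n_instruments=3, seed=2))
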