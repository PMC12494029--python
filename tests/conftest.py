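import warnings

import numpy as np
import pytest

from fawave.synthetic import generate_stack, generate_traces, stack_preset, trace_preset

warnings.filterwarnings("ignore", message="stack shorter than the 3D median window")


@pytest.fixture(scope="session")
def default_spec():
    from fawave.traction import PillarSpec

    return PillarSpec(radius_um=1.0, height_um=8.0, youngs_modulus_pa=2e6, pitch_um=4.0)


@pytest.fixture(scope="session")
def control_stack():
    """Noise-free control-preset stack with 10 FAs and its ground truth."""
    cfg = stack_preset("control", n_fas=10, seed=5)
    return cfg, *generate_stack(cfg)


@pytest.fixture(scope="session")
def noisy_stack():
    """Control-preset stack at the default camera-noise level."""
    cfg = stack_preset("control", n_fas=10, seed=5, noise=True)
    return cfg, *generate_stack(cfg)


@pytest.fixture(scope="session")
def paper_default_traces():
    """100-FA trace ensemble under untreated-cell conditions (seed 11)."""
    cfg = trace_preset("paper_default", n_fas=100, duration_s=1200.0, seed=11)
    return cfg, *generate_traces(cfg)


def make_segment(frame, label, x_um, y_um, area_um2=2.0, brightness=100.0,
                 pixel_size_um=0.2):
    """Minimal FASegment for tracking tests (pixel set is a dot)."""
    from fawave.segmentation import FASegment

    r, c = int(y_um / pixel_size_um), int(x_um / pixel_size_um)
    return FASegment(
        frame=frame, label=label, area_um2=area_um2, centroid_um=(x_um, y_um),
        mean_brightness=brightness, pixels=np.array([[r, c]]),
    )
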