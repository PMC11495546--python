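import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sampam.phantom import (AcousticLayer, PhantomConfig, TransducerConfig,
                            generate_phantom)

settings.register_profile(
    "default", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def transducer() -> TransducerConfig:
    return TransducerConfig()


def make_layers(*, water=0.5e-3, skin=1.3e-3, skin_speed=1550.0,
                skin_absorption=0.0, film=False, film_absorption=0.0,
                dish=True):
    """Compact layer-stack builder for test phantoms."""
    layers = [
        AcousticLayer(name="water", thickness=water, sound_speed=1500.0,
                      acoustic_impedance=1.48e6),
        AcousticLayer(name="skin", thickness=skin, sound_speed=skin_speed,
                      acoustic_impedance=1.65e6,
                      optical_absorption=skin_absorption),
    ]
    if film:
        layers.append(AcousticLayer(name="film", thickness=124e-6,
                                    sound_speed=2620.0,
                                    acoustic_impedance=3.1e6,
                                    optical_absorption=film_absorption))
    if dish:
        layers.append(AcousticLayer(name="dish", thickness=1.0e-3,
                                    sound_speed=2350.0,
                                    acoustic_impedance=2.47e6))
    return layers


@pytest.fixture
def slab_phantom():
    """Noise-free single-A-line water/skin/dish phantom (no inclusions)."""
    cfg = PhantomConfig(grid_nx=1, grid_ny=1, layers=make_layers(),
                        pigment_count=0, scale_count=0, noise_std=0.0,
                        skin_layer="skin", petridish_echo=False, seed=0)
    return generate_phantom(cfg)


def point_phantom(z0: float, *, absorbing_top=True, seed=0,
                  noise_std=0.0) -> PhantomConfig:
    """Water over an absorbing skin face at depth z0.

    The skin's top face is both an impedance step (SAM echo) and, when
    ``absorbing_top``, a photoacoustic source — a point structure visible
    in both modalities at the same true depth.
    """
    layers = [
        AcousticLayer(name="water", thickness=z0, sound_speed=1500.0,
                      acoustic_impedance=1.48e6),
        AcousticLayer(name="skin", thickness=0.8e-3, sound_speed=1500.0,
                      acoustic_impedance=1.65e6,
                      optical_absorption=1.0 if absorbing_top else 0.0),
    ]
    return PhantomConfig(grid_nx=1, grid_ny=1, layers=layers, pigment_count=0,
                         scale_count=0, noise_std=noise_std, seed=seed,
                         skin_layer="skin", petridish_echo=False)
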