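"""Shared fixtures: synthetic sequences and graphs built once per session."""
import numpy as np
import pytest

import endograph as eg


@pytest.fixture(scope="session")
def texture():
    return eg.make_texture(seed=3)


@pytest.fixture(scope="session")
def sequence(texture):
    """Default 12-frame noiseless sequence, two anatomic sites."""
    return eg.make_sequence(texture, n_frames=12, seed=5, n_sites=2)


@pytest.fixture(scope="session")
def graph(sequence):
    """Image graph of the default sequence at the desk-scale threshold."""
    return eg.build_graph(sequence.frames, 0.3, seed=2)


@pytest.fixture(scope="session")
def markers6(sequence):
    return eg.make_phantom_markers(sequence, 6, radius=10.0, seed=7)


@pytest.fixture(scope="session")
def noisy_sequence(texture):
    return eg.make_sequence(texture, n_frames=12, seed=5, n_sites=2,
                            noise_sigma=0.05)


@pytest.fixture(scope="session")
def noisy_graph(noisy_sequence):
    return eg.build_graph(noisy_sequence.frames, 0.3, seed=2)


@pytest.fixture(scope="session")
def small_features(texture):
    """Feature sets of two neighbouring synthetic frames (cheap reuse)."""
    seq = eg.make_sequence(texture, n_frames=2, seed=21)
    f0 = eg.extract_features(seq.frames[0].image)
    f1 = eg.extract_features(seq.frames[1].image)
    return seq, f0, f1


def random_affine(rng, max_rot=0.5, scale_lo=0.8, scale_hi=1.25, max_t=40.0):
    """Well-conditioned random affine (shared helper for algebra tests)."""
    theta = rng.uniform(-max_rot, max_rot)
    sx, sy = rng.uniform(scale_lo, scale_hi, 2)
    shear = rng.uniform(-0.1, 0.1)
    tx, ty = rng.uniform(-max_t, max_t, 2)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    lin = rot @ np.array([[sx, shear * sx], [0.0, sy]])
    m = np.eye(3)
    m[:2, :2] = lin
    m[:2, 2] = (tx, ty)
    return eg.AffineTransform(m)
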