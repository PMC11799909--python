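import numpy as np
import pytest

from planscope import Beam, ControlPoint, MachineLimits, Plan


def make_random_beam(rng, n_cp=5, n_pairs=4, beam_mu=120.0, leaf_width=10.0):
    """A valid random arc: sorted meterset weights, non-negative gaps."""
    w = np.sort(rng.uniform(0, 1, n_cp))
    w[0], w[-1] = 0.0, 1.0
    half = leaf_width * n_pairs / 2.0
    boundaries = -half + leaf_width * np.arange(n_pairs + 1)
    gantry0 = rng.uniform(0, 360)
    cps = []
    for i in range(n_cp):
        a = rng.uniform(-60, 40, n_pairs)
        gaps = rng.choice([0.0, 0.3, 1.5, 4.0, 8.0, 25.0], size=n_pairs)
        cps.append(ControlPoint(
            index=i,
            cumulative_meterset_weight=float(w[i]),
            gantry_angle=float((gantry0 + 2.0 * i) % 360),
            bank_a_positions=a,
            bank_b_positions=a + gaps,
            jaw_x=(-100.0, 100.0),
            jaw_y=(-half, half),
        ))
    return Beam(beam_mu=beam_mu, control_points=cps, leaf_boundaries=boundaries,
                machine_limits=MachineLimits())


def make_uniform_beam(n_cp=3, n_pairs=4, gap=20.0, tip_center=0.0, beam_mu=100.0,
                      leaf_width=5.0, jaw_x=(-100.0, 100.0), gantry_step=2.0):
    """A static beam with every pair open at the same gap (handy for arithmetic)."""
    half = leaf_width * n_pairs / 2.0
    boundaries = -half + leaf_width * np.arange(n_pairs + 1)
    cps = []
    for i in range(n_cp):
        a = np.full(n_pairs, tip_center - gap / 2.0)
        cps.append(ControlPoint(
            index=i,
            cumulative_meterset_weight=i / (n_cp - 1),
            gantry_angle=(180.0 + gantry_step * i) % 360,
            bank_a_positions=a,
            bank_b_positions=a + gap,
            jaw_x=jaw_x,
            jaw_y=(-half, half),
        ))
    return Beam(beam_mu=beam_mu, control_points=cps, leaf_boundaries=boundaries)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_beam(rng):
    return make_random_beam(rng)


@pytest.fixture
def uniform_beam():
    return make_uniform_beam()
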