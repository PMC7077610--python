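import math

import numpy as np
import pytest
from hypothesis import settings

from affectvar import AffectPoint, SimConfig, generate_study

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_points(thetas, distances):
    """Affect points from polar coordinates (test helper)."""
    return [
        AffectPoint(valence=d * math.cos(t), activation=d * math.sin(t))
        for t, d in zip(thetas, distances)
    ]


def circular_sd_angle_space(points):
    """Independent angle-space oracle for spin.

    Computes each point's angle with a quadrant-aware arctangent, averages
    the unit vectors in angle space, and returns sqrt(-2 ln mean-resultant-
    length) — sharing no code with the vector-formula implementation.
    """
    angles = [math.atan2(p.activation, p.valence) for p in points if not p.is_degenerate]
    c = sum(math.cos(a) for a in angles) / len(angles)
    s = sum(math.sin(a) for a in angles) / len(angles)
    r = math.hypot(c, s)
    return math.sqrt(-2.0 * math.log(min(r, 1.0)))


@pytest.fixture(scope="session")
def small_study():
    """A 30-participant synthetic study shared by structural tests."""
    return generate_study(SimConfig(seed=7, n_participants=30))


@pytest.fixture(scope="session")
def small_long(small_study):
    return small_study.outcomes_long


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_study_scale_long(seed, gamma, tau=1.55, sigma=1.10,
                          n_participants=214, n_sessions=14, change_after=7):
    """Study-scale long table with person traits and configurable true effects.

    Draws person spin/pulse from the cohort anchor distributions directly
    (no affect series needed) and generates the outcome from the supplied
    coefficient dict — a lightweight path for replicated recovery and
    calibration runs.
    """
    import pandas as pd

    from affectvar.growth_design import ChangeDesign, attach_design
    from affectvar.synthetic_data import simulate_outcomes

    rng = np.random.default_rng(seed)
    pids = np.repeat(np.arange(n_participants), n_sessions)
    long = pd.DataFrame(
        {
            "participant_id": pids,
            "session_index": np.tile(np.arange(1, n_sessions + 1), n_participants),
        }
    )
    long = attach_design(long, ChangeDesign(n_sessions, change_after))
    spin_p = np.clip(rng.normal(0.83, 0.51, n_participants), 0.05, None)
    pulse_p = np.clip(rng.normal(2.49, 0.94, n_participants), 0.2, None)
    long["spin"] = spin_p[pids]
    long["pulse"] = pulse_p[pids]
    streams = {
        pid: np.random.default_rng((seed, int(pid))) for pid in range(n_participants)
    }
    long["outcome"] = simulate_outcomes(long, gamma, tau=tau, sigma=sigma, streams=streams)
    return long
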