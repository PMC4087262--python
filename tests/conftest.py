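"""Shared fixtures: scaled-down sessions of the motor-imagery paradigm.

The timing fixture keeps the paradigm's structure (baseline, cue, task,
variable rest, task-onset markers) but shortens the periods and samples at
250 Hz directly, so whole-pipeline tests stay fast.  The generator's own
defaults remain the full-length protocol.
"""

from __future__ import annotations

import numpy as np
import pytest

import tfpbci as t

#: Scaled-down trial timing used throughout the tests (epochs need
#: >= 1 s on each side of task onset).
FAST_TIMING = t.TrialTimingSpec(
    baseline_s=1.5, cue_s=0.5, task_s=2.0, rest_s=(0.5, 0.7), fs_hz=250.0
)

LABEL_MAP = {"speed": 0, "force": 1}


def phase_effects(offset: float = np.pi / 2, jitter: float = 0.3):
    """Class difference only in mu phase dynamics (band power matched)."""
    return {
        "speed": [t.ClassEffectSpec("mu", "phase_dynamics", -offset, noise_sd=jitter)],
        "force": [t.ClassEffectSpec("mu", "phase_dynamics", +offset, noise_sd=jitter)],
    }


def power_effects(ratio: float = 0.5):
    """Class difference only in mu band power (phase left random)."""
    return {
        "speed": [t.ClassEffectSpec("mu", "power_shift", ratio, noise_sd=0.1)],
        "force": [t.ClassEffectSpec("mu", "power_shift", 1.0, noise_sd=0.1)],
    }


def null_effects():
    """Identical specs for both classes: no class difference at all."""
    spec = [t.ClassEffectSpec("mu", "power_shift", 1.0, noise_sd=0.1)]
    return {"speed": list(spec), "force": list(spec)}


def make_session(effects, seed, n_trials=60, montage=None, timing=FAST_TIMING, **kw):
    montage = montage or t.make_montage("paper21")
    return t.simulate_session(
        montage, timing, effects, n_trials=n_trials, rng_seed=seed, **kw
    )


def session_epochs(effects, seed, n_trials=60, montage=None, laplacian=True):
    """Simulate, broadband-filter, (Laplacian), and epoch one session."""
    montage = montage or t.make_montage("paper21")
    rec = make_session(effects, seed, n_trials, montage)
    rec = t.bandpass(rec, (5.0, 45.0))
    if laplacian:
        rec = t.laplacian_filter(rec, montage)
    return t.epoch(rec, t.EpochConfig(label_map=LABEL_MAP))


@pytest.fixture(scope="session")
def montage21():
    return t.make_montage("paper21")


@pytest.fixture(scope="session")
def small_recording():
    """4-trial paper21 session for I/O and preprocessing tests."""
    return make_session(power_effects(), seed=7, n_trials=4)


@pytest.fixture(scope="session")
def power_world_epochs():
    """One 60-trial session with a planted mu power difference."""
    return session_epochs(power_effects(), seed=11)


@pytest.fixture(scope="session")
def phase_world_epochs():
    """One 60-trial session with a planted mu phase difference."""
    return session_epochs(phase_effects(), seed=11)
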