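"""Shared fixtures: synthetic sessions and tuned cell batteries.

Heavy simulations are session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

import bordercell as bc
from bordercell import synthetic as syn
from bordercell.classify import ShuffleEngine
from bordercell.pipeline import RunConfig, analyze_cells


@pytest.fixture(scope="session")
def square_arena():
    return bc.make_arena("square", 100.0)


@pytest.fixture(scope="session")
def session_600(square_arena):
    """A 600 s, 50 Hz foraging session in the 1 m square arena."""
    return syn.simulate_trajectory(
        square_arena, syn.TrajectoryParams(duration=600.0), seed=1)


@pytest.fixture(scope="session")
def mask_600(session_600):
    mask, _ = bc.speed_filter(session_600, np.empty(0))
    return mask


@pytest.fixture(scope="session")
def tuned_cells(session_600, square_arena):
    """One spike train per response model on the shared 600 s session."""
    specs = {
        "allo": syn.CellSpec("allocentric_border"),
        "left": syn.CellSpec("left_ego"),
        "right": syn.CellSpec("right_ego", bearing_pref=270.0),
        "unif": syn.CellSpec("uniform", base_rate=5.0),
        "theta": syn.CellSpec("uniform", base_rate=5.0, theta_depth=0.8,
                              theta_freq=8.0),
    }
    out = {}
    for k, (name, spec) in enumerate(specs.items()):
        lam = syn.rate_function(spec, square_arena)
        out[name] = syn.generate_spikes(session_600, lam, spec.lam_max,
                                        seed=100 + k, unit_id=name)
    return out


def filtered(session, train):
    """Speed-filtered spike times of a train on a session."""
    _, st = bc.speed_filter(session, train.spike_times)
    return st


@pytest.fixture(scope="session")
def engine_600(session_600):
    return ShuffleEngine(session_600)


@pytest.fixture(scope="session")
def recovery(square_arena):
    """Labeled 50-unit population (1200 s) pushed through the pipeline.

    10 allocentric + 10 left-ego + 10 right-ego border cells plus 20
    uniform distractors, gain/base = 10/1 Hz, analysed with the default
    configuration (100 shuffles per cell).
    """
    pop = syn.make_population(
        10, 10, 10, 20, 0, arena=square_arena,
        params=syn.TrajectoryParams(duration=1200.0), seed=7)
    result = analyze_cells(pop.session, pop.cells, RunConfig(seed=1),
                           waveform_fs=pop.waveform_fs)
    frame = result.frame.merge(pop.labels, on="unit_id")
    return pop, result, frame


@pytest.fixture(scope="session")
def calibration(square_arena):
    """200 homogeneous-Poisson cells through the full shuffle gate."""
    session = syn.simulate_trajectory(
        square_arena, syn.TrajectoryParams(duration=600.0), seed=11)
    rng = np.random.default_rng(12)
    cells = []
    for k in range(200):
        spec = syn.CellSpec("uniform", base_rate=float(rng.uniform(1, 8)))
        lam = syn.rate_function(spec, square_arena)
        cells.append(syn.generate_spikes(session, lam, spec.lam_max,
                                         seed=int(rng.integers(2 ** 31)),
                                         unit_id=f"u{k:03d}"))
    engine = ShuffleEngine(session)
    null = bc.build_null(session, cells, n_shuffles=100, rng=13,
                         engines=[engine] * len(cells))
    observed = [engine.score(c.spike_times) for c in cells]
    return null, observed
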