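import numpy as np
import pytest

from memperturb import AnalysisConfig, make_bilayer_trajectory
from memperturb.synthetic import EventScript, ScriptedEvent


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def mixed_script():
    """Expulsions, flip-flops, a PBC crossing and a re-entry, 22 enhancers."""
    events = [
        ScriptedEvent(0, "expel", 10, 30),
        ScriptedEvent(1, "expel", 25, 45),
        ScriptedEvent(2, "expel", 40, 60),
        ScriptedEvent(3, "expel", 55, 75),
        ScriptedEvent(4, "expel", 70, 90),
        ScriptedEvent(5, "flipflop", 15, 45),
        ScriptedEvent(6, "flipflop", 50, 80),
        ScriptedEvent(7, "flipflop", 100, 130),
        ScriptedEvent(8, "pbc_cross", 120, 126),
        ScriptedEvent(9, "expel_return", 20, 40,
                      {"return_start": 100, "return_end": 120}),
    ]
    return EventScript(events)


@pytest.fixture(scope="session")
def scripted_traj(mixed_script):
    traj, truth = make_bilayer_trajectory(
        n_pe=22, script=mixed_script, n_frames=160, seed=42
    )
    return traj, truth


@pytest.fixture(scope="session")
def quiet_traj():
    """Small all-stay bilayer for structure/order/contact tests."""
    traj, truth = make_bilayer_trajectory(n_pe=6, n_frames=12, seed=7)
    return traj, truth
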