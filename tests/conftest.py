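import numpy as np
import pytest

from biocyberloop import LoopConfig, generate_recording, script_from_states
from biocyberloop import metrics as metrics_mod


@pytest.fixture(scope="session")
def baseline_profile():
    """One calibrated resting baseline shared across tests (60-s relaxation)."""
    return metrics_mod.make_baseline(seed=101)


@pytest.fixture(scope="session")
def boredom_recording():
    """300-s all-boredom stream at deviation strength 3."""
    script = script_from_states([(300.0, "boredom")], 3.0)
    return generate_recording(script, seed=202)


@pytest.fixture(scope="session")
def baseline_recording_300s():
    """300-s no-deviation stream (ratios ~1 throughout)."""
    script = script_from_states([(300.0, "baseline")])
    return generate_recording(script, seed=303)


@pytest.fixture
def liberal_config(baseline_profile):
    return LoopConfig(baseline=baseline_profile, seed=404)
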