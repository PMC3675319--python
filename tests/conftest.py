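import numpy as np
import pytest

from tim2iron import build_protocol, load_table1


@pytest.fixture(scope="session")
def params():
    """Packaged reference parameter set (extracted TIM-2 constants)."""
    return load_table1()


@pytest.fixture(scope="session")
def tim2_protocols():
    """Uptake + storage protocols for the TIM-2 line, keyed as in datasets."""
    return {name + "_tim2": build_protocol(name, "tim2") for name in ("uptake", "storage")}


@pytest.fixture(scope="session")
def storage_hourly(params):
    """Noise-free storage chase sampled hourly (for decay-phase analysis)."""
    from tim2iron import observe, simulate

    proto = build_protocol("storage", "tim2", sample_times_min=np.arange(0.0, 2881.0, 60.0))
    traj = simulate(proto, params)
    times, biotin = observe(traj, "biotinylated_55fe")
    return traj, times, biotin
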