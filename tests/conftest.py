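import numpy as np
import pytest

import serialbias as sb


@pytest.fixture(scope="session")
def e1_spec():
    return sb.DesignSpec.for_experiment(1)


@pytest.fixture(scope="session")
def regime_table(e1_spec):
    """Simulated E1 dataset in the human-data parameter regime.

    14 participants x 288 trials, repulsive adaptation ~2.2 deg, attractive
    serial dependence ~1.2 deg, 3-deg momentum shift, 9-deg noise.
    """
    return sb.simulate_dataset(e1_spec, 14, sb.ObserverParams(), seed=11)


@pytest.fixture(scope="session")
def regime_clean(regime_table):
    clean, _ = sb.preprocess(regime_table)
    return clean


@pytest.fixture(scope="session")
def null_table(e1_spec):
    """Bias-free observer: response noise only."""
    return sb.simulate_dataset(e1_spec, 10, sb.ObserverParams.null(9.0), seed=7)
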