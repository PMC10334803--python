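import numpy as np
import pytest

import wlcgating as wg


@pytest.fixture(scope="session")
def params16() -> wg.WLCParams:
    """Default 16-residue linker parameters (lp 0.38 nm, kBT 4.114 pN nm)."""
    return wg.WLCParams()


@pytest.fixture(scope="session")
def ensemble():
    """Calibrated synthetic closed state + six open structures (posed)."""
    closed, closed_truth = wg.closed_state_fixture()
    opens, truths = wg.open_state_ensemble(seed=7)
    truths[closed.id] = closed_truth
    return closed, opens, truths


@pytest.fixture(scope="session")
def ensemble_report(ensemble) -> wg.AnalysisReport:
    closed, opens, _ = ensemble
    return wg.run_analysis([closed] + opens)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230703)
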