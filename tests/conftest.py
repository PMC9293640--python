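import numpy as np
import pytest

import rg4fret as r


@pytest.fixture(scope="session")
def atrg3_dataset():
    """Small ATRG3-configured dataset shared by read-only tests."""
    return r.simulate_dataset(r.atrg3_model(), n_molecules=60, n_frames=300, seed=11)


@pytest.fixture(scope="session")
def atrg3_analysis(atrg3_dataset):
    from rg4fret.pipeline import analyze_condition

    return analyze_condition(
        atrg3_dataset.traces, n_states=3, seed=11, hmm_restarts=3, condition="K10"
    )


def pure_emission_traces(model, n_traces, n_frames, seed):
    """FRET observation arrays straight from state paths + Gaussian emission.

    Bypasses the camera/bleaching layer for tests that target the HMM and
    mixture estimators directly.
    """
    rng_master = np.random.SeedSequence(seed)
    out, paths = [], []
    for child in rng_master.spawn(n_traces):
        rng = np.random.default_rng(child)
        path = r.simulate_state_path(model, n_frames, rng)
        obs = rng.normal(model.emission_means[path], model.emission_sds[path])
        out.append(np.clip(obs, 0.0, 1.0))
        paths.append(path)
    return out, paths
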