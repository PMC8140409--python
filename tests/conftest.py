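import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pmhia import scenarios
from pmhia.synthetic_data import SynthSpec, known_truth_case, write_synthetic_bundle

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def synth_spec() -> SynthSpec:
    """Default-condition generator spec with a fixed seed."""
    return SynthSpec(seed=1)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, synth_spec):
    """A complete synthetic input bundle written to disk once per session."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths = write_synthetic_bundle(synth_spec, outdir)
    return paths


@pytest.fixture(scope="session")
def scenario_results(bundle_dir):
    """Present and future scenario runs on the session bundle."""
    present_cfg, future_cfg = scenarios.load_config(bundle_dir["config"])
    return scenarios.run_scenario(present_cfg), scenarios.run_scenario(future_cfg)


@pytest.fixture(scope="session")
def truth_bundle():
    return known_truth_case()


def max_rel_err(expected, got) -> float:
    """Elementwise relative error, treating exact-zero pairs as agreeing."""
    e = np.asarray(expected, dtype=float)
    g = np.asarray(got, dtype=float)
    err = np.zeros(np.broadcast(e, g).shape)
    nz = ~((e == 0) & (g == 0))
    err[nz] = np.abs(e - g)[nz] / np.maximum(np.abs(e)[nz], 1e-300)
    return float(err.max()) if err.size else 0.0
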