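import numpy as np
import pytest

from proxcal import ALL_STRATA, GeneratorTruth, datasets, logstore, synthetic


@pytest.fixture(scope="session")
def example_logs():
    return datasets.example_logs()


@pytest.fixture()
def example_log_csv(tmp_path, example_logs):
    path = tmp_path / "logs.csv"
    logstore.write_logs(example_logs, path)
    return path


@pytest.fixture(scope="session")
def default_params():
    return datasets.default_coefficients()


@pytest.fixture(scope="session")
def default_truth(default_params):
    var = datasets.default_variance_components()
    return GeneratorTruth(
        params=default_params,
        var_send=var["var_send"],
        var_receive=var["var_receive"],
        cov_send_receive=var["cov_send_receive"],
        var_exchange=dict(var["var_exchange"]),
        var_replicate=var["var_replicate"],
        var_residual=var["var_residual"],
    )


@pytest.fixture(scope="session")
def two_strata():
    # one ground, one arboreal stratum from different habitats
    return (ALL_STRATA[0], ALL_STRATA[7])


@pytest.fixture(scope="session")
def small_calibration(default_truth, two_strata):
    """Two-trial calibration dataset with the full noise structure."""
    designs = [
        synthetic.build_array(12, stratum=s, trial_id=i)
        for i, s in enumerate(two_strata)
    ]
    return synthetic.simulate_calibration(
        designs, default_truth, pulses_per_direction=2, seed=11
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20151)
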