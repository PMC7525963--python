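import numpy as np
import pytest

from ddmkit import SyntheticScenario, simulate_dataset, simulate_truth


@pytest.fixture(scope="session")
def perfect():
    """Noiseless closed stable population, full registration and coverage."""
    s = SyntheticScenario()
    ds, truth = simulate_dataset(s)
    return s, ds, truth


@pytest.fixture(scope="session")
def c070():
    """Stable population with constant completeness 0.7."""
    s = SyntheticScenario(true_completeness=0.7)
    ds, truth = simulate_dataset(s)
    return s, ds, truth


@pytest.fixture(scope="session")
def stationary_c060():
    """Stationary (zero growth) population with constant completeness 0.6."""
    s = SyntheticScenario(true_completeness=0.6, growth_rate=0.0)
    ds, truth = simulate_dataset(s)
    return s, ds, truth


@pytest.fixture()
def write_intercensal(tmp_path):
    """Write a toy intercensal CSV + sidecar config, return both paths."""

    def _write(rows, census1_time=2000.0, census2_time=2010.0, **cfg_extra):
        import yaml

        csv_path = tmp_path / "data.csv"
        lines = ["region,sex,age,pop1,pop2,deaths"]
        lines += [",".join(str(v) for v in row) for row in rows]
        csv_path.write_text("\n".join(lines) + "\n")
        cfg = {"census1_time": census1_time, "census2_time": census2_time}
        cfg.update(cfg_extra)
        cfg_path = csv_path.with_suffix(".yaml")
        cfg_path.write_text(yaml.safe_dump(cfg))
        return csv_path, cfg_path

    return _write
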