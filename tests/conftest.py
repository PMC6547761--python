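import warnings

import pytest
from hypothesis import HealthCheck, settings

from asnmd.pipeline import run_pipeline
from asnmd.synthetic_data import ScenarioConfig, build_scenario, write_scenario

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


SMALL_CONFIG = dict(
    n_genes=30,
    n_poison_loops=3,
    n_essential_loops=3,
    n_codirectional=1,
    n_null_rbps=4,
)


@pytest.fixture(scope="session")
def small_scenario(tmp_path_factory):
    """A 30-gene scenario with 7 planted loops, written to disk once."""
    cfg = ScenarioConfig(seed=11, **SMALL_CONFIG)
    scenario = build_scenario(cfg)
    out = tmp_path_factory.mktemp("scenario")
    write_scenario(scenario, out, force=True)
    return scenario, out


@pytest.fixture(scope="session")
def small_pipeline(small_scenario):
    scenario, out = small_scenario
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_pipeline(out, min_bin_records=20)
    return scenario, result


def write_toy_gtf(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return str(path)


def write_toy_fasta(path, seqs):
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
    return str(path)
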