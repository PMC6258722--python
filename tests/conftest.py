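import json
from importlib.resources import files
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from speqtl.pipeline import RunConfig, run_all  # noqa: E402
from speqtl.synthetic import GenomeSpec, SimulationConfig  # noqa: E402


@pytest.fixture(scope="session")
def demo_config() -> RunConfig:
    """The packaged demonstration study (fixed seed, planted effects)."""
    return RunConfig.from_yaml(files("speqtl") / "data" / "demo.yaml")


@pytest.fixture(scope="session")
def demo_run(demo_config, tmp_path_factory):
    """One full pipeline run on the packaged demo config; reused read-only."""
    outdir = tmp_path_factory.mktemp("demo_run")
    report = run_all(demo_config, outdir)
    return {"report": report, "outdir": outdir, "config": demo_config}


@pytest.fixture()
def tiny_sim_config() -> SimulationConfig:
    """A minimal two-chromosome study for fast unit tests."""
    return SimulationConfig(
        genome=GenomeSpec(
            chromosomes=[("chr1", 100_000), ("chr2", 80_000)],
            fragment_size_mean=1000, n_genes=12, n_snps=20,
            hla_like_interval=("chr1", 0, 30_000),
            gene_length_min=1500, gene_length_max=5000,
        ),
        tissues=["t1", "t2"], n_samples=80, n_cis_effects=3, n_trans_effects=1,
        beta=2.0, noise_sd=1.0, background_rate=0.0, min_samples=70,
    )


def load_golden(name: str):
    return json.loads((Path(__file__).parent / "data" / name).read_text())
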