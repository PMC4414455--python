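import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from typhamir.pipeline import PipelineConfig, run_pipeline
from typhamir.synthetic import simulate

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

SIM_SEED = 101
SIM_DEPTH = 30_000


@pytest.fixture(scope="session")
def sim(tmp_path_factory):
    """One medium-depth simulated input bundle shared by the suite."""
    outdir = tmp_path_factory.mktemp("sim")
    return simulate(seed=SIM_SEED, outdir=outdir, depth=SIM_DEPTH)


def config_for(data, outdir) -> PipelineConfig:
    return PipelineConfig(
        reads_ck=str(data.paths["reads_ck"]),
        reads_cd=str(data.paths["reads_cd"]),
        transcriptome=str(data.paths["transcriptome"]),
        mature_ref=str(data.paths["mature_ref"]),
        ncrna_genbank=str(data.paths["ncrna_genbank"]),
        ncrna_genbank_types=str(data.paths["ncrna_genbank_types"]),
        ncrna_rfam=str(data.paths["ncrna_rfam"]),
        ncrna_rfam_types=str(data.paths["ncrna_rfam_types"]),
        outdir=str(outdir),
        seed=SIM_SEED,
    )


@pytest.fixture(scope="session")
def report(sim, tmp_path_factory):
    """Full pipeline run on the shared simulation."""
    outdir = tmp_path_factory.mktemp("run")
    return run_pipeline(config_for(sim, outdir))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
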