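import numpy as np
import pytest

from epiloop import pipeline, synthdata


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Tiny synthetic dataset (noise off) plus its ground truth."""
    outdir = tmp_path_factory.mktemp("tiny")
    truth = synthdata.generate_all(synthdata.preset("tiny", 11), outdir)
    return outdir, truth


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """Default-scale synthetic dataset: the main planted-truth surface."""
    outdir = tmp_path_factory.mktemp("default")
    truth = synthdata.generate_all(synthdata.preset("default", 11), outdir)
    return outdir, truth


@pytest.fixture(scope="session")
def default_run(default_dataset, tmp_path_factory):
    """Full pipeline run on the default dataset, with stage objects kept."""
    outdir, truth = default_dataset
    cfg = pipeline.load_config(outdir / "config.yaml")
    cfg.outdir = str(tmp_path_factory.mktemp("default_out"))
    report = pipeline.run_pipeline(cfg)
    return cfg, truth, report
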