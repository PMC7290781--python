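import pytest
from hypothesis import settings

from venomkit import pipeline, synthetic

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

DATASET_SEED = 1


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """Default synthetic venom-gland dataset plus its ground truth."""
    d = tmp_path_factory.mktemp("dataset")
    cfg = synthetic.GeneratorConfig()
    truth = synthetic.generate_dataset(cfg, DATASET_SEED, d)
    return d, truth, cfg


@pytest.fixture(scope="session")
def pipeline_config(dataset):
    d, _, _ = dataset
    return {
        "inputs": {
            "contigs": str(d / "contigs.fasta"),
            "counts": str(d / "counts.tsv"),
            "annotations": str(d / "annotations.tsv"),
            "signal_annotations": str(d / "signal_annotations.tsv"),
            "evidence": str(d / "evidence.tsv"),
        }
    }


@pytest.fixture(scope="session")
def pipeline_out(pipeline_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("reports")
    reports = pipeline.run_pipeline(pipeline_config, out)
    return out, reports
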