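import pytest

import equitrx as ex

SEED = 11


@pytest.fixture(scope="session")
def design():
    return ex.StudyDesign(seed=SEED)


@pytest.fixture(scope="session")
def corpus():
    """Default small 24-sample corpus shared across the suite."""
    return ex.generate_corpus(ex.CorpusConfig(seed=SEED))


@pytest.fixture(scope="session")
def corpus_paths(corpus, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("corpus")
    return corpus.write(outdir)


@pytest.fixture(scope="session")
def pipeline_config(corpus_paths, tmp_path_factory):
    from equitrx.pipeline import PipelineConfig

    keys = set(PipelineConfig.__dataclass_fields__)
    return PipelineConfig(
        outdir=str(tmp_path_factory.mktemp("pipe_out")),
        **{k: str(v) for k, v in corpus_paths.items() if k in keys},
    )
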