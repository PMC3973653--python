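import numpy as np
import pytest

from canesrna import pipeline as pl
from canesrna import synthetic
from canesrna.config import PipelineConfig


def dataset_inputs(ds: synthetic.SyntheticDataset) -> pl.PipelineInputs:
    t = ds.truth
    return pl.PipelineInputs(
        adapter3=ds.settings.adapter3,
        mirna_reference=t.mirna_reference,
        contaminants=t.contaminants,
        transcripts=t.transcripts,
        repeats=t.repeats,
        repeat_annotation=t.repeat_annotation,
        library_meta=ds.libraries,
        raw_reads={k: [(s, 1) for s in v] for k, v in ds.raw_reads.items()},
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140402)


@pytest.fixture(scope="session")
def synth_small():
    """Reduced-depth synthetic study (4 x 20k reads) for unit tests."""
    return synthetic.generate_dataset(
        synthetic.SyntheticSettings(reads_per_library=20_000, seed=7)
    )


@pytest.fixture(scope="session")
def result_small(synth_small):
    """Full pipeline run over the reduced-depth study."""
    return pl.run_pipeline(dataset_inputs(synth_small), PipelineConfig())
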