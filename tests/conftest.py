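import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from capscaffold import pipeline, synthetic


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    """A small error-free simulated dataset with planted novel-TSS groups,
    shared across tests (read-only)."""
    cfg = synthetic.SimConfig(
        seed=7,
        n_reads=400,
        substitution_rate=0.0,
        n_novel_clusters=3,
        n_novel_singletons=2,
    )
    ref = synthetic.make_reference(cfg)
    result = synthetic.simulate_reads(cfg, ref)
    outdir = tmp_path_factory.mktemp("sim_small")
    paths = synthetic.write_outputs(result, ref, outdir)
    return {"config": cfg, "reference": ref, "result": result, "paths": paths}


@pytest.fixture(scope="session")
def sim_small_pipeline(sim_small):
    """Pipeline output on the shared small dataset."""
    paths = sim_small["paths"]
    return pipeline.run_all(
        paths["reads.fastq"],
        paths["untrimmed.sam"],
        paths["trimmed.sam"],
        paths["polya_table.tsv"],
        paths["annotation.gtf"],
        paths["polya_sites.bed"],
    )
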