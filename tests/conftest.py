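import numpy as np
import pytest

import iciscore as ic


@pytest.fixture(scope="session")
def signature():
    return ic.load_synthetic_signature()


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort: 300 samples, 3 immune phenotypes."""
    return ic.simulate_cohort(ic.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def toy_gene_sets(default_cohort):
    genes = default_cohort.expression.gene_ids
    return ic.GeneSetCollection({
        "IMMUNE_UP": [g for g in genes if g.startswith("SIGA")][:40],
        "IMMUNE_DN": [g for g in genes if g.startswith("SIGB")][:40],
        "RANDOM_SET": [g for g in genes if g.startswith("GENE")][:40],
    })


@pytest.fixture(scope="session")
def pipeline_result(default_cohort, signature, toy_gene_sets, tmp_path_factory):
    """One full pipeline run on the default cohort, shared across tests."""
    outdir = tmp_path_factory.mktemp("pipeline")
    return ic.run_pipeline(
        default_cohort.expression,
        default_cohort.clinical,
        signature,
        maf=default_cohort.maf,
        gene_sets=toy_gene_sets,
        params=ic.PipelineParams(n_resample=200, seed=7),
        outdir=outdir,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
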