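import numpy as np
import pandas as pd
import pytest

from metprog import io, synthetic
from metprog.pipeline import PipelineConfig


@pytest.fixture(scope="session")
def bundle():
    """Planted prognostic study at full scale (200 genes, 400 tumours)."""
    return synthetic.planted_prognostic_bundle(1)


@pytest.fixture(scope="session")
def bundle_files(bundle, tmp_path_factory):
    """The planted bundle written to disk plus a matching pipeline config."""
    d = tmp_path_factory.mktemp("bundle")
    io.write_expression(bundle.cohort.expression, d / "expr.tsv")
    io.write_annotation(bundle.cohort.annotation.join(bundle.survival), d / "ann.tsv")
    io.write_network(bundle.network, d / "net.tsv")
    io.write_gmt(bundle.gene_sets, d / "gs.gmt")
    cfg = PipelineConfig(
        expression=str(d / "expr.tsv"),
        annotation=str(d / "ann.tsv"),
        network=str(d / "net.tsv"),
        gene_sets=str(d / "gs.gmt"),
        out_dir=str(d / "out"),
        seed=1,
    )
    return cfg


@pytest.fixture(scope="session")
def pipeline_bundle(bundle_files):
    """Result of one full pipeline run on the planted study."""
    from metprog.pipeline import run_pipeline

    return run_pipeline(bundle_files)


@pytest.fixture
def small_cohort():
    return synthetic.generate_cohort(
        synthetic.CohortSpec(
            n_genes=50, n_tumour=20, n_normal=20, de_fraction=0.2,
            lfc_effect=2.0, noise_sd=0.5, seed=7,
        )
    )


def random_survival(rng, n, *, censor=0.3, tied=False):
    """Small random right-censored dataset for oracle comparisons."""
    time = rng.exponential(5.0, size=n)
    if tied:
        time = np.ceil(time)
    cens = rng.exponential(5.0 / censor, size=n) if censor > 0 else np.full(n, np.inf)
    event = (time <= cens).astype(int)
    obs = np.minimum(time, cens)
    if event.sum() == 0:
        event[0] = 1
    return obs, event
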