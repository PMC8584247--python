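import numpy as np
import pandas as pd
import pytest

from cnamir.genome import Cytoband
from cnamir.pipeline import run_pipeline, validate_config
from cnamir.simulate import default_config, generate_cohort


@pytest.fixture(scope="session")
def toy_cytobands():
    """Hand-made cytoband table for chr4/chr8 interval tests."""
    return [
        Cytoband("chr8", 0, 2_000_000, "p12", "gneg"),
        Cytoband("chr8", 2_000_000, 3_500_000, "p11.11", "gpos50"),
        Cytoband("chr8", 3_500_000, 5_000_000, "q11", "gneg"),
        Cytoband("chr8", 5_000_000, 8_000_000, "q24.21", "gpos50"),
        Cytoband("chr4", 0, 1_000_000, "p16.3", "gneg"),
        Cytoband("chr4", 1_000_000, 2_500_000, "p15", "gpos50"),
        Cytoband("chr4", 2_500_000, 4_000_000, "p12", "gneg"),
    ]


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """Study-conditions cohort plus a full pipeline run (seed 11)."""
    outdir = tmp_path_factory.mktemp("study")
    config = default_config(seed=11)
    manifest = generate_cohort(config, outdir)
    pipeline_cfg = validate_config(outdir / "pipeline_config.yaml")
    report = run_pipeline(pipeline_cfg)
    return dict(
        dir=outdir, config=config, manifest=manifest, report=report,
        results=outdir / "results",
    )


@pytest.fixture(scope="session")
def noiseless_run(tmp_path_factory):
    """Noiseless group-pure cohort plus a full pipeline run (seed 5)."""
    outdir = tmp_path_factory.mktemp("noiseless")
    config = default_config(seed=5, preset="noiseless")
    manifest = generate_cohort(config, outdir)
    pipeline_cfg = validate_config(outdir / "pipeline_config.yaml")
    report = run_pipeline(pipeline_cfg)
    return dict(
        dir=outdir, config=config, manifest=manifest, report=report,
        results=outdir / "results",
    )


def read_stage_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


@pytest.fixture
def rng():
    return np.random.default_rng(20210)
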