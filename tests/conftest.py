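import numpy as np
import pandas as pd
import pytest

from seednet import expression, pipeline


def make_matrix(values: np.ndarray, n_reps: int = 3) -> expression.ExpressionMatrix:
    """Wrap a genes x samples array with an S1..Sk / replicate design."""
    n_genes, n_samples = values.shape
    assert n_samples % n_reps == 0
    samples, stages, reps = [], [], []
    for s in range(n_samples // n_reps):
        for r in range(n_reps):
            samples.append(f"S{s+1}_r{r+1}")
            stages.append(f"S{s+1}")
            reps.append(str(r + 1))
    design = pd.DataFrame(
        {"stage": stages, "replicate": reps}, index=pd.Index(samples, name="sample")
    )
    df = pd.DataFrame(
        values, index=[f"g{i+1}" for i in range(n_genes)], columns=samples
    )
    return expression.ExpressionMatrix(values=df, design=design)


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """The default synthetic dataset, written once per session."""
    out = tmp_path_factory.mktemp("fixture")
    return pipeline.make_fixture(out, seed=1)


@pytest.fixture(scope="session")
def pipeline_run(fixture_paths, tmp_path_factory):
    """One full pipeline run on the default fixture, shared across tests."""
    out = tmp_path_factory.mktemp("run")
    cfg = pipeline.PipelineConfig(
        expression_tsv=str(fixture_paths["expression"]),
        design_tsv=str(fixture_paths["design"]),
        promoter_fasta=str(fixture_paths["promoters"]),
        pwm_file=str(fixture_paths["pwms"]),
        output_dir=str(out),
        seed=1,
    )
    report = pipeline.run_pipeline(cfg)
    return {"config": cfg, "report": report, "out": out, "paths": fixture_paths}
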