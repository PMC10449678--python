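import numpy as np
import pytest
from hypothesis import settings

from derivachrom import pipeline as pl
from derivachrom import simtrio as st

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

# the case-study depth calibration: disomic mean 58.44, SD 13.41
PAPER_MU = 58.44
PAPER_SIGMA = 13.41


@pytest.fixture(scope="session")
def paper_design():
    return st.paper_like_design()


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory, paper_design):
    """One full synthetic trio dataset at the default study conditions."""
    outdir = tmp_path_factory.mktemp("sim_default")
    config = st.SimConfig(seed=20230711)
    out = st.simulate_trio(paper_design, config, outdir)
    truth = out.pop("truth_dict")
    return {"paths": out, "truth": truth, "config": config, "design": paper_design}


@pytest.fixture(scope="session")
def default_pipeline_run(tmp_path_factory, default_sim):
    outdir = tmp_path_factory.mktemp("pipeline_default")
    cfg = default_sim["config"]
    pcfg = pl.PipelineConfig(
        inputs=default_sim["paths"],
        outdir=str(outdir),
        baseline_region=(cfg.control_chrom, 0, cfg.control_chrom_bp),
    )
    report = pl.run_pipeline(pcfg)
    card = pl.validate_report(report, default_sim["truth"])
    return {"report": report, "scorecard": card, "config": pcfg}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
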