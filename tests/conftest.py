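import numpy as np
import pandas as pd
import pytest

import micquant as mq


def make_table(counts: dict[str, list[int]], sample_id="S1", sample_type="sample",
               location="A", month=1) -> mq.OTUCountTable:
    """Small hand-written count table; keys are otu ids (include 'IC')."""
    df = pd.DataFrame(
        {f"replicate_{i + 1}": [v[i] for v in counts.values()]
         for i in range(len(next(iter(counts.values()))))},
        index=pd.Index(list(counts.keys()), name="otu_id"),
    )
    return mq.OTUCountTable(
        sample_id=sample_id, counts=df, sample_type=sample_type,
        location=location, month=month,
    )


def run_campaign(seed: int, sim_overrides: dict | None = None,
                 pipe_overrides: dict | None = None):
    """Simulate and fully process one campaign; returns (cfg, truth, bundle)."""
    cfg = mq.SimulationConfig(seed=seed, **(sim_overrides or {}))
    truth = mq.simulate_truth(cfg)
    tables = mq.simulate_reads(truth, cfg)
    pipe = mq.PipelineConfig(
        calibration=mq.CalibrationConfig(ic_copies=cfg.ic_copies),
        **(pipe_overrides or {}),
    )
    bundle = mq.run_pipeline(tables, pipe)
    return cfg, truth, bundle


@pytest.fixture(scope="session")
def default_campaign():
    """One fully processed default campaign, shared across read-only tests."""
    return run_campaign(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
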