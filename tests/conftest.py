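import numpy as np
import pandas as pd
import pytest

import spikequant as sq


@pytest.fixture(scope="session")
def kinetics():
    return sq.KineticParams()


@pytest.fixture(scope="session")
def genome_small():
    return sq.build_genome(80, n_enhancers=10, n_spike=40, seed=11)


@pytest.fixture(scope="session")
def genome_mid():
    return sq.build_genome(500, n_enhancers=40, n_spike=100, seed=2)


@pytest.fixture(scope="session")
def conditions():
    return {
        "UNT": sq.ConditionSpec(label="UNT"),
        "dSET1": sq.ConditionSpec(label="dSET1", s=0.0),
        "dZC3H4": sq.ConditionSpec(label="dZC3H4", z=0.0),
        "dBOTH": sq.ConditionSpec(label="dBOTH", s=0.0, z=0.0),
    }


@pytest.fixture(scope="session")
def expectations_small(genome_small, conditions, kinetics):
    return {
        label: sq.expected_signals(genome_small, cond, kinetics)
        for label, cond in conditions.items()
    }


def make_count_frame(genome, expectations, labels, replicates, seed, depth_cond=None):
    """Sampled target/spike count matrices and a design series."""
    samples, design = [], {}
    for label in labels:
        for r in range(replicates):
            sid = f"{label}_rep{r}"
            sc, _ = sq.sample_counts(expectations[label], depth_cond, seed, sample_id=sid)
            samples.append(sc)
            design[sid] = label
    target = pd.DataFrame({s.sample_id: s.target for s in samples})
    spike = pd.DataFrame({s.sample_id: s.spike for s in samples})
    return target, spike, pd.Series(design)
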