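"""Shared fixtures: trained models and multi-seed pipeline runs are expensive,
so they are session-scoped and shared across test modules."""

import dataclasses

import numpy as np
import pytest

from radpath.alignment import TrainConfig, train_alignment
from radpath.pipeline import RunConfig, run_pipeline
from radpath.synthetic import SyntheticConfig, generate_cohort, low_noise_config


@pytest.fixture(scope="session")
def low_noise_alignment():
    """Cohort of 98 low-noise patients with a model trained on 60, held-out 38."""
    cfg = low_noise_config(n_patients=98, seed=0)
    cohort = generate_cohort(cfg)
    result = train_alignment(cohort.samples[:60], cohort.samples[60:],
                             config=TrainConfig(epochs=30, tau=0.07, seed=0))
    return cohort, result


@pytest.fixture(scope="session")
def mediated_runs():
    """Full pipeline under the default mediated generator, seeds 1..5."""
    return [run_pipeline(RunConfig(seed=s)) for s in range(1, 6)]


@pytest.fixture(scope="session")
def unmediated_runs():
    """Pipeline with the pathology-mediated survival weight set to zero."""
    out = []
    for s in range(1, 6):
        rc = RunConfig(seed=s, ablation_ks=(1,))
        rc.synthetic = dataclasses.replace(
            rc.synthetic, survival_weights=np.zeros(rc.synthetic.latent_dim))
        out.append(run_pipeline(rc))
    return out
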