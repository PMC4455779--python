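"""Shared fixtures: small synthetic panels reused across test modules.

Pipeline runs are session-scoped because they exercise the whole stack;
individual tests then assert different properties of the same run.
"""

from __future__ import annotations

import warnings

import pytest

from soysv import svclasses as svc
from soysv.pipeline import CoalescentConfig, EventConfig, RunConfig, run_pipeline
from soysv.synthetic_data import GenomeConfig, generate_annotation

MIXED_PROPORTIONS = {
    svc.DOWN_CNV_PAV: 0.25,
    svc.UP_PAV: 0.15,
    svc.UP_PAV_UP_CNV: 0.15,
    svc.UP_CNV_DOWN_CNV: 0.15,
    svc.UP_CNV: 0.15,
    svc.MULTI_ALLELIC_UP_CNV: 0.15,
}


def small_run_config(seed: int, **overrides) -> RunConfig:
    kw = dict(
        seed=seed,
        events=EventConfig(n_events=12, proportions=dict(MIXED_PROPORTIONS)),
        coalescent=CoalescentConfig(n_loci=20),
        enrichment_sims=200,
    )
    kw.update(overrides)
    return RunConfig(**kw)


@pytest.fixture(scope="session")
def annotation():
    return generate_annotation(GenomeConfig(seed=11))


@pytest.fixture(scope="session")
def noisefree_result():
    """Full pipeline on a noise-free panel with all six classes planted."""
    cfg = small_run_config(seed=1, cgh_noise_sd=0.0, exact_counts=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(cfg)


@pytest.fixture(scope="session")
def noisy_result():
    """Full pipeline at the study noise levels (probe sd 0.15, 2-31x)."""
    return run_pipeline(small_run_config(seed=7))


@pytest.fixture(scope="session")
def null_result():
    """No planted events, no probe noise: the end-to-end null."""
    cfg = small_run_config(
        seed=5, cgh_noise_sd=0.0, exact_counts=True,
        events=EventConfig(n_events=0),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(cfg)
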