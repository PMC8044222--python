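import logging

import pytest

from lipivar import GeneratorConfig, HierarchicalModelSpec, generate_cohort
from lipivar.cohort import resolve_ldl_series
from lipivar.variability import fit_hierarchical

logging.getLogger("lifelines").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic 600-subject cohort shared across read-only tests."""
    cfg = GeneratorConfig(n_subjects=600, seed=42)
    measurements, profiles, trajectories, truth = generate_cohort(cfg)
    return cfg, measurements, profiles, trajectories, truth


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """Hierarchical fit of the shared cohort with moderate chains."""
    _, measurements, *_ = small_cohort
    resolved = resolve_ldl_series(measurements)
    spec = HierarchicalModelSpec(seed=11, burn_in=500, draws=2000)
    estimates, report = fit_hierarchical(resolved, spec)
    return resolved, spec, estimates, report
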