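import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from lncmap import ModuleMapper, SynthConfig
from lncmap.preprocess import prepare_cohort
from lncmap.regnet import build_network
from lncmap.synthdata import generate_cohort, generate_genesets, generate_modules


def small_config(**overrides) -> SynthConfig:
    """A fast cohort: 120 samples, 400 genes, 60 lncRNAs, 12 modules."""
    base = dict(
        n_samples=150,
        beta_lnc_effect=0.6,
        n_genes=400,
        n_lncrnas=60,
        n_essential=80,
        n_modules=12,
        n_driver_modules=6,
        module_size_range=(8, 14),
        n_driver_inducers=3,
        n_driver_suppressors=3,
        n_dataset_specific=5,
        n_prognostic=4,
        n_peak_proximal=3,
        seed=11,
    )
    base.update(overrides)
    return SynthConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = small_config()
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def small_prepared(small_cohort):
    _, cohort, _ = small_cohort
    with pytest.warns(UserWarning):
        return prepare_cohort(cohort)


@pytest.fixture(scope="session")
def small_network(small_prepared):
    return build_network(small_prepared)


@pytest.fixture(scope="session")
def default_run():
    """The reference-scale synthetic study, fitted end to end (fixed seed)."""
    cfg = SynthConfig(seed=1)
    cohort, truth = generate_cohort(cfg)
    modules = generate_modules(cfg, truth, cohort)
    hallmark, kegg = generate_genesets(cfg, truth)
    model = ModuleMapper(cohort, modules, [hallmark, kegg], truth.essential_genes)
    results = model.fit(n_draws=1000, seed=7)
    return cfg, cohort, truth, modules, results


def assert_close(a, b, tol=1e-8):
    assert np.all(np.abs(np.asarray(a) - np.asarray(b)) < tol)
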