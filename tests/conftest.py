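import logging

import numpy as np
import pandas as pd
import pytest

from duomics.pipeline import PipelineConfig
from duomics.simulate import SimConfig, generate_study

logging.getLogger("duomics").setLevel(logging.ERROR)


def small_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """A reduced study: same design (9 vs 14), ~5x fewer features."""
    base = dict(
        n_genes=400, n_proteins=160, n_metabolites=60, n_lipids=80,
        module_sizes={"transcriptome": 8, "proteome": 5, "metabolome": 3, "lipidome": 4},
        planted_set_size=8, n_decoy_sets=10, drug_target_size=10, n_decoy_drugs=10,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_study(small_sim_config(seed=11))


@pytest.fixture(scope="session")
def small_pipeline_config(tmp_path_factory):
    cfg = PipelineConfig(outdir=str(tmp_path_factory.mktemp("run")))
    cfg.simulate = small_sim_config(seed=11)
    cfg.gsea_n_perm = 100
    cfg.network_prefilter_top = 60
    return cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def two_group_frame(rng, n_features=50, n_control=9, n_alcohol=14, effect=0.0, sd=0.5):
    """Gaussian log2 matrix with an additive group effect, plus labels."""
    cols = [f"c{i}" for i in range(n_control)] + [f"a{i}" for i in range(n_alcohol)]
    groups = pd.Series(["control"] * n_control + ["alcohol"] * n_alcohol, index=cols)
    base = rng.normal(10.0, 1.0, size=(n_features, 1))
    X = base + rng.normal(0.0, sd, size=(n_features, len(cols)))
    X[:, n_control:] += effect
    idx = [f"f{i:03d}" for i in range(n_features)]
    return pd.DataFrame(X, index=idx, columns=cols), groups
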