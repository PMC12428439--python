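import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pepscreen as ps

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rulesets():
    return {
        "ro5": ps.builtin_ruleset("ro5"),
        "ro5_no_lower": ps.builtin_ruleset("ro5", logp_lower=False),
        "bro5": ps.builtin_ruleset("bro5"),
        "muegge": ps.builtin_ruleset("muegge"),
        "muegge_full": ps.builtin_ruleset("muegge", variant="full"),
    }


@pytest.fixture(scope="session")
def small_stratified_dataset():
    """1,000 stratified synthetic descriptor rows labelled for all rules."""
    cfg = ps.SamplerConfig(n=1000, seed=11, stratify_rule="ro5")
    table = ps.sample_descriptor_vectors(cfg)
    return ps.build_dataset_from_descriptor_table(
        table,
        [ps.builtin_ruleset("ro5"), ps.builtin_ruleset("bro5"), ps.builtin_ruleset("muegge")],
    )


@pytest.fixture(scope="session")
def glycine_descriptors():
    return ps.compute_descriptors(ps.parse_molecule("NCC(=O)O"))


def random_descriptor_frame(rng, n):
    """Descriptor rows drawn beyond the default sampler ranges (for oracles)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "mw": rng.uniform(10, 3000, n),
            "logp": rng.uniform(-12, 15, n),
            "hbd": rng.integers(0, 40, n).astype(float),
            "hba": rng.integers(0, 50, n).astype(float),
            "tpsa": rng.uniform(0, 800, n),
            "n_rotb": rng.integers(0, 60, n).astype(float),
            "n_carbon": rng.integers(1, 150, n).astype(float),
            "n_hetero": rng.integers(0, 80, n).astype(float),
            "n_rings": rng.integers(0, 15, n).astype(float),
        }
    )
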