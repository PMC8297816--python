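import numpy as np
import pytest

from ohnofate import simulate
from ohnofate.retention import FamilyRecord

REFS = ["rpl13", "rpl19", "ppiaa"]


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_experiment():
    """One family per mechanism at default noise: (config, ct_a, ct_b, truth)."""
    cfg = simulate.default_scenario(
        1,
        seed=11,
        mechanisms=(
            "redundancy",
            "subfunctionalization",
            "neo_gain",
            "neo_loss",
            "canonical_neo",
        ),
    )
    ct_a, ct_b, truth = simulate.simulate_experiment(cfg)
    return cfg, ct_a, ct_b, truth


@pytest.fixture(scope="session")
def noise_free_experiment():
    """Noise-free, jitter-free triples for exact round-trip checks."""
    families = [
        simulate.FamilySpec(
            "redfam", "redundancy", "II", lineage="A", jitter_sd=0.0
        ),
        simulate.FamilySpec(
            "lossfam", "neo_loss", "III", lineage="B", jitter_sd=0.0
        ),
    ]
    cfg = simulate.SimConfig(
        seed=3, families=families, ct_noise_sd=0.0, biological_cv=0.0
    )
    ct_a, ct_b, truth = simulate.simulate_experiment(cfg)
    return cfg, ct_a, ct_b, truth


def family_records(cfg):
    return [
        FamilyRecord(f.name, f.lineage, f.lso_a, f.lso_b, f.singleton)
        for f in cfg.families
    ]
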