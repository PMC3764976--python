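from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_nt(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(np.array(list("ACGT")), size=n, p=p))


def mutate(rng: np.random.Generator, seq: str, k: int) -> str:
    """Exactly k substitutions at distinct positions (always to another base)."""
    chars = list(seq)
    for i in rng.choice(len(chars), size=k, replace=False):
        chars[i] = rng.choice([b for b in "ACGT" if b != chars[i]])
    return "".join(chars)


@pytest.fixture(scope="session")
def small_sim():
    """One shared desk-scale simulation: 30 genes, pseudogenes, introns."""
    from hydraseq.synthdata import SimConfig, generate_genome_and_transcripts

    cfg = SimConfig(seed=11, n_genes=30, genome_target_len=0, pseudogene_rate=0.2)
    return cfg, generate_genome_and_transcripts(cfg)
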