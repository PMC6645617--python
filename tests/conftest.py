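import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from minisplice import (
    ClassifierParams,
    FixtureConfig,
    apply_variant,
    build_fixture,
    build_signatures,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_cfg():
    return FixtureConfig()


@pytest.fixture(scope="session")
def gene(fixture_cfg):
    return build_fixture(fixture_cfg)


@pytest.fixture(scope="session")
def variant(fixture_cfg):
    return fixture_cfg.variant


@pytest.fixture(scope="session")
def mutant(gene, variant):
    return apply_variant(gene, variant)


@pytest.fixture(scope="session")
def params():
    return ClassifierParams()


@pytest.fixture(scope="session")
def signatures(gene, variant, fixture_cfg, params):
    return build_signatures(gene, variant, fixture_cfg.retained_len, params)


def random_minigene(seed, n_introns=2, min_exon=6, max_exon=15, min_intron=6, max_intron=20):
    """Small random but structurally valid mini-gene for property tests."""
    from minisplice import MiniGene, Segment

    rng = np.random.default_rng(seed)

    def bases(n):
        return "".join("ACGT"[i] for i in rng.integers(0, 4, n))

    segs = []
    for i in range(n_introns + 1):
        segs.append(Segment(f"e{i}", "exon", bases(int(rng.integers(min_exon, max_exon + 1)))))
        if i < n_introns:
            n = int(rng.integers(min_intron, max_intron + 1))
            segs.append(Segment(f"i{i}", "intron", "GT" + bases(n - 4) + "AG"))
    anchor = int(rng.integers(1, 500))
    return MiniGene(f"rand{seed}", tuple(segs), anchor, int(rng.integers(0, 3)))
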