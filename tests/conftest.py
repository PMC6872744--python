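import pytest

import varclass as vc


def vk(chrom, pos, ref="A", alt="T"):
    return vc.VariantKey.make(chrom, pos, ref, alt)


@pytest.fixture
def abc_sites():
    """Three distinct sites in genomic order A < B < C."""
    return vk("1", 100), vk("1", 200), vk("2", 100)


@pytest.fixture
def abc_profiles(abc_sites):
    """Three profiles: site A in all, B in two, C in one."""
    a, b, c = abc_sites
    return [
        vc.VariantProfile("s1", "X", frozenset({a, b, c})),
        vc.VariantProfile("s2", "X", frozenset({a, b})),
        vc.VariantProfile("s3", "X", frozenset({a})),
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """Small 3-class + healthy simulated cohort shared across tests."""
    cfg = vc.SimConfig(classes=["A", "B", "C"], n_per_class=40, n_healthy=40,
                       n_signature=60, penetrance=0.9, n_background=400,
                       bg_rate=0.02, signature_overlap={("A", "B"): 0.5}, seed=7)
    profiles, truth = vc.simulate_cohort(cfg)
    return cfg, profiles, truth
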