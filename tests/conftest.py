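import pytest

from exopattern.simulate import CohortConfig, simulate_study
from exopattern.variants import AnnotatedVariant, SampleCallset, VariantCatalog


def make_variant(chrom="chr1", pos=100, ref="C", alt="T", **kw):
    return AnnotatedVariant(chrom, pos, ref, alt, **kw)


def make_callset(sample_id, phenotype, variants):
    cs = SampleCallset(sample_id, phenotype)
    for v in variants:
        cs.add(v)
    return cs


@pytest.fixture(scope="session")
def small_bundle():
    """One reduced-size simulated study shared across tests."""
    return simulate_study(CohortConfig.small(seed=7))


@pytest.fixture(scope="session")
def default_bundle():
    """The full default-size simulated study (a few seconds to build)."""
    return simulate_study(CohortConfig(seed=11))


@pytest.fixture
def toy_callsets():
    """Three tiny hand-built callsets: keys are easy to reason about."""
    def snv(pos, **kw):
        return make_variant(pos=pos, **kw)

    t1 = make_callset("T1", "tumor", [
        snv(1, genes=("GA",), region="exonic", exonic_function="nonsynonymous"),
        snv(2, genes=("GB",), region="exonic", exonic_function="synonymous"),
        snv(3, genes=("GC",)),
    ])
    t2 = make_callset("T2", "tumor", [
        snv(1, genes=("GA",), region="exonic", exonic_function="nonsynonymous"),
        snv(3, genes=("GC",)),
        snv(4, genes=("GD",)),
    ])
    ctl = make_callset("C1", "control", [snv(3, genes=("GC",))])
    return t1, t2, ctl
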