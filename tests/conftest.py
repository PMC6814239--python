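import pytest

from exotier.acmg import EngineConfig, ReferenceTables
from exotier.fixtures import default_spec, generate_cohort


@pytest.fixture(scope="session")
def tables():
    return ReferenceTables.load_default()


@pytest.fixture(scope="session")
def config():
    return EngineConfig()


@pytest.fixture(scope="session")
def fixture_result(tmp_path_factory):
    """The default 10-sample, 12-variant synthetic cohort, written to disk."""
    outdir = tmp_path_factory.mktemp("cohort")
    return generate_cohort(default_spec(seed=1), outdir)


def make_variant(**kwargs):
    """An exonic missense variant with a mid-range frequency; overridable."""
    from exotier.models import AnnotatedVariant

    defaults = dict(
        chrom="1",
        pos=1000,
        ref="A",
        alt="G",
        gene="GENE1",
        func_region="exonic",
        exonic_func="nonsynonymous SNV",
        pop_freqs={"exac_all": 5e-4},
    )
    defaults.update(kwargs)
    return AnnotatedVariant(**defaults)


@pytest.fixture
def variant_factory():
    return make_variant
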