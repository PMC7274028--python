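import pytest

from varscope.fixtures import FixtureSpec, generate_fixture
from varscope.genotype import build_matrix, filter_sites
from varscope.io import read_sample_catalog, read_variants
from varscope.query import RegionQuery, parse_sample_expression


@pytest.fixture(scope="session")
def fx(tmp_path_factory):
    """Default synthetic instance (seed 1): 12 samples, 40 random sites,
    planted haplotypes, planted effect variants, geography."""
    out = tmp_path_factory.mktemp("fx_default")
    return generate_fixture(FixtureSpec(seed=1), str(out))


@pytest.fixture(scope="session")
def fx_clean(tmp_path_factory):
    """Noise-free instance: no missing calls, no hets, no indels — exact
    haplotype recovery is possible."""
    out = tmp_path_factory.mktemp("fx_clean")
    spec = FixtureSpec(
        seed=2,
        missing_rate=0.0,
        het_rate=0.0,
        noise_rate=0.0,
        indel_fraction=0.0,
        planted_haplotypes=3,
    )
    return generate_fixture(spec, str(out))


@pytest.fixture(scope="session")
def fx_big(tmp_path_factory):
    """1,000-site × 50-sample instance for the filter/region oracles."""
    out = tmp_path_factory.mktemp("fx_big")
    spec = FixtureSpec(
        seed=3,
        contigs={"1A": 12000, "1B": 12000},
        n_samples=50,
        n_sites=1000,
        groups={"grpA": 25, "grpB": 25},
        missing_rate=0.1,
        het_rate=0.15,
        indel_fraction=0.05,
    )
    return generate_fixture(spec, str(out))


@pytest.fixture(scope="session")
def catalog(fx):
    return read_sample_catalog(fx.paths["samples"], fx.paths["groups"])


def matrix_for(fixture, region, samples="#ALL", maf=0.0, missing_max=1.0):
    cat = read_sample_catalog(fixture.paths["samples"], fixture.paths["groups"])
    sel = parse_sample_expression(samples, cat)
    vcf_ids = [cat.vcf_id_of(a) for a in sel.members]
    records = read_variants(fixture.paths["vcf"], region, vcf_ids)
    return filter_sites(build_matrix(records, sel, cat), maf, missing_max)


@pytest.fixture
def region_1a():
    return RegionQuery("1A", 1, 3000)
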