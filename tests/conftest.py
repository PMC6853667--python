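import pathlib

import pytest
from hypothesis import settings

from snv2struct.fixtures import make_fixture_bundle
from snv2struct.pipeline import Resources, annotate
from snv2struct.variant_io import parse_variant_table

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def bundle_plus(tmp_path_factory):
    return make_fixture_bundle(tmp_path_factory.mktemp("fx_plus"), seed=FIXTURE_SEED, strand="+")


@pytest.fixture(scope="session")
def bundle_minus(tmp_path_factory):
    return make_fixture_bundle(tmp_path_factory.mktemp("fx_minus"), seed=FIXTURE_SEED, strand="-")


def load_resources(bundle) -> Resources:
    return Resources.load(
        genome=bundle.genome,
        gtf=bundle.gtf,
        isoforms=bundle.isoforms,
        structures=bundle.structure_dir,
        msa=bundle.msa,
        catalytic=bundle.catalytic,
        disease=bundle.disease,
        passthrough=bundle.passthrough,
    )


@pytest.fixture(scope="session")
def resources_plus(bundle_plus) -> Resources:
    return load_resources(bundle_plus)


@pytest.fixture(scope="session")
def resources_minus(bundle_minus) -> Resources:
    return load_resources(bundle_minus)


def annotate_bundle(bundle, resources):
    with open(bundle.variants) as fh:
        variants, rejections = parse_variant_table(fh)
    assert not rejections
    return annotate(variants, resources)


@pytest.fixture(scope="session")
def table_plus(bundle_plus, resources_plus):
    return annotate_bundle(bundle_plus, resources_plus)


@pytest.fixture(scope="session")
def table_minus(bundle_minus, resources_minus):
    return annotate_bundle(bundle_minus, resources_minus)


@pytest.fixture(scope="session")
def exact_chain(resources_plus):
    return next(c for c in resources_plus.chains if c.pdb_id == "1AAA" and c.chain_id == "A")
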