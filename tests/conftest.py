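import pytest

from cctrace import CoConversionModel, make_fixtures
from cctrace.fixtures import FIXTURE_NAMES


@pytest.fixture(scope="session")
def bundles():
    return {name: make_fixtures(name) for name in FIXTURE_NAMES}


def fit_bundle(bundle, **kwargs):
    model = CoConversionModel(
        bundle.locus,
        bundle.focal_clade,
        tree=bundle.phylogeny,
        edit_sites=bundle.edit_sites,
        donor_clade=bundle.donor_clade or None,
        **kwargs,
    )
    return model.fit()


@pytest.fixture(scope="session")
def fitted(bundles):
    return {name: fit_bundle(b) for name, b in bundles.items()}
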