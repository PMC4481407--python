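import pytest

from telofuse import Sex, Variant, build_karyotype, make_fixtures


@pytest.fixture(scope="session")
def male():
    return build_karyotype(Sex.MALE)


@pytest.fixture(scope="session")
def female():
    return build_karyotype(Sex.FEMALE)


@pytest.fixture(scope="session")
def marked_y():
    return build_karyotype(Sex.MALE, Variant.MARKED_Y)


@pytest.fixture(scope="session")
def fixtures():
    return make_fixtures(seed=20240901)
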