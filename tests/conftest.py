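import pytest

from identilab import rank_classify, registry_get


@pytest.fixture(scope="session")
def fhn():
    return registry_get("fhn")


@pytest.fixture(scope="session")
def lc_full():
    return registry_get("lc_full")


@pytest.fixture(scope="session")
def lc_reduced():
    return registry_get("lc_reduced")


# rank analyses are the slowest step; compute once per session
@pytest.fixture(scope="session")
def fhn_rank(fhn):
    return rank_classify(fhn, seed=0)


@pytest.fixture(scope="session")
def lc_reduced_rank(lc_reduced):
    return rank_classify(lc_reduced, seed=0)


@pytest.fixture(scope="session")
def lc_full_rank(lc_full):
    return rank_classify(lc_full, seed=0)
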