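import pytest

from fetcea import builtin_table1, classify_cohort, estimate_chance_nodes


@pytest.fixture(scope="session")
def table1():
    return builtin_table1()


@pytest.fixture(scope="session")
def classified(table1):
    return classify_cohort(table1)


@pytest.fixture(scope="session")
def nodes_os(classified):
    return estimate_chance_nodes(classified, "os")


@pytest.fixture(scope="session")
def nodes_pfs(classified):
    return estimate_chance_nodes(classified, "pfs")
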