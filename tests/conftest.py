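import pytest

from heteropath import fixtures


@pytest.fixture(scope="session")
def table2_cases(tmp_path_factory):
    base = tmp_path_factory.mktemp("table2")
    return {
        name: fixtures.table2_fixture(name, workdir=base / name)
        for name in fixtures.TABLE2_CASES
    }


@pytest.fixture(scope="session")
def fba_toys(tmp_path_factory):
    base = tmp_path_factory.mktemp("toys")
    return {case.name: case for case in fixtures.analytic_fba_toys(workdir=base)}
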