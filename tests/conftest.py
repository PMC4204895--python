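import numpy as np
import pytest

from ssio import make_recovery_case


@pytest.fixture(scope="session")
def cascade3():
    return make_recovery_case("cascade3")


@pytest.fixture(scope="session")
def feedback_bistable2():
    return make_recovery_case("feedback_bistable2")


@pytest.fixture(scope="session")
def adipo_mini5():
    return make_recovery_case("adipo_mini5")


@pytest.fixture(scope="session")
def model1_like15():
    return make_recovery_case("model1_like15")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def expression_file(tmp_path):
    """A small TSV expression table on disk (one value below the floor)."""
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene\t-2\t0\t2\t7\n"
        "CEBPB\t25\t40\t5\t120\n"
        "CEBPA\t30\t32\t60\t200\n"
        "PPARG\t22\t28\t90\t300\n"
    )
    return path
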