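import dataclasses

import pytest

from glycocall import (
    Condition,
    SimulationParams,
    simulate_pair,
)

MINIMAL_GPR = (
    "ATF\t1.0\n"
    "1\t7\n"
    '"Scan=demo"\n'
    "Block\tRow\tColumn\tName\tF635 Median\tB635 Median\tFlags\n"
    '1\t1\t1\t"ProtA"\t100\t20\t0\n'
    '1\t1\t2\t"ProtB"\t40\t20\t0\n'
)


def clone_as(scan, condition):
    """Same spots, opposite probing condition (for self-comparison tests)."""
    condition = Condition(condition)
    competitor = (
        "chitin hydrolysate" if condition is Condition.PLUS_COMPETITOR else None
    )
    return dataclasses.replace(
        scan, condition=condition, competitor_name=competitor
    )


@pytest.fixture(scope="session")
def small_pair():
    """Noisy 150-protein assay, default noise level, fixed seed."""
    return simulate_pair(SimulationParams(n_proteins=150, seed=7))


@pytest.fixture(scope="session")
def noise_free_pair():
    """Exact generative identities: 150 proteins, spot_cv = 0."""
    return simulate_pair(SimulationParams(n_proteins=150, seed=11, spot_cv=0.0))


@pytest.fixture(scope="session")
def table1():
    from glycocall import load_table1_fixture

    return load_table1_fixture()


@pytest.fixture
def minimal_gpr(tmp_path):
    p = tmp_path / "demo.gpr"
    p.write_text(MINIMAL_GPR, encoding="utf-8")
    return p
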