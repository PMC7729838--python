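import pytest

from comopat import DiseaseCatalog, TransactionDB


@pytest.fixture(scope="session")
def catalog() -> DiseaseCatalog:
    return DiseaseCatalog.default()


@pytest.fixture()
def toy_tdb() -> TransactionDB:
    """Six small transactions used for oracle-vs-Apriori checks."""
    return TransactionDB.from_sets([
        {"A", "B", "C"}, {"A", "B"}, {"A", "C"}, {"B", "C"}, {"A"}, {"B"},
    ])


@pytest.fixture()
def pair_tdb() -> TransactionDB:
    """Four transactions with a partially-correlated pair."""
    return TransactionDB.from_sets([{"A", "B"}, {"A", "B"}, {"A"}, {"B"}])
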