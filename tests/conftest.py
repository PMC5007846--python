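import pytest

from laaocea import canonical_book, run_all_strategies


@pytest.fixture(scope="session")
def book():
    """Canonical base-case parameter book (session-scoped; treat as read-only)."""
    return canonical_book()


@pytest.fixture(scope="session")
def base_outcomes(book):
    """Base-case cohort outcomes for all eight strategies."""
    return run_all_strategies(book)
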