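"""Shared fixtures: one moderately sized synthetic extract reused across tests."""

import pytest

from pvsignals.io import harmonize
from pvsignals.synthetic import SyntheticConfig, generate
from pvsignals.terms import DrugSynonymTable, TermSet


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_cases=10_000, duplicate_rate=0.2, seed=42)


@pytest.fixture(scope="session")
def small_data(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def harmonized(small_data):
    """(reports, exposures, events) frames of the shared extract (all versions)."""
    return harmonize(small_data.tables)


@pytest.fixture(scope="session")
def toy_terms(small_config) -> TermSet:
    narrow = [e.pt for e in small_config.event_vocab if e.smq_narrow]
    return TermSet.from_terms("toy-cataract-smq", "narrow", narrow)


@pytest.fixture(scope="session")
def toy_synonyms(small_config) -> DrugSynonymTable:
    return DrugSynonymTable.from_vocab(small_config.drug_vocab)
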