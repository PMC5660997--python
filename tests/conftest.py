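"""Shared fixtures: synthetic datasets and search results cached per seed."""

from __future__ import annotations

import functools

import pytest

from aranevir.search import search
from aranevir.synth import build_dataset, default_config


@functools.lru_cache(maxsize=8)
def dataset(seed: int):
    """Build (once per session) the default synthetic benchmark for a seed."""
    return build_dataset(default_config(), seed=seed)


@functools.lru_cache(maxsize=8)
def search_hits(seed: int):
    """Translated-search results on the default benchmark for a seed."""
    ds = dataset(seed)
    return search(ds.transcripts, ds.reference_proteins, max_evalue=1e-5)


@pytest.fixture(scope="session")
def ds1():
    return dataset(1)


@pytest.fixture(scope="session")
def hits1():
    return search_hits(1)
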