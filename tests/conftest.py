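import pytest

from hsescan import PromoterRecord


@pytest.fixture
def canonical_record():
    """A constructed 15-bp canonical element: three adjacent perfect units."""
    return PromoterRecord("canon", "AGAACATTCGAGAAT", 15)


@pytest.fixture
def minimal_record():
    """A constructed 10-bp minimal element: two adjacent perfect units."""
    return PromoterRecord("mini", "AGAACTTTCG", 10)


@pytest.fixture
def motif_free_record():
    """50 C's: every core has 3 substitutions, beyond any preset budget."""
    return PromoterRecord("flat", "C" * 50, 50)


@pytest.fixture
def benchmark_mix():
    return {
        "canonical": 0.25,
        "minimal_perfect": 0.25,
        "imperfect_triple": 0.25,
        "imperfect_minimal": 0.25,
    }
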