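import pytest

from rbpspectrum.seqdata import (
    GenomicInterval,
    SequenceRecord,
    TranscriptAnnotation,
)


@pytest.fixture
def toy_genome():
    return {
        "c1": "AATTGGCCAATTGGCCAATTGGCC",
        "c2": "ACGTACGTACGTACGTACGTACGTACGTACGT",
    }


@pytest.fixture
def toy_annotation():
    return TranscriptAnnotation(
        [
            GenomicInterval("c1", 0, 24, "tx1", "+"),
            GenomicInterval("c2", 0, 32, "tx2", "+"),
        ]
    )


@pytest.fixture
def tiny_records():
    """Four separable records: U-rich positives, A-rich negatives."""
    return [
        SequenceRecord("p1", "UUUUUUUUUU", "positive"),
        SequenceRecord("p2", "UUUUAUUUUU", "positive"),
        SequenceRecord("n1", "AAAAAAAAAA", "negative"),
        SequenceRecord("n2", "AAAAGAAAAA", "negative"),
    ]
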