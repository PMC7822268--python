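import random

import pytest

from oligopipe.core import DesignType, OligoCandidate, Transcript, reverse_complement


def random_dna(rng: random.Random, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


def make_candidate(sense: str, start: int = 0,
                   design_type: DesignType = DesignType.SIRNA,
                   oligo_id: str | None = None,
                   **properties) -> OligoCandidate:
    c = OligoCandidate(
        oligo_id=oligo_id or f"T1_{start + 1}",
        design_type=design_type,
        start=start,
        end=start + len(sense),
        sense_seq=sense,
        antisense_seq=reverse_complement(sense),
    )
    c.properties.update(properties)
    return c


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)


@pytest.fixture
def primary_transcript(rng) -> Transcript:
    return Transcript("T1", "G1", "human", random_dna(rng, 300),
                      exon_ends=[100, 200], is_primary=True)
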