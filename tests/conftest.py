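import random

import pytest

from imirp import MiRNA, parse_mature_fasta

MIR7_FASTA = (
    ">hsa-miR-7-5p MIMAT0000252 Homo sapiens miR-7-5p\n"
    "UGGAAGACUAGUGAUUUUGUUGU\n"
)


@pytest.fixture
def mir7() -> MiRNA:
    """hsa-miR-7-5p, whose seed UGGAAGAC anchors most worked examples."""
    return parse_mature_fasta(MIR7_FASTA)[0]


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)


def random_seed8(rng: random.Random) -> str:
    return "".join(rng.choice("ACGU") for _ in range(8))


def random_mirna(rng: random.Random, mirna_id: str = "syn-miR-rand") -> MiRNA:
    seq = random_seed8(rng) + "".join(rng.choice("ACGU") for _ in range(14))
    return MiRNA(id=mirna_id, sequence=seq)
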