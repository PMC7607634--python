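"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_seq(rng: np.random.Generator, length: int) -> str:
    """Uniform random nucleotide string of the given length."""
    return "".join(rng.choice(list(ALPHABET), size=length))


def check_alphabet(seq: str, context: str = "sequence") -> None:
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise ValueError(
            f"{context} contains characters outside A/C/G/T: {sorted(bad)!r}"
        )
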