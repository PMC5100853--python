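"""Small sequence utilities shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, context: str = "sequence") -> None:
    bad = set(seq.upper()) - VALID_BASES
    if bad:
        raise ValueError(f"non-ACGTN characters {sorted(bad)} in {context}")
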