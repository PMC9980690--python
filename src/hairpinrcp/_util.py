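"""Small shared helpers: sequence ops and seed derivation."""

from __future__ import annotations

import zlib

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed.

    Rule (stable across runs and platforms): crc32 of the stage name
    XORed with the global seed, reduced mod 2**31.
    """
    return (int(global_seed) ^ zlib.crc32(stage.encode("utf-8"))) % (2**31)
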