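"""Small shared sequence helpers."""

from __future__ import annotations

import numpy as np

DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# integer encoding used by the vectorised off-target scanner
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(DNA):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    """GC content of ``seq`` as a percentage in [0, 100]."""
    if not seq:
        return 0.0
    gc = sum(1 for b in seq.upper() if b in "GC")
    return 100.0 * gc / len(seq)


def encode(seq: str) -> np.ndarray:
    """Encode DNA as int8 (A=0 C=1 G=2 T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(DNA), size=length))
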