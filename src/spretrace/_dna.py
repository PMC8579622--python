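"""Small DNA-string helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")

# integer codes used by the DP kernels: A=0 C=1 G=2 T=3, N=4 (missing), 5 = masked
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

BASES = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def normalize(seq: str) -> str:
    """Uppercase and map every non-ACGTN character to N."""
    s = seq.upper()
    return "".join(c if c in "ACGTN" else "N" for c in s)


def encode(seq: str) -> np.ndarray:
    """Encode a normalized DNA string to int8 codes (A0 C1 G2 T3, else 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def random_seq(rng: np.random.Generator, length: int, q=None) -> str:
    probs = None if q is None else np.asarray(q, dtype=float)
    idx = rng.choice(4, size=length, p=probs)
    return "".join(BASES[i] for i in idx)


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Per-base substitution, uniform over the three alternatives."""
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        if out[i] in BASES:
            alts = [b for b in BASES if b != out[i]]
            out[i] = alts[rng.integers(3)]
    return "".join(out)
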