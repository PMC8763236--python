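"""Small shared helpers: sequence arithmetic and seeded RNG plumbing."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTRYKMNacgtrykmn", "TGCAYRMKNtgcayrmkn")

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def gc_fraction(seq: str) -> float:
    """GC over unambiguous (ACGT) bases; NaN for an empty/unresolvable sequence."""
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (s.count("G") + s.count("C")) / acgt


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """I.i.d. bases with P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return array_to_seq(BASES[rng.choice(4, size=length, p=p)])


def spawn_rng(seed: int, *path: int) -> np.random.Generator:
    """Derive an independent generator from (seed, path) deterministically."""
    return np.random.default_rng(np.random.SeedSequence((seed, *path)))


def child_seeds(seed: int, n: int) -> list[int]:
    """n independent 31-bit child seeds derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
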