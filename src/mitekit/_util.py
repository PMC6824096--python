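"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def check_alphabet(seq: str, name: str = "sequence") -> None:
    if not set(seq) <= set(DNA_ALPHABET):
        bad = sorted(set(seq) - set(DNA_ALPHABET))
        raise ValueError(f"{name} contains non-ACGT characters: {bad!r}")


def random_seq(rng: np.random.Generator, length: int) -> str:
    """i.i.d. uniform ACGT background sequence."""
    return "".join(rng.choice(list(DNA_ALPHABET), size=length))


def mutate_substitutions(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Apply i.i.d. substitutions at `rate` per site (always to a different base)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        cur = arr[i].decode()
        arr[i] = rng.choice([b for b in DNA_ALPHABET if b != cur]).encode()
    return arr.tobytes().decode()


def force_substitutions(rng: np.random.Generator, seq: str, n: int) -> str:
    """Substitute exactly `n` distinct positions (n <= len(seq))."""
    if n > len(seq):
        raise ValueError("more substitutions requested than positions")
    idx = rng.choice(len(seq), size=n, replace=False)
    out = list(seq)
    for i in idx:
        out[i] = rng.choice([b for b in DNA_ALPHABET if b != out[i]])
    return "".join(out)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def iupac_match_fraction(window: str, consensus: str) -> float:
    """Fraction of non-N consensus positions matched by `window`."""
    informative = 0
    matched = 0
    for base, cons in zip(window, consensus):
        if cons == "N":
            continue
        informative += 1
        if base in IUPAC[cons]:
            matched += 1
    return matched / informative if informative else 1.0
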