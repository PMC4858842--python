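"""Small sequence utilities shared across the pipeline."""
from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"
STOPS = ("TAA", "TAG", "TGA")

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_DECODE = np.frombuffer(b"ACGT", dtype="S1")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random sequence with the requested expected GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(4, size=length, p=p)
    return encode_to_str(arr)


def seq_to_array(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    out = np.zeros(arr.size, dtype=np.int8)
    out[arr == ord("C")] = 1
    out[arr == ord("G")] = 2
    out[arr == ord("T")] = 3
    return out


def encode_to_str(arr: np.ndarray) -> str:
    return _DECODE[np.asarray(arr, dtype=np.intp)].tobytes().decode()


def translate(seq: str) -> str:
    """Standard-code translation; trailing partial codon dropped."""
    from Bio.Seq import Seq

    n = len(seq) - len(seq) % 3
    return str(Seq(seq[:n]).translate())


def has_intact_orf(cds: str, min_len: int = 150) -> bool:
    """ATG start, stop-codon end, no internal stop, length >= min_len and 3n."""
    if len(cds) < min_len or len(cds) % 3 != 0:
        return False
    if not cds.startswith("ATG") or cds[-3:] not in STOPS:
        return False
    for i in range(3, len(cds) - 3, 3):
        if cds[i : i + 3] in STOPS:
            return False
    return True


def find_orfs(seq: str, min_len: int = 150) -> list[tuple[int, int, str]]:
    """Six-frame ORF scan.

    Returns ``(start, end, strand)`` triples in forward-genome coordinates,
    each an ATG..stop span of length >= ``min_len`` with no internal stop.
    """
    hits: list[tuple[int, int, str]] = []
    L = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            i = frame
            while i + 3 <= len(s):
                if s[i : i + 3] == "ATG":
                    j = i + 3
                    while j + 3 <= len(s):
                        if s[j : j + 3] in STOPS:
                            if j + 3 - i >= min_len:
                                if strand == "+":
                                    hits.append((i, j + 3, "+"))
                                else:
                                    hits.append((L - (j + 3), L - i, "-"))
                            break
                        j += 3
                    i = j + 3
                else:
                    i += 3
    return hits
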