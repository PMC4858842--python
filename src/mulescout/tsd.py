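"""Target-site-duplication (TSD) detection.

A MULE insertion duplicates its 7-11 bp target site, leaving one copy
immediately outside each TIR.  The detector searches every TSD length and
every offset within a +/-``swing`` window of the putative TIR outer ends
and validates a candidate when the edit distance (Levenshtein, unit costs)
between the two copies is within the length-dependent allowance:
perfect match for 7 bp, one mismatch/indel for 8 bp, two for 9-11 bp.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import edlib

TSD_LENGTHS = (7, 8, 9, 10, 11)


def allowance(length: int) -> int:
    """Maximum mismatches/indels tolerated between the two TSD copies."""
    if length == 7:
        return 0
    if length == 8:
        return 1
    if 9 <= length <= 11:
        return 2
    raise ValueError(f"TSD length {length} outside [7, 11]")


@dataclass(frozen=True)
class TsdCall:
    length: int
    left_seq: str
    right_seq: str
    mismatches: int
    left_offset: int
    right_offset: int

    def __post_init__(self) -> None:
        if self.mismatches > allowance(self.length):
            raise ValueError("mismatch count exceeds allowance for this length")
        if abs(self.left_offset) > 10 or abs(self.right_offset) > 10:
            raise ValueError("offset outside the permitted swing")


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def find_tsd(
    seq: str,
    left_tir_start: int,
    right_tir_end: int,
    swing: int = 10,
) -> Optional[TsdCall]:
    """Best valid TSD for a putative TIR pair, or None.

    All lengths 7-11 and all offset pairs within ``+/-swing`` of the TIR
    outer ends are scored; ties break on fewest mismatches, then longest
    TSD, then smallest total |offset|.  Candidates running off the
    chromosome are skipped (insufficient flank).
    """
    best: Optional[TsdCall] = None
    best_key = None
    L = len(seq)
    for t in TSD_LENGTHS:
        allow = allowance(t)
        for dl in range(-swing, swing + 1):
            ls = left_tir_start + dl - t
            if ls < 0 or ls + t > L:
                continue
            left = seq[ls : ls + t]
            for dr in range(-swing, swing + 1):
                rs = right_tir_end + dr
                if rs < 0 or rs + t > L:
                    continue
                if ls + t > rs:
                    continue  # copies must not overlap each other
                right = seq[rs : rs + t]
                if left == right:
                    dist = 0
                else:
                    dist = _edit_distance(left, right)
                    if dist > allow:
                        continue
                key = (dist, -t, abs(dl) + abs(dr))
                if best_key is None or key < best_key:
                    best_key = key
                    best = TsdCall(t, left, right, dist, dl, dr)
    return best
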