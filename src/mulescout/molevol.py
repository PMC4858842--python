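"""Divergence dating and Ka/Ks estimation.

Dating uses the Kimura two-parameter (K2P) closed form on each element's
closest same-family paralog and converts divergence to an amplification
time with T = k / (2 r), r defaulting to the rice-calibrated neutral rate
1.3e-8 substitutions/site/year.  Selection is tested with Nei-Gojobori
(1986) counting (pathway-averaged, Jukes-Cantor corrected) and a normal
approximation to Ka - Ks; q-values are Benjamini-Hochberg adjusted and a
call is made at q <= 0.05.  These closed-form estimators stand in for ML
machinery (baseml/codeml) and all outputs are labelled accordingly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Optional

import numpy as np
from Bio import Align
from statsmodels.stats.multitest import multipletests

from .seqs import STOPS

DEFAULT_RATE = 1.3e-8  # substitutions / site / year

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}

_CODON_TABLE = {}


def _build_codon_table() -> dict[str, str]:
    from Bio.Data.CodonTable import standard_dna_table

    table = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        table[stop] = "*"
    return table


_CODON_TABLE = _build_codon_table()


@dataclass
class AlignedPair:
    id_a: str
    id_b: str
    sites: int              # gap-excluded columns compared
    p_transition: float     # P
    q_transversion: float   # Q

    def __post_init__(self) -> None:
        if self.sites < 1:
            raise ValueError("need >= 1 compared site")
        if self.p_transition < 0 or self.q_transversion < 0:
            raise ValueError("P and Q must be >= 0")
        if self.p_transition + self.q_transversion > 1:
            raise ValueError("P + Q must be <= 1")


@dataclass
class DivergenceEstimate:
    divergence: Optional[float]       # k, substitutions/site (None = saturated)
    rate: float                       # r
    time_years: Optional[float]       # T = k / (2 r)

    @property
    def time_my(self) -> Optional[float]:
        return None if self.time_years is None else self.time_years / 1e6


@dataclass
class SelectionResult:
    gene_id: str
    partner_id: str
    ka: Optional[float]
    ks: Optional[float]
    ratio: Optional[float]
    p_value: Optional[float]
    q_value: Optional[float] = None
    call: str = "untestable"


# ---------------------------------------------------------------------------
# pairwise nucleotide alignment -> AlignedPair
# ---------------------------------------------------------------------------

_nt_aligner = Align.PairwiseAligner()
_nt_aligner.mode = "global"
_nt_aligner.match_score = 1
_nt_aligner.mismatch_score = -1
_nt_aligner.open_gap_score = -2
_nt_aligner.extend_gap_score = -0.5


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


def aligned_pair_from_seqs(
    a: str, b: str, id_a: str = "a", id_b: str = "b", align: bool = True
) -> AlignedPair:
    """Count transition/transversion fractions over a pair.

    With ``align`` a global alignment is computed first; ``align=False``
    compares equal-length sequences position-wise (indel-free pairs, e.g.
    long simulated sequences where a quadratic alignment is wasteful).
    """
    if not align:
        if len(a) != len(b):
            raise ValueError("align=False needs equal-length sequences")
        ra, rb = a.upper(), b.upper()
    else:
        aln = _nt_aligner.align(a.upper(), b.upper())[0]
        ra, rb = aln[0], aln[1]
    sites = ti = tv = 0
    for x, y in zip(ra, rb):
        if x == "-" or y == "-" or x == "N" or y == "N":
            continue
        sites += 1
        if x != y:
            if _is_transition(x, y):
                ti += 1
            else:
                tv += 1
    if sites == 0:
        raise ValueError("no comparable sites after alignment")
    return AlignedPair(id_a, id_b, sites, ti / sites, tv / sites)


def k2p_distance(pair: AlignedPair) -> Optional[float]:
    """Kimura two-parameter distance; None when saturated."""
    P, Q = pair.p_transition, pair.q_transversion
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return None
    return 0.5 * math.log(1.0 / w1) + 0.25 * math.log(1.0 / w2)


def amplification_time(
    k: Optional[float], r: float = DEFAULT_RATE
) -> DivergenceEstimate:
    """T = k / (2 r); propagates an undefined (saturated) k."""
    if r <= 0:
        raise ValueError("rate must be > 0")
    if k is None:
        return DivergenceEstimate(None, r, None)
    if k < 0:
        raise ValueError("divergence must be >= 0")
    return DivergenceEstimate(k, r, k / (2.0 * r))


# ---------------------------------------------------------------------------
# nearest paralog
# ---------------------------------------------------------------------------

def nearest_paralog(
    element_id: str,
    family_of: dict[str, str],
    hit_scores: dict[tuple[str, str], float],
) -> Optional[str]:
    """Best-scoring non-self partner with the same TIR family.

    ``hit_scores`` maps ordered id pairs to similarity scores (an
    all-by-all hit table); ties break to the lexicographically smaller id.
    """
    fam = family_of.get(element_id)
    candidates = []
    for (qa, qb), score in hit_scores.items():
        if qa != element_id or qb == element_id:
            continue
        if family_of.get(qb) != fam:
            continue
        candidates.append((-score, qb))
    if not candidates:
        return None
    candidates.sort()
    return candidates[0][1]


def all_by_all_scores(seqs: dict[str, str]) -> dict[tuple[str, str], float]:
    """Symmetric edlib similarity scores for every sequence pair."""
    import edlib

    ids = sorted(seqs)
    scores: dict[tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            res = edlib.align(seqs[a], seqs[b], mode="NW", task="distance")
            score = max(len(seqs[a]), len(seqs[b])) - res["editDistance"]
            scores[(a, b)] = score
            scores[(b, a)] = score
    return scores


# ---------------------------------------------------------------------------
# codon alignment trimming
# ---------------------------------------------------------------------------

def codon_align_trim(cds: str, partner: str, min_codons: int = 30) -> Optional[tuple[str, str]]:
    """In-frame codon alignment of a CDS against a genomic slice.

    The pair is globally aligned; every CDS codon whose three bases align
    without gaps to three partner bases is kept, except columns where
    either codon is a stop (premature stops and frame-shifted codons are
    discarded pairwise, restoring frame).  Returns None (untestable) when
    fewer than ``min_codons`` codons survive.
    """
    cds = cds.upper()
    partner = partner.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    aln = _nt_aligner.align(cds, partner)[0]
    ra, rb = aln[0], aln[1]
    # map alignment columns back to CDS positions
    out_a: list[str] = []
    out_b: list[str] = []
    cds_pos = 0
    cur_a: list[str] = []
    cur_b: list[str] = []
    for x, y in zip(ra, rb):
        if x == "-":
            # partner insertion: breaks the current codon only if inside it
            if cur_a:
                cur_a.append("-")
            continue
        cur_a.append(x)
        cur_b.append(y)
        cds_pos += 1
        if cds_pos % 3 == 0:
            codon_a = "".join(c for c in cur_a if c != "-")
            codon_b = "".join(cur_b)
            ok = (
                len(codon_a) == 3
                and "-" not in cur_a
                and "-" not in codon_b
                and len(codon_b) == 3
                and "N" not in codon_a
                and "N" not in codon_b
                and codon_a not in STOPS
                and codon_b not in STOPS
            )
            # drop the terminal stop codon of the CDS silently
            if ok:
                out_a.append(codon_a)
                out_b.append(codon_b)
            cur_a, cur_b = [], []
    if len(out_a) < min_codons:
        return None
    return "".join(out_a), "".join(out_b)


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986)
# ---------------------------------------------------------------------------

def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the three possible changes at ``pos`` that are synonymous."""
    aa = _CODON_TABLE[codon]
    syn = 0
    for b in "ACGT":
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        alt_aa = _CODON_TABLE[alt]
        # changes creating stops count as nonsynonymous (NG86 convention)
        if alt_aa != "*" and alt_aa == aa:
            syn += 1
    return syn / 3.0


def _codon_sites(codon: str) -> tuple[float, float]:
    s = sum(_syn_fraction(codon, i) for i in range(3))
    return s, 3.0 - s


def _pathway_diffs(a: str, b: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts over pathways."""
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_tot = 0.0
    non_tot = 0.0
    n_paths = 0
    for order in permutations(diff_pos):
        cur = a
        syn = non = 0
        valid = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if _CODON_TABLE[nxt] == "*":
                valid = False
                break
            if _CODON_TABLE[nxt] == _CODON_TABLE[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if valid:
            syn_tot += syn
            non_tot += non
            n_paths += 1
    if n_paths == 0:
        # all pathways pass through stops; split evenly as a fallback
        return len(diff_pos) / 2.0, len(diff_pos) / 2.0
    return syn_tot / n_paths, non_tot / n_paths


def _jc_correct(p: float) -> Optional[float]:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_kaks(
    aligned_cds: str,
    aligned_partner: str,
    gene_id: str = "gene",
    partner_id: str = "partner",
) -> SelectionResult:
    """NG86 Ka/Ks with a normal-approximation test of Ka != Ks.

    Sites are averaged over the two sequences; multi-substitution codons
    average over substitution pathways; proportions are Jukes-Cantor
    corrected.  The p-value is a two-sided normal test on Ka - Ks using
    the NG86 large-sample variances.
    """
    if len(aligned_cds) != len(aligned_partner) or len(aligned_cds) % 3 != 0:
        raise ValueError("aligned sequences must be equal length, multiple of 3")
    n_codons = len(aligned_cds) // 3
    S = N = 0.0
    Sd = Nd = 0.0
    for i in range(n_codons):
        ca = aligned_cds[3 * i : 3 * i + 3]
        cb = aligned_partner[3 * i : 3 * i + 3]
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _pathway_diffs(ca, cb)
        Sd += sd
        Nd += nd
    if S <= 0 or N <= 0:
        return SelectionResult(gene_id, partner_id, None, None, None, None)
    ps, pn = Sd / S, Nd / N
    ks = _jc_correct(ps)
    ka = _jc_correct(pn)
    if ks is None or ka is None:
        return SelectionResult(gene_id, partner_id, ka, ks, None, None)
    if ks == 0.0 and ka == 0.0:
        return SelectionResult(gene_id, partner_id, 0.0, 0.0, None, None)
    ratio = None if ks == 0.0 else ka / ks
    var_ks = _d_variance(ps, S)
    var_ka = _d_variance(pn, N)
    if var_ks + var_ka <= 0:
        p_value = 1.0
    else:
        z = (ka - ks) / math.sqrt(var_ka + var_ks)
        from scipy.stats import norm

        p_value = 2.0 * float(norm.sf(abs(z)))
    return SelectionResult(gene_id, partner_id, ka, ks, ratio, p_value)


def _d_variance(p: float, n_sites: float) -> float:
    """Large-sample variance of the JC-corrected distance."""
    denom = (1.0 - 4.0 * p / 3.0) ** 2 * n_sites
    if denom <= 0:
        return 0.0
    return p * (1.0 - p) / denom


def adjust_fdr(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1) | np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(arr, method="fdr_bh")
    return list(q)


def finalize_calls(
    results: list[SelectionResult], q_threshold: float = 0.05
) -> list[SelectionResult]:
    """Fill q-values over the testable results and set selection calls."""
    testable = [r for r in results if r.p_value is not None and r.ratio is not None]
    testable_ids = {id(r) for r in testable}
    qs = adjust_fdr([r.p_value for r in testable])
    for r, q in zip(testable, qs):
        r.q_value = q
        if q <= q_threshold:
            r.call = "purifying" if r.ka < r.ks else "positive"
        else:
            r.call = "neutral"
    for r in results:
        if id(r) not in testable_ids:
            r.call = "untestable"
    return results
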