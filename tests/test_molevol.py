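"""K2P dating, codon trimming, NG86 Ka/Ks and FDR control."""
import math

import numpy as np
import pytest

from mulescout.molevol import (
    AlignedPair,
    adjust_fdr,
    aligned_pair_from_seqs,
    all_by_all_scores,
    amplification_time,
    codon_align_trim,
    finalize_calls,
    k2p_distance,
    nearest_paralog,
    ng86_kaks,
)
from mulescout.seqs import random_seq
from mulescout.synthetic import _random_cds, evolve_sequence


def test_k2p_closed_form():
    assert k2p_distance(AlignedPair("a", "b", 100, 0.0, 0.0)) == 0.0
    k = k2p_distance(AlignedPair("a", "b", 1000, 0.1, 0.05))
    expected = 0.5 * math.log(1 / (1 - 0.2 - 0.05)) + 0.25 * math.log(1 / (1 - 0.1))
    assert k == pytest.approx(expected)
    assert k == pytest.approx(0.17018, abs=1e-4)


def test_k2p_saturation_undefined():
    assert k2p_distance(AlignedPair("a", "b", 100, 0.5, 0.0)) is None
    assert k2p_distance(AlignedPair("a", "b", 100, 0.0, 0.5)) is None


def test_k2p_reduces_to_jc_in_small_k_limit():
    """With P = 2Q (the JC expectation) K2P ~ JC for small divergences."""
    for p_total in (0.006, 0.015, 0.03):
        P, Q = 2 * p_total / 3, p_total / 3
        k2p = k2p_distance(AlignedPair("a", "b", 10_000, P, Q))
        jc = -0.75 * math.log(1 - 4 * p_total / 3)
        assert k2p == pytest.approx(jc, rel=0.01)


def test_amplification_time_arithmetic():
    assert amplification_time(0.0).time_years == 0.0
    assert amplification_time(0.026, 1.3e-8).time_my == pytest.approx(1.0)
    assert amplification_time(0.0026).time_my == pytest.approx(0.1)
    assert amplification_time(None).time_years is None
    with pytest.raises(ValueError):
        amplification_time(0.01, 0.0)


def test_dating_recovery_against_planted_ages(rng):
    """Pairs diverged for 2T at r recover T = k/(2r) within 15 %."""
    r = 1.3e-8
    for T_my in (0.5, 2.0, 6.0):
        ests = []
        for i in range(5):
            anc = random_seq(np.random.default_rng(40 + i), 60_000, 0.45)
            a = evolve_sequence(anc, r, T_my * 1e6, seed=100 + i)
            b = evolve_sequence(anc, r, T_my * 1e6, seed=200 + i)
            pair = aligned_pair_from_seqs(a, b, align=False)
            est = amplification_time(k2p_distance(pair), r)
            ests.append(est.time_my)
        assert abs(np.median(ests) - T_my) / T_my < 0.15


def test_nearest_paralog_rules():
    fam = {"a": "f1", "b": "f1", "c": "f2", "d": "f1"}
    scores = {("a", "b"): 10.0, ("a", "c"): 50.0, ("a", "d"): 10.0,
              ("b", "a"): 10.0}
    # c excluded (other family); b and d tie at 10 -> lexicographic
    assert nearest_paralog("a", fam, scores) == "b"
    assert nearest_paralog("c", fam, scores) is None  # singleton family


def test_all_by_all_identical_sibling_chosen(rng):
    base = random_seq(rng, 500, 0.5)
    other = random_seq(rng, 500, 0.5)
    seqs = {"e1": base, "e2": base, "e3": other}
    fam = {k: "f" for k in seqs}
    scores = all_by_all_scores(seqs)
    assert nearest_paralog("e1", fam, scores) == "e2"


# ---------------------------------------------------------------------------
# codon alignment trimming
# ---------------------------------------------------------------------------

def test_trim_identical_sequences(rng):
    cds = "ATG" + _random_cds(rng, 50, 0.5) + "TAA"
    out = codon_align_trim(cds, cds, min_codons=10)
    assert out is not None
    a, b = out
    assert a == b
    assert len(a) % 3 == 0


def test_trim_single_deletion_restores_frame():
    """A 1-bp deletion removes the spanning codon, keeping the rest."""
    cds = "ATGAAACCCGGGTTTTAA"       # ATG AAA CCC GGG TTT TAA
    partner = "ATGAAACCGGGTTT"       # one C deleted from codon 3
    out = codon_align_trim(cds, partner, min_codons=1)
    assert out is not None
    a, b = out
    assert len(a) == len(b)
    assert len(a) % 3 == 0
    assert "ATG" in a and "TTT" in a
    assert len(a) <= len(cds) - 6  # deleted codon + terminal stop gone


def test_trim_removes_premature_stop_column():
    cds = "ATGAAACCCGGGTTTTAA"
    partner = "ATGAAATAAGGGTTT"      # codon 3 is a premature TAA
    out = codon_align_trim(cds, partner, min_codons=1)
    assert out is not None
    a, b = out
    assert "TAA" not in [b[i:i+3] for i in range(0, len(b), 3)]
    assert len(a) == len(cds) - 6


def test_trim_untestable_when_too_short():
    assert codon_align_trim("ATGTAA", "ATG", min_codons=30) is None


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

def test_identical_pair_untestable():
    r = ng86_kaks("ATGAAACCC", "ATGAAACCC")
    assert r.ka == 0.0 and r.ks == 0.0 and r.ratio is None
    finalize_calls([r])
    assert r.call == "untestable"


def test_single_synonymous_change():
    """TTT -> TTC is synonymous: Ka = 0, Ks > 0."""
    a = "TTT" * 40
    b = ("TTT" * 39) + "TTC"
    r = ng86_kaks(a, b)
    assert r.ka == 0.0
    assert r.ks > 0.0


def test_fourfold_degenerate_mutation_is_purifying(rng):
    from mulescout.molevol import _CODON_TABLE

    four_fold = sorted(
        c for c in _CODON_TABLE
        if _CODON_TABLE[c] != "*"
        and all(_CODON_TABLE[c[:2] + b] == _CODON_TABLE[c] for b in "ACGT")
    )
    codons = [four_fold[int(rng.integers(len(four_fold)))] for _ in range(200)]
    a = "".join(codons)
    b = "".join(
        (c[:2] + "ACGT"[int(rng.integers(4))]) if rng.random() < 0.3 else c
        for c in codons
    )
    r = ng86_kaks(a, b)
    finalize_calls([r])
    assert r.ka == 0.0 and r.ks > 0.0
    assert r.call == "purifying"
    assert r.q_value <= 0.05


def test_ng86_matches_biopython_oracle(rng):
    """Cross-check against an independent NG86 implementation."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
    for seed in (3, 11, 29):
        a = "ATG" + _random_cds(np.random.default_rng(60 + seed), 150, 0.5)
        b = evolve_sequence(a, 1e-8, 4e6, seed=seed)
        out = codon_align_trim(a + "TAA", b + "TAA")
        assert out is not None
        mine = ng86_kaks(out[0], out[1])
        dn, ds = cal_dn_ds(CodonSeq(out[0]), CodonSeq(out[1]), method="NG86")
        assert mine.ka == pytest.approx(dn, abs=1e-9)
        assert mine.ks == pytest.approx(ds, abs=1e-9)


def test_neutral_mutation_ratio_near_one():
    """Uniform random substitution gives mean Ka/Ks ~ 1 (no selection)."""
    ratios = []
    for i in range(40):
        a = "ATG" + _random_cds(np.random.default_rng(3000 + i), 400, 0.5)
        b = evolve_sequence(a, 1e-8, 12e6, ti_tv_ratio=0.5, seed=i)
        out = codon_align_trim(a + "TAA", b + "TAA")
        if out is None:
            continue
        r = ng86_kaks(out[0], out[1])
        if r.ratio is not None:
            ratios.append(r.ratio)
    assert len(ratios) >= 30
    assert abs(np.mean(ratios) - 1.0) < 0.15


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def test_bh_step_up_examples():
    assert adjust_fdr([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]
    assert adjust_fdr([0.01]) == [0.01]
    qs = adjust_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(qs, [0.04, 0.04, 0.04, 0.04])
    with pytest.raises(ValueError):
        adjust_fdr([0.5, 1.5])
    assert adjust_fdr([]) == []
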