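"""Methylation statistics, meta-profiles, TE content, TIR similarity, sRNA."""
import numpy as np
import pandas as pd
import pytest

from mulescout.epigenome import (
    CallIndex,
    RegionPartition,
    group_compare,
    meta_profile,
    methylation_level,
    srna_occupancy,
    te_content,
    tir_similarity,
)
from mulescout.intervals import GenomicInterval
from mulescout.io import CytosineCall
from mulescout.seqs import random_seq, revcomp
from mulescout.synthetic import evolve_sequence, simulate_methylome


def _call(pos, meth, total, ctx="CG"):
    return CytosineCall(GenomicInterval("c", pos, pos + 1, "+"), ctx, meth, total)


def test_pooled_level_example():
    calls = [_call(1, 2, 4), _call(2, 0, 3), _call(3, 4, 5)]
    s = methylation_level(GenomicInterval("c", 0, 10), calls, "CG")
    assert s.level == pytest.approx(0.5)
    assert s.n_cytosines == 3 and s.n_mapped == 3


def test_low_coverage_undefined():
    calls = [_call(i, 1, 3 if i < 4 else 1) for i in range(10)]
    s = methylation_level(GenomicInterval("c", 0, 20), calls, "CG")
    assert s.level is None and s.undefined_reason == "low_coverage"
    assert s.n_mapped == 4 and s.n_cytosines == 10


def test_no_cytosines_distinct_flag():
    s = methylation_level(GenomicInterval("c", 0, 10), [_call(1, 1, 5, "CHH")], "CG")
    assert s.level is None and s.undefined_reason == "no_cytosines"


def test_full_methylation():
    calls = [_call(i, 5, 5) for i in range(8)]
    s = methylation_level(GenomicInterval("c", 0, 10), calls, "CG")
    assert s.level == 1.0


def test_site_mode():
    calls = [_call(0, 1, 5), _call(1, 0, 5), _call(2, 5, 5), _call(3, 0, 5)]
    s = methylation_level(GenomicInterval("c", 0, 10), calls, "CG", mode="site")
    assert s.level == pytest.approx(0.5)


def test_brute_force_oracle_equivalence(rng):
    """Weighted level equals a per-site recomputation on random fixtures."""
    for trial in range(10):
        r = np.random.default_rng(500 + trial)
        calls = [
            _call(int(p), int(r.integers(0, t + 1)), int(t),
                  ["CG", "CHG", "CHH"][int(r.integers(3))])
            for p, t in zip(r.choice(200, 60, replace=False), r.integers(0, 9, 60))
            if t > 0
        ]
        region = GenomicInterval("c", 20, 150)
        for ctx in ("CG", "CHG", "CHH"):
            mine = methylation_level(region, calls, ctx, min_coverage=3)
            inside = [c for c in calls
                      if c.context == ctx and 20 <= c.position.start < 150]
            mapped = [c for c in inside if c.total >= 3]
            if not inside:
                assert mine.undefined_reason == "no_cytosines"
            elif len(mapped) / len(inside) < 0.5:
                assert mine.undefined_reason == "low_coverage"
            else:
                expect = sum(c.methylated for c in mapped) / sum(
                    c.total for c in mapped
                )
                assert mine.level == pytest.approx(expect)


def test_coverage_threshold_monotonicity(rng):
    """Raising min coverage never increases the defined-region count."""
    r = np.random.default_rng(77)
    calls = []
    regions = [GenomicInterval("c", i * 100, i * 100 + 100) for i in range(30)]
    for reg in regions:
        for p in range(reg.start, reg.end, 7):
            t = int(r.poisson(5))
            if t:
                calls.append(_call(p, int(r.integers(0, t + 1)), t))
    defined = []
    for min_cov in (3, 5, 7):
        n = sum(
            methylation_level(reg, calls, "CG", min_coverage=min_cov).level
            is not None
            for reg in regions
        )
        defined.append(n)
    assert defined[0] >= defined[1] >= defined[2]


def test_meta_profile_recovers_planted_levels(rng):
    """Internal ~0.8 / TIR ~0.2 plateaus recovered within binomial error."""
    seq = random_seq(rng, 60_000, 0.5)
    genome = {"chr1": seq}
    parts, regions = [], []
    for i in range(12):
        base = 1000 + i * 4500
        lt = GenomicInterval("chr1", base, base + 200)
        internal = GenomicInterval("chr1", base + 200, base + 2200)
        rt = GenomicInterval("chr1", base + 2200, base + 2400)
        parts.append(RegionPartition.from_element(lt, internal, rt, chrom_len=60_000))
        regions.append((lt, {"CG": 0.2}))
        regions.append((rt, {"CG": 0.2}))
        regions.append((internal, {"CG": 0.8}))
    calls = simulate_methylome(genome, regions, {"CG": 0.05, "CHG": 0.0, "CHH": 0.0},
                               depth_mean=12, seed=4)
    prof = meta_profile({"grp": parts}, CallIndex(calls), contexts=("CG",),
                        min_elements=5)
    internal_bins = prof[(prof["section"] == "internal")]
    tir_bins = prof[prof["section"].isin(["left_tir", "right_tir"])]
    assert internal_bins["mean_level"].mean() == pytest.approx(0.8, abs=0.05)
    assert tir_bins["mean_level"].mean() == pytest.approx(0.2, abs=0.05)
    assert not internal_bins["flagged"].any()


def test_meta_profile_flat_and_empty(rng):
    seq = random_seq(rng, 12_000, 0.5)
    lt = GenomicInterval("chr1", 1000, 1200)
    internal = GenomicInterval("chr1", 1200, 2500)
    rt = GenomicInterval("chr1", 2500, 2700)
    part = RegionPartition.from_element(lt, internal, rt, chrom_len=12_000)
    calls = simulate_methylome({"chr1": seq},
                               [(GenomicInterval("chr1", 0, 12_000), {"CG": 0.4})],
                               depth_mean=15, seed=9)
    prof = meta_profile({"g": [part]}, CallIndex(calls), contexts=("CG",))
    # flat planted level: every anatomical section averages near 0.4
    section_means = prof.groupby("section")["mean_level"].mean()
    assert (section_means - 0.4).abs().max() < 0.1
    assert prof["flagged"].all()  # single element < min_elements
    empty = meta_profile({"g": []}, CallIndex(calls), contexts=("CG",))
    assert empty.empty


# ---------------------------------------------------------------------------
# TE content + TIR similarity
# ---------------------------------------------------------------------------

def test_te_content_cases():
    internal = GenomicInterval("c", 0, 1000)
    assert te_content(internal, []) == 0.0
    assert te_content(internal, [GenomicInterval("c", 0, 1000)]) == 1.0
    two = [GenomicInterval("c", 100, 300), GenomicInterval("c", 250, 400)]
    assert te_content(internal, two) == pytest.approx(0.3)


def test_te_content_union_oracle(rng):
    internal = GenomicInterval("c", 0, 2000)
    r = np.random.default_rng(31)
    hits = [
        GenomicInterval("c", int(s), int(s) + int(w))
        for s, w in zip(r.integers(0, 1900, 25), r.integers(10, 150, 25))
    ]
    covered = np.zeros(2000, dtype=bool)
    for h in hits:
        covered[h.start : min(2000, h.end)] = True
    assert te_content(internal, hits) == pytest.approx(covered.mean())


def test_tir_similarity_cases(rng):
    tir = random_seq(rng, 120, 0.5)
    assert tir_similarity(tir, revcomp(tir)) == 1.0
    # right TIR chosen so its reverse complement reads ACGA against ACGT
    assert tir_similarity("ACGT", "TCGT") == pytest.approx(0.75)
    with pytest.raises(ValueError):
        tir_similarity("", "ACGT")


def test_tir_similarity_decreases_with_divergence(rng):
    tir = random_seq(rng, 150, 0.5)
    means = []
    for T in (0.0, 2e6, 8e6):
        sims = [
            tir_similarity(
                evolve_sequence(tir, 1.3e-8, T, seed=900 + i),
                revcomp(evolve_sequence(tir, 1.3e-8, T, seed=1900 + i)),
            )
            for i in range(20)
        ]
        means.append(np.mean(sims))
    assert means[0] > means[1] > means[2]


# ---------------------------------------------------------------------------
# sRNA occupancy
# ---------------------------------------------------------------------------

def _srna_df(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "length", "abundance", "n_locations"]
    )


def test_srna_length_and_unique_filters():
    region = GenomicInterval("c", 100, 200)
    df = _srna_df([
        ("c", 110, 131, 21, 5, 1),   # 21-nt: excluded
        ("c", 120, 144, 24, 3, 2),   # multi-mapping: excluded if unique_only
        ("c", 130, 154, 24, 7, 1),   # counted
        ("c", 300, 324, 24, 9, 1),   # outside region
    ])
    res = srna_occupancy({"g": [region]}, df, unique_only=True)
    assert res.iloc[0]["mean_per_region"] == 7.0
    res2 = srna_occupancy({"g": [region]}, df, unique_only=False)
    assert res2.iloc[0]["mean_per_region"] == 10.0
    res3 = srna_occupancy({"g": [region]}, df, unique_only=True, mode="species")
    assert res3.iloc[0]["mean_per_region"] == 1.0


def test_srna_group_ordering_recovered(small_sim):
    from mulescout.synthetic import OmicsProfiles, simulate_srna_and_expression

    bundle = small_sim.bundles["Osj"]
    n = len(bundle.truth)
    planted = {
        t.element_id: g
        for t, g in zip(bundle.truth, ["young"] * (n // 2) + ["old"] * (n - n // 2))
    }
    prof = OmicsProfiles(srna_mean_by_group={"young": 40.0, "old": 5.0})
    srna, _ = simulate_srna_and_expression(bundle, planted, prof, seed=21)
    groups = {
        g: [t.internal for t in bundle.truth if planted[t.element_id] == g]
        for g in ("young", "old")
    }
    res = srna_occupancy(groups, srna, unique_only=False)
    by_group = dict(zip(res["group"], res["mean_per_region"]))
    assert by_group["young"] > by_group["old"]


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def test_group_compare_degenerate():
    stat, p, flag = group_compare([1.0, 1.0], [1.0, 1.0])
    assert p == 1.0 and flag


def test_group_compare_separated_samples():
    u, p, flag = group_compare([1, 2, 3], [10, 11, 12])
    assert u == 0.0
    assert 0.02 < p < 0.15  # minimal attainable for n=3,3 (normal approx.)
    assert not flag


def test_group_compare_shifted_normals(rng):
    detected = 0
    for i in range(20):
        r = np.random.default_rng(800 + i)
        a = r.normal(0, 1, 100)
        b = r.normal(2, 1, 100)
        _, p, _ = group_compare(a, b)
        detected += p < 0.001
    assert detected >= 19


def test_group_compare_t_and_errors():
    stat, p, _ = group_compare([1, 2, 3, 4], [1.5, 2.5, 3.5, 4.5], test="t")
    assert p > 0.05
    with pytest.raises(ValueError):
        group_compare([1.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        group_compare([1, 2], [3, 4], test="bogus")
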