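"""Element calling: pairing rules, screening, classification."""
import numpy as np
import pytest

from mulescout.caller import (
    FamilyValidation,
    MuleElement,
    TirHit,
    call_mules,
    classify_genic,
    pair_tirs,
    scan_tir_hits,
    screen_transposase,
    call_mule_derived_genes,
    validate_tir_family,
)
from mulescout.intervals import GenomicInterval
from mulescout.io import HitRecord, Transcript
from mulescout.seqs import random_seq, revcomp
from mulescout.synthetic import PlantConfig, simulate_genomes
from mulescout.tsd import TsdCall


def _planted_genome(rng, n_elements=3, tir_len=120, spacing=3000, family="famX"):
    """Hand-build a genome with clean planted TIR pairs + 9-bp TSDs."""
    tir = random_seq(rng, tir_len, 0.5)
    parts = [random_seq(rng, 500, 0.5)]
    pos = 500
    hits = []
    spans = []
    for _ in range(n_elements):
        tsd = random_seq(rng, 9, 0.5)
        internal = random_seq(rng, 700, 0.5)
        parts.append(tsd + tir + internal + revcomp(tir) + tsd)
        ls = pos + 9
        hits.append(TirHit(family, GenomicInterval("chr1", ls, ls + tir_len, "+"), 100.0))
        rs = ls + tir_len + 700
        hits.append(TirHit(family, GenomicInterval("chr1", rs, rs + tir_len, "-"), 100.0))
        spans.append((ls, rs + tir_len))
        pos += 18 + 2 * tir_len + 700
        parts.append(random_seq(rng, spacing, 0.5))
        pos += spacing
    return {"chr1": "".join(parts)}, hits, spans


def test_pairing_recovers_planted_elements(rng):
    genome, hits, spans = _planted_genome(rng)
    elements = pair_tirs(hits, genome)
    assert [(e.left_tir.start, e.right_tir.end) for e in elements] == spans
    assert all(e.tsd.mismatches == 0 for e in elements)


def test_same_orientation_hits_do_not_pair(rng):
    genome, hits, _ = _planted_genome(rng, n_elements=1)
    same = [
        TirHit(h.family, GenomicInterval(h.interval.chrom, h.interval.start,
                                         h.interval.end, "+"), h.identity)
        for h in hits
    ]
    assert pair_tirs(same, genome) == []


def test_distance_rule_20kb(rng):
    tir = random_seq(rng, 100, 0.5)
    tsd = "GATCGATCG"
    gap = random_seq(rng, 25_000, 0.5)
    seq = random_seq(rng, 200, 0.5) + tsd + tir + gap + revcomp(tir) + tsd \
        + random_seq(rng, 200, 0.5)
    ls = 209
    hits = [
        TirHit("f", GenomicInterval("chr1", ls, ls + 100, "+"), 100.0),
        TirHit("f", GenomicInterval("chr1", ls + 100 + 25_000,
                                    ls + 200 + 25_000, "-"), 100.0),
    ]
    assert pair_tirs(hits, {"chr1": seq}) == []


def test_different_family_does_not_pair(rng):
    genome, hits, _ = _planted_genome(rng, n_elements=1)
    hits[1].family = "other"
    assert pair_tirs(hits, genome) == []


def test_tir_hit_joins_at_most_one_element(small_sim):
    bundle = small_sim.bundles["Oruf"]
    hits = scan_tir_hits(bundle.seqs, small_sim.tir_families)
    elements = pair_tirs(hits, bundle.seqs)
    used = [
        (e.left_tir.start, e.left_tir.end) for e in elements
    ] + [(e.right_tir.start, e.right_tir.end) for e in elements]
    assert len(used) == len(set(used))
    # no two same-family elements overlap
    for i, a in enumerate(elements):
        for b in elements[i + 1 :]:
            if a.family == b.family:
                assert a.span.overlap_len(b.span) == 0


def test_monotone_degradation_with_tsd_mutation():
    """More TSD corruption never increases the number of called elements."""
    counts = []
    for n_mut in (0, 2, 4):
        cfg = PlantConfig(
            seed=303, genome_length=250_000, branch_insertions={"Osj": 8},
            n_donor_genes=4, n_background_genes=4, tsd_mutations=n_mut,
        )
        res = simulate_genomes(cfg)
        b = res.bundles["Osj"]
        hits = scan_tir_hits(b.seqs, res.tir_families)
        counts.append(len(pair_tirs(hits, b.seqs)))
    assert counts[0] >= counts[1] >= counts[2]
    assert counts[0] == 8


# ---------------------------------------------------------------------------
# transposase screening
# ---------------------------------------------------------------------------

def _one_element():
    tsd = TsdCall(9, "A" * 9, "A" * 9, 0, 0, 0)
    return MuleElement(
        "e1", "f",
        GenomicInterval("chr1", 1000, 1100),
        GenomicInterval("chr1", 1100, 1800),
        GenomicInterval("chr1", 1800, 1900),
        tsd,
    )


@pytest.mark.parametrize("evalue,expected", [
    (1e-10, "autonomous"),
    (1e-8, "non-autonomous"),
])
def test_transposase_evalue_threshold(evalue, expected):
    el = _one_element()
    hit = HitRecord("tpase", GenomicInterval("chr1", 1200, 1500), 95.0, 300,
                    evalue=evalue)
    screen_transposase([el], [hit])
    assert el.element_class == expected


def test_no_transposase_hits_all_non_autonomous():
    el = _one_element()
    screen_transposase([el], [])
    assert el.element_class == "non-autonomous"


# ---------------------------------------------------------------------------
# genic classification
# ---------------------------------------------------------------------------

def _transcript_with_cds(genome, start, cds_seq, tid="t1"):
    seq = genome["chr1"]
    genome["chr1"] = seq[:start] + cds_seq + seq[start + len(cds_seq):]
    iv = GenomicInterval("chr1", start, start + len(cds_seq), "+")
    return Transcript(tid, tid, iv, exons=[iv], cds=[iv])


def _make_cds(n_codons, rng):
    from mulescout.synthetic import _random_cds

    return "ATG" + _random_cds(rng, n_codons, 0.5) + "TAA"


def test_cds_below_150_is_nongenic(rng):
    el = _one_element()
    el.element_class = "non-autonomous"
    genome = {"chr1": random_seq(rng, 3000, 0.5)}
    cds = _make_cds(47, rng)  # 147 bp < 150
    tr = _transcript_with_cds(genome, 1200, cds)
    classify_genic([el], [tr], genome)
    assert el.gene_class == "nongenic"


def test_intact_orf_inside_element_is_genic(rng):
    el = _one_element()
    el.element_class = "non-autonomous"
    genome = {"chr1": random_seq(rng, 3000, 0.5)}
    cds = _make_cds(100, rng)  # 306 bp
    tr = _transcript_with_cds(genome, 1200, cds)
    classify_genic([el], [tr], genome)
    assert el.gene_class == "genic"
    assert el.transcript_ids == ["t1"]


def test_overlap_below_30_percent_is_nongenic(rng):
    el = _one_element()
    el.element_class = "non-autonomous"
    genome = {"chr1": random_seq(rng, 6000, 0.5)}
    cds = _make_cds(400, rng)  # 1206 bp transcript
    # place so only ~300 bp (25 %) falls inside the element span (ends 1900)
    tr = _transcript_with_cds(genome, 1600, cds)
    classify_genic([el], [tr], genome)
    assert el.gene_class == "nongenic"


def test_internal_stop_excludes_gene(rng):
    el = _one_element()
    el.element_class = "non-autonomous"
    genome = {"chr1": random_seq(rng, 3000, 0.5)}
    cds = _make_cds(100, rng)
    cds = cds[:150] + "TAA" + cds[153:]  # internal stop in frame
    tr = _transcript_with_cds(genome, 1200, cds)
    classify_genic([el], [tr], genome)
    assert el.gene_class == "nongenic"
    assert call_mule_derived_genes([el], [tr], genome) == []


def test_mule_derived_genes_match_planted_captures(small_sim):
    bundle = small_sim.bundles["Oniv"]
    hits = scan_tir_hits(bundle.seqs, small_sim.tir_families)
    result = call_mules(bundle.seqs, hits, bundle.genes)
    expected = {t.transcript_id for t in bundle.truth if t.transcript_id}
    got = {g.transcript_id for g in result.putative_genes}
    assert got == expected
    for g in result.putative_genes:
        assert g.overlap_fraction >= 0.30
        assert g.element_ids


# ---------------------------------------------------------------------------
# family validation
# ---------------------------------------------------------------------------

def test_family_copy_number_threshold(rng):
    genome, hits, _ = _planted_genome(rng, n_elements=3)
    few = hits[:2] * 9 + hits[:1]  # 19 hits
    v = validate_tir_family("famX", "A" * 100, few, [], genome)
    assert not v.accepted and "copy number" in v.reason


def test_family_mask_threshold(rng):
    genome, hits, _ = _planted_genome(rng, n_elements=10)
    assert len(hits) == 20
    mask = [GenomicInterval("consensus", 0, 40)]  # 40 % of a 100-bp consensus
    v = validate_tir_family("famX", "A" * 100, hits, mask, genome)
    assert not v.accepted and "masked" in v.reason


def test_family_accepted_with_enough_validated_elements(rng):
    genome, hits, spans = _planted_genome(rng, n_elements=10)
    v = validate_tir_family("famX", "A" * 100, hits, [], genome)
    assert v.accepted
    assert v.copy_number == 20
    assert v.validated_elements == 10


def test_family_no_copies():
    v = validate_tir_family("famX", "A" * 100, [], [], {"chr1": "ACGT" * 100})
    assert not v.accepted and v.reason == "no copies"
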