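"""K-mer-seeded, identity-thresholded similarity search.

This is the pipeline's internal substitute for BLAT/BLASTN when running on
synthetic genomes: seeds sampled along the query are matched exactly against
the target, clustered by diagonal, and each cluster is verified with an
edlib semi-global alignment.  Real-data runs import external hit tables
instead; E-value thresholds apply only to those, while internal hits are
filtered on identity and query coverage.
"""
from __future__ import annotations

from dataclasses import dataclass

import edlib

from .intervals import GenomicInterval
from .io import HitRecord
from .seqs import revcomp

DEFAULT_K = 13
DEFAULT_STEP = 5


@dataclass
class _Seed:
    qname: str
    qpos: int
    strand: str


def _collect_seeds(queries: dict[str, str], k: int, step: int) -> dict[str, list[_Seed]]:
    seeds: dict[str, list[_Seed]] = {}
    for qname, qseq in queries.items():
        for strand in ("+", "-"):
            eff = qseq if strand == "+" else revcomp(qseq)
            last = len(eff) - k
            if last < 0:
                continue
            positions = list(range(0, last + 1, step))
            if positions[-1] != last:
                positions.append(last)  # keep the terminal k-mer for exact ends
            for qpos in positions:
                km = eff[qpos : qpos + k]
                if "N" in km:
                    continue
                seeds.setdefault(km, []).append(_Seed(qname, qpos, strand))
    return seeds


def _cluster_diagonals(
    votes: list[tuple[int, int]], gap: int
) -> list[list[tuple[int, int]]]:
    """Group (diagonal, qpos) votes whose diagonals lie within ``gap``."""
    votes = sorted(votes)
    groups: list[list[tuple[int, int]]] = []
    cur: list[tuple[int, int]] = []
    for d, q in votes:
        if cur and d - cur[-1][0] > gap:
            groups.append(cur)
            cur = []
        cur.append((d, q))
    if cur:
        groups.append(cur)
    return groups


def scan_hits(
    queries: dict[str, str],
    genome: dict[str, str],
    k: int = DEFAULT_K,
    step: int = DEFAULT_STEP,
    min_identity: float = 0.8,
    min_coverage: float = 0.8,
    diag_gap: int = 40,
    min_seeds: int = 2,
    pad: int = 30,
) -> list[HitRecord]:
    """All hits of each query (both strands) in the genome.

    One linear pass per chromosome against the pooled seed set of all
    queries, so the cost is O(genome) + O(hits) regardless of query count.
    Identity is computed over the seed-covered query span; ``min_coverage``
    filters on the fraction of the query that span covers (set it to 0 to
    keep partial hits, e.g. for presence/absence coverage tests).
    """
    seeds = _collect_seeds(queries, k, step)
    hits: list[HitRecord] = []
    for chrom, gseq in genome.items():
        votes: dict[tuple[str, str], list[tuple[int, int]]] = {}
        L = len(gseq)
        for i in range(L - k + 1):
            lst = seeds.get(gseq[i : i + k])
            if lst is None:
                continue
            for sd in lst:
                votes.setdefault((sd.qname, sd.strand), []).append((i - sd.qpos, sd.qpos))
        for (qname, strand), vs in votes.items():
            qseq = queries[qname]
            eff = qseq if strand == "+" else revcomp(qseq)
            qlen = len(qseq)
            for group in _cluster_diagonals(vs, diag_gap):
                if len(group) < min_seeds and qlen > 2 * k:
                    continue
                qpos_list = [q for _, q in group]
                qs, qe = min(qpos_list), max(qpos_list) + k
                coverage = (qe - qs) / qlen
                if coverage < min_coverage:
                    continue
                dmin = min(d for d, _ in group)
                dmax = max(d for d, _ in group)
                ws = max(0, dmin + qs - pad)
                we = min(L, dmax + qe + pad)
                if we <= ws:
                    continue
                sub = eff[qs:qe]
                res = edlib.align(sub, gseq[ws:we], mode="HW", task="locations")
                dist = res["editDistance"]
                if dist < 0:
                    continue
                identity = 1.0 - dist / len(sub)
                if identity < min_identity:
                    continue
                loc_s, loc_e = res["locations"][0]
                subject = GenomicInterval(chrom, ws + loc_s, ws + loc_e + 1, strand)
                # query span reported in forward-query coordinates
                if strand == "+":
                    q_start, q_end = qs, qe
                else:
                    q_start, q_end = qlen - qe, qlen - qs
                hits.append(
                    HitRecord(
                        query=qname,
                        subject=subject,
                        identity=100.0 * identity,
                        aln_length=len(sub),
                        evalue=None,
                        score=float(len(sub) - dist),
                        query_coverage=coverage,
                        query_start=q_start,
                        query_end=q_end,
                    )
                )
    return _dedupe(hits)


def _dedupe(hits: list[HitRecord]) -> list[HitRecord]:
    """Drop duplicate/contained hits of the same query at the same locus."""
    hits = sorted(
        hits, key=lambda h: (h.query, h.subject.chrom, -(h.score or 0), h.subject.start)
    )
    kept: list[HitRecord] = []
    for h in hits:
        redundant = False
        for other in kept:
            if (
                other.query == h.query
                and other.subject.chrom == h.subject.chrom
                and other.subject.strand == h.subject.strand
                and other.subject.overlap_len(h.subject) > 0.5 * len(h.subject)
            ):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda h: (h.query, h.subject.chrom, h.subject.start))
    return kept


def best_hit(
    query: str,
    genome: dict[str, str],
    min_coverage: float = 0.0,
    min_identity: float = 0.5,
    **kw,
) -> HitRecord | None:
    """Best-scoring hit of one query; None when no seed cluster verifies."""
    hits = scan_hits(
        {"q": query}, genome, min_identity=min_identity, min_coverage=min_coverage, **kw
    )
    if not hits:
        return None
    return max(hits, key=lambda h: h.score or 0)


def best_hits(
    queries: dict[str, str],
    genome: dict[str, str],
    min_coverage: float = 0.0,
    min_identity: float = 0.5,
    **kw,
) -> dict[str, HitRecord]:
    """Best hit per query in one pass over the genome."""
    hits = scan_hits(
        queries, genome, min_identity=min_identity, min_coverage=min_coverage, **kw
    )
    out: dict[str, HitRecord] = {}
    for h in hits:
        cur = out.get(h.query)
        if cur is None or (h.score or 0) > (cur.score or 0):
            out[h.query] = h
    return out
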