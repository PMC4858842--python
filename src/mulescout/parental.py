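"""Tracing parental sequences of MULE-derived putative genes.

A MULE-derived gene's parental locus is the non-TE genomic copy its
internal sequence was captured from: after masking non-MULE TE content,
the gene is mapped back to its own genome and the best surviving hit --
not overlapping a TE, not flanked by a MULE TIR, and not the gene's own
locus -- is the parental sequence.  Genes with parental hits in two or
more distinct annotated genes are chimeras.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .intervals import GenomicInterval
from .io import HitRecord, Transcript

PARENTAL_EVALUE = 1e-10
TIR_FLANK_WINDOW = 500
SELF_OVERLAP_FRACTION = 0.5


@dataclass
class ParentalAssignment:
    gene_id: str
    parental_intervals: list[GenomicInterval] = field(default_factory=list)
    parental_gene_ids: list[str] = field(default_factory=list)

    @property
    def chimera(self) -> bool:
        return len(set(self.parental_gene_ids)) >= 2


def mask_non_mule(seq: str, hits: list[GenomicInterval]) -> str:
    """Replace non-MULE repeat positions with N (length preserved)."""
    chars = list(seq)
    for iv in hits:
        if iv.start < 0 or iv.end > len(seq):
            raise ValueError(
                f"mask interval {iv.start}-{iv.end} outside sequence of length {len(seq)}"
            )
        chars[iv.start : iv.end] = "N" * len(iv)
    return "".join(chars)


def _flanked_by_tir(
    hit: GenomicInterval, tirs: list[GenomicInterval], window: int
) -> bool:
    probe = hit.expanded(window)
    return any(probe.overlaps(t) for t in tirs)


def find_parental_sequences(
    gene_locus: GenomicInterval,
    hits: list[HitRecord],
    tir_coords: list[GenomicInterval],
    te_coords: list[GenomicInterval],
    flank_window: int = TIR_FLANK_WINDOW,
    evalue_threshold: float = PARENTAL_EVALUE,
) -> list[HitRecord]:
    """Surviving highest-identity hit(s) = parental sequence(s).

    Discards hits overlapping a TE, hits with a MULE TIR inside the
    ``flank_window`` on either side, the gene's own locus (>= 50 %
    reciprocal overlap) and hits failing the E-value threshold when an
    E-value is present (internal scan hits carry identity instead).
    """
    survivors = []
    for h in hits:
        if h.evalue is not None and h.evalue >= evalue_threshold:
            continue
        s = h.subject
        ov = s.overlap_len(gene_locus)
        if ov >= SELF_OVERLAP_FRACTION * min(len(s), len(gene_locus)):
            continue  # self-hit
        if any(s.overlaps(te) for te in te_coords):
            continue
        if _flanked_by_tir(s, tir_coords, flank_window):
            continue
        survivors.append(h)
    if not survivors:
        return []
    top = max(h.identity for h in survivors)
    return [h for h in survivors if h.identity >= top - 1e-9]


def assign_parental_genes(
    gene_id: str,
    parental_hits: list[HitRecord],
    annotation: list[Transcript],
) -> ParentalAssignment:
    """Annotated genes overlapping a parental interval become parents."""
    intervals = [h.subject for h in parental_hits]
    gene_ids: list[str] = []
    for iv in intervals:
        for tr in annotation:
            if tr.interval.overlaps(iv) and tr.gene_id not in gene_ids:
                gene_ids.append(tr.gene_id)
    return ParentalAssignment(gene_id, intervals, gene_ids)


def gc_content(seq: str) -> Optional[float]:
    """(G+C)/(A+C+G+T); N excluded from the denominator; None if all N."""
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        return None
    return gc / acgt


def select_non_te_genes(
    annotation: list[Transcript],
    te_tir_coords: list[GenomicInterval],
    flank: int = 500,
) -> list[Transcript]:
    """Control genes: no TE/TIR overlap and none within the flank window."""
    if flank not in (500, 1000):
        raise ValueError("flank must be 500 or 1000")
    out = []
    for tr in annotation:
        probe = tr.interval.expanded(flank)
        if not any(probe.overlaps(iv) for iv in te_tir_coords):
            out.append(tr)
    return out
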