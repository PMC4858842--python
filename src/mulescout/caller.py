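"""Calling putative MULEs from TIR hits and classifying them.

The calling rules: two TIR hits form an element when they belong to the
same family, lie in opposite orientations less than 20 kb apart, and a
valid 7-11 bp TSD flanks both repeats.  Elements overlapping a transposase
hit (E < 1e-9 for imported tables) are autonomous; the remainder are
non-autonomous and are classified genic when an annotated transcript with
>= 150 bp of intact coding sequence overlaps them by >= 30 % of the
transcript length.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .intervals import GenomicInterval, union_length
from .io import HitRecord, Transcript
from .scan import scan_hits
from .seqs import has_intact_orf, revcomp
from .tsd import TsdCall, find_tsd

MAX_TIR_DISTANCE = 20_000
TRANSPOSASE_EVALUE = 1e-9
MIN_CDS_LEN = 150
MIN_OVERLAP_FRACTION = 0.30
MIN_FAMILY_COPIES = 20
MAX_MASKED_FRACTION = 0.30
MIN_VALIDATED_ELEMENTS = 5


@dataclass
class TirHit:
    family: str
    interval: GenomicInterval
    identity: float
    source: str = "internal"

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("TIR hit needs a family name")


@dataclass
class MuleElement:
    element_id: str
    family: str
    left_tir: GenomicInterval
    internal: GenomicInterval
    right_tir: GenomicInterval
    tsd: TsdCall
    element_class: str = "unclassified"   # autonomous | non-autonomous
    gene_class: str = "unclassified"      # genic | nongenic
    transcript_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (
            self.left_tir.end <= self.internal.start
            and self.internal.end <= self.right_tir.start
        ):
            raise ValueError("element intervals out of order")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.left_tir.chrom, self.left_tir.start, self.right_tir.end
        )


@dataclass
class PutativeGene:
    transcript_id: str
    transcript: Transcript
    overlap_fraction: float
    element_ids: list[str]
    chimera: bool = False
    parental_gene_ids: list[str] = field(default_factory=list)


@dataclass
class FamilyValidation:
    family: str
    accepted: bool
    reason: str
    copy_number: int
    masked_fraction: float
    validated_elements: int


# ---------------------------------------------------------------------------
# TIR scanning (synthetic runs; real runs import RepeatMasker/BLAST tables)
# ---------------------------------------------------------------------------

def scan_tir_hits(
    genome: dict[str, str],
    families: dict[str, str],
    min_identity: float = 0.8,
    min_coverage: float = 0.8,
) -> list[TirHit]:
    """K-mer-seeded scan of the genome for TIR-family copies."""
    hits = scan_hits(
        families, genome, min_identity=min_identity, min_coverage=min_coverage
    )
    return [
        TirHit(h.query, h.subject, h.identity, source="internal") for h in hits
    ]


def tir_hits_from_records(
    records: list[HitRecord], source: str = "imported"
) -> list[TirHit]:
    return [TirHit(h.query, h.subject, h.identity, source=source) for h in records]


# ---------------------------------------------------------------------------
# family validation
# ---------------------------------------------------------------------------

def validate_tir_family(
    family: str,
    consensus: str,
    hits: list[TirHit],
    non_mule_mask: list[GenomicInterval],
    genome: dict[str, str],
) -> FamilyValidation:
    """Accept a candidate TIR family or reject it with a reason.

    ``non_mule_mask`` holds intervals of the consensus covered by known
    non-MULE repeats (coordinates on the consensus itself).
    """
    fam_hits = [h for h in hits if h.family == family]
    copies = len(fam_hits)
    masked = union_length(non_mule_mask) / len(consensus) if consensus else 0.0
    if copies == 0:
        return FamilyValidation(family, False, "no copies", 0, masked, 0)
    if copies < MIN_FAMILY_COPIES:
        return FamilyValidation(
            family, False, f"copy number {copies} < {MIN_FAMILY_COPIES}",
            copies, masked, 0,
        )
    if masked >= MAX_MASKED_FRACTION:
        return FamilyValidation(
            family, False,
            f"masked fraction {masked:.2f} >= {MAX_MASKED_FRACTION}",
            copies, masked, 0,
        )
    elements = pair_tirs(fam_hits, genome)
    if len(elements) < MIN_VALIDATED_ELEMENTS:
        return FamilyValidation(
            family, False,
            f"only {len(elements)} TSD-validated elements < {MIN_VALIDATED_ELEMENTS}",
            copies, masked, len(elements),
        )
    return FamilyValidation(family, True, "accepted", copies, masked, len(elements))


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def pair_tirs(
    hits: list[TirHit],
    genome: dict[str, str],
    max_distance: int = MAX_TIR_DISTANCE,
    swing: int = 10,
    id_prefix: str = "el",
) -> list[MuleElement]:
    """Greedy left-to-right pairing of TIR hits into elements.

    For each unused hit the nearest valid partner (same family, opposite
    orientation, inner-edge distance < 20 kb, valid TSD) is taken first;
    a TIR hit joins at most one element.
    """
    elements: list[MuleElement] = []
    by_chrom: dict[str, list[TirHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.interval.chrom, []).append(h)
    counter = 0
    for chrom in sorted(by_chrom):
        seq = genome[chrom]
        chits = sorted(by_chrom[chrom], key=lambda h: (h.interval.start, h.interval.end))
        used = [False] * len(chits)
        for i, left in enumerate(chits):
            if used[i]:
                continue
            partners = [
                (j, chits[j])
                for j in range(i + 1, len(chits))
                if not used[j]
                and chits[j].family == left.family
                and chits[j].interval.strand != left.interval.strand
                and chits[j].interval.start >= left.interval.end
                and chits[j].interval.start - left.interval.end < max_distance
            ]
            partners.sort(key=lambda p: p[1].interval.start - left.interval.end)
            for j, right in partners:
                if right.interval.start <= left.interval.end:
                    continue
                tsd = find_tsd(
                    seq, left.interval.start, right.interval.end, swing=swing
                )
                if tsd is None:
                    continue
                elements.append(
                    MuleElement(
                        element_id=f"{id_prefix}{counter:05d}",
                        family=left.family,
                        left_tir=left.interval,
                        internal=GenomicInterval(
                            chrom, left.interval.end, right.interval.start
                        ),
                        right_tir=right.interval,
                        tsd=tsd,
                    )
                )
                counter += 1
                used[i] = used[j] = True
                break
    return elements


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _hit_passes_transposase(h: HitRecord, evalue_threshold: float) -> bool:
    if h.evalue is not None:
        return h.evalue < evalue_threshold
    # PSL/internal tables carry no E-value: identity + coverage proxy
    return h.identity >= 80.0 and h.query_coverage >= 0.5


def screen_transposase(
    elements: list[MuleElement],
    transposase_hits: list[HitRecord],
    evalue_threshold: float = TRANSPOSASE_EVALUE,
) -> list[MuleElement]:
    """Label elements autonomous/non-autonomous by transposase overlap."""
    strong = [
        h for h in transposase_hits if _hit_passes_transposase(h, evalue_threshold)
    ]
    for el in elements:
        span = el.span
        el.element_class = (
            "autonomous"
            if any(span.overlaps(h.subject) for h in strong)
            else "non-autonomous"
        )
    return elements


def _cds_sequence(tr: Transcript, genome: dict[str, str]) -> str:
    if not tr.cds:
        return ""
    seq = genome.get(tr.interval.chrom, "")
    parts = [seq[c.start : c.end] for c in sorted(tr.cds, key=lambda c: c.start)]
    cds = "".join(parts)
    if tr.interval.strand == "-":
        cds = revcomp(cds)
    return cds


def _transcript_overlap_fraction(tr: Transcript, span: GenomicInterval) -> float:
    parts = tr.exons or [tr.interval]
    overlap = sum(p.overlap_len(span) for p in parts)
    return overlap / tr.transcript_length if tr.transcript_length else 0.0


def _qualifying_transcript(
    tr: Transcript,
    genome: dict[str, str],
    transposase_hits: list[HitRecord],
    evalue_threshold: float,
) -> bool:
    if tr.cds_length < MIN_CDS_LEN:
        return False
    cds = _cds_sequence(tr, genome)
    if not has_intact_orf(cds, MIN_CDS_LEN):
        return False
    strong = [
        h for h in transposase_hits if _hit_passes_transposase(h, evalue_threshold)
    ]
    if any(tr.interval.overlaps(h.subject) for h in strong):
        return False
    return True


def classify_genic(
    elements: list[MuleElement],
    transcripts: list[Transcript],
    genome: dict[str, str],
    transposase_hits: Optional[list[HitRecord]] = None,
    min_overlap: float = MIN_OVERLAP_FRACTION,
) -> list[MuleElement]:
    """Set gene_class genic/nongenic on non-autonomous elements.

    A transcript qualifies with >= 150 bp of CDS, intact ATG start and
    stop codon, no internal stop and no transposase overlap; the element
    is genic iff such a transcript overlaps it by >= 30 % of the
    transcript length (sum of exon lengths).
    """
    tp_hits = transposase_hits or []
    qualifying = [
        tr
        for tr in transcripts
        if _qualifying_transcript(tr, genome, tp_hits, TRANSPOSASE_EVALUE)
    ]
    for el in elements:
        if el.element_class == "autonomous":
            el.gene_class = "unclassified"
            continue
        span = el.span
        matched = [
            tr
            for tr in qualifying
            if _transcript_overlap_fraction(tr, span) >= min_overlap
        ]
        el.gene_class = "genic" if matched else "nongenic"
        el.transcript_ids = [tr.transcript_id for tr in matched]
    return elements


def call_mule_derived_genes(
    elements: list[MuleElement],
    transcripts: list[Transcript],
    genome: dict[str, str],
    transposase_hits: Optional[list[HitRecord]] = None,
    min_overlap: float = MIN_OVERLAP_FRACTION,
) -> list[PutativeGene]:
    """Transcripts derived from non-autonomous MULEs.

    Returns transcripts with intact >= 150 bp CDS overlapped by
    non-autonomous element spans on >= 30 % of the transcript length,
    linked to the overlapping element(s).
    """
    tp_hits = transposase_hits or []
    non_auto = [el for el in elements if el.element_class != "autonomous"]
    out: list[PutativeGene] = []
    for tr in transcripts:
        if not _qualifying_transcript(tr, genome, tp_hits, TRANSPOSASE_EVALUE):
            continue
        parts = tr.exons or [tr.interval]
        linked = []
        covered = 0
        for el in non_auto:
            ov = sum(p.overlap_len(el.span) for p in parts)
            if ov > 0:
                linked.append(el.element_id)
                covered += ov
        frac = covered / tr.transcript_length if tr.transcript_length else 0.0
        if linked and frac >= min_overlap:
            out.append(
                PutativeGene(
                    transcript_id=tr.transcript_id,
                    transcript=tr,
                    overlap_fraction=frac,
                    element_ids=linked,
                )
            )
    return out


# ---------------------------------------------------------------------------
# one-call pipeline
# ---------------------------------------------------------------------------

@dataclass
class CallResult:
    elements: list[MuleElement]
    putative_genes: list[PutativeGene]
    rejection_log: dict[str, int]


def call_mules(
    genome: dict[str, str],
    tir_hits: list[TirHit],
    transcripts: list[Transcript],
    transposase_hits: Optional[list[HitRecord]] = None,
) -> CallResult:
    """Pair, screen and classify in one pass; logs per-rule counts."""
    elements = pair_tirs(tir_hits, genome)
    screen_transposase(elements, transposase_hits or [])
    n_auto = sum(1 for e in elements if e.element_class == "autonomous")
    classify_genic(elements, transcripts, genome, transposase_hits)
    genes = call_mule_derived_genes(
        [e for e in elements if e.element_class == "non-autonomous"],
        transcripts,
        genome,
        transposase_hits,
    )
    log = {
        "tir_hits": len(tir_hits),
        "elements_called": len(elements),
        "autonomous_removed": n_auto,
        "genic": sum(1 for e in elements if e.gene_class == "genic"),
        "nongenic": sum(1 for e in elements if e.gene_class == "nongenic"),
        "putative_genes": len(genes),
    }
    return CallResult(elements, genes, log)
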