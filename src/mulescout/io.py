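"""Readers and writers for the external formats the pipeline touches.

All coordinates are normalised to the internal 0-based half-open convention
on the way in and converted back on the way out, so the conversion is an
involution for the 1-based formats (GFF3, RepeatMasker .out, cytosine
reports).  Supported formats:

==================  =======================================================
GFF3                genes/transcripts/arbitrary features, 1-based inclusive
BED6                0-based half-open
RepeatMasker .out   1-based inclusive; orientation column ``C`` = minus
BLAST outfmt 6      12-column tabular hits, 1-based inclusive subject coords
PSL                 BLAT; 0-based half-open, identity from matches/span
cytosine report     bismark-style 6 columns, 1-based positions
FASTA               via Biopython
==================  =======================================================
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import AnnotatedInterval, GenomicInterval


class FormatError(ValueError):
    """Raised for malformed input lines; carries the offending line number."""


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass
class HitRecord:
    """One similarity-search hit (BLAST/BLAT/internal scan)."""

    query: str
    subject: GenomicInterval
    identity: float              # percent, [0, 100]
    aln_length: int
    evalue: Optional[float] = None
    score: Optional[float] = None
    query_coverage: float = 1.0  # fraction of the query aligned, [0, 1]
    query_start: int = 0
    query_end: int = 0

    def __post_init__(self) -> None:
        if self.aln_length < 1:
            raise ValueError("alignment length must be >= 1")
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if not (0.0 <= self.query_coverage <= 1.0):
            raise ValueError("query coverage outside [0, 1]")
        if self.evalue is not None and self.evalue < 0:
            raise ValueError("negative E-value")


@dataclass
class CytosineCall:
    """Per-cytosine bisulfite call: counts of methylated/total reads."""

    position: GenomicInterval  # width 1, stranded
    context: str               # CG | CHG | CHH
    methylated: int
    total: int

    def __post_init__(self) -> None:
        if self.context not in ("CG", "CHG", "CHH"):
            raise ValueError(f"unknown cytosine context {self.context!r}")
        if not (0 <= self.methylated <= self.total):
            raise ValueError(
                f"require 0 <= methylated ({self.methylated}) <= total ({self.total})"
            )
        if len(self.position) != 1:
            raise ValueError("cytosine position must have width 1")


@dataclass
class Transcript:
    """A transcript with exon and CDS structure (internal coordinates)."""

    transcript_id: str
    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)

    @property
    def transcript_length(self) -> int:
        """Sum of exon lengths (mature transcript length)."""
        parts = self.exons or [self.interval]
        return sum(len(e) for e in parts)

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(path: str, seqs: dict[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(recs, path, "fasta")


# ---------------------------------------------------------------------------
# interval formats
# ---------------------------------------------------------------------------

def _parse_gff3_attributes(text: str) -> dict:
    attrs = {}
    for part in text.strip().rstrip(";").split(";"):
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_intervals(path: str, format: str) -> list[AnnotatedInterval]:
    """Read annotated intervals from GFF3, BED or RepeatMasker .out.

    GFF3 and RepeatMasker 1-based inclusive coordinates are shifted to the
    internal 0-based half-open convention; BED is passed through unchanged.
    """
    fmt = format.lower()
    if fmt == "gff3":
        return _read_gff3_intervals(path)
    if fmt == "bed":
        return _read_bed(path)
    if fmt in ("repeatmasker-out", "rmout", "repeatmasker"):
        return _read_repeatmasker_out(path)
    raise FormatError(f"unknown interval format {format!r}")


def _read_gff3_intervals(path: str) -> list[AnnotatedInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            try:
                start = int(cols[3]) - 1  # 1-based inclusive -> 0-based
                end = int(cols[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = cols[6] if cols[6] in ("+", "-") else "."
            attrs = _parse_gff3_attributes(cols[8])
            score = None if cols[5] == "." else float(cols[5])
            out.append(
                AnnotatedInterval(
                    GenomicInterval(cols[0], start, end, strand),
                    feature=cols[2],
                    name=attrs.get("ID", attrs.get("Name", "")),
                    score=score,
                    attributes={**attrs, "source": cols[1]},
                )
            )
    return out


def write_gff3(path: str, items: list[AnnotatedInterval]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for it in items:
            iv = it.interval
            attrs = {k: v for k, v in it.attributes.items() if k != "source"}
            if it.name and "ID" not in attrs:
                attrs = {"ID": it.name, **attrs}
            attr_text = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            score = "." if it.score is None else f"{it.score:g}"
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        it.attributes.get("source", "mulescout"),
                        it.feature,
                        str(iv.start + 1),
                        str(iv.end),
                        score,
                        iv.strand,
                        ".",
                        attr_text,
                    ]
                )
                + "\n"
            )


def _read_bed(path: str) -> list[AnnotatedInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = cols[3] if len(cols) > 3 else ""
            score = None
            if len(cols) > 4 and cols[4] not in (".", ""):
                score = float(cols[4])
            strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "."
            attrs = {}
            # extra columns beyond BED6 are kept verbatim
            if len(cols) > 6:
                attrs["extra"] = cols[6:]
            out.append(
                AnnotatedInterval(
                    GenomicInterval(cols[0], start, end, strand),
                    feature="bed",
                    name=name,
                    score=score,
                    attributes=attrs,
                )
            )
    return out


def write_bed(path: str, items: list[AnnotatedInterval]) -> None:
    with open(path, "w") as fh:
        for it in items:
            iv = it.interval
            score = "0" if it.score is None else f"{it.score:g}"
            cols = [iv.chrom, str(iv.start), str(iv.end), it.name or ".", score, iv.strand]
            cols.extend(it.attributes.get("extra", []))
            fh.write("\t".join(cols) + "\n")


_RM_HEADER_TOKENS = ("SW", "score")


def _read_repeatmasker_out(path: str) -> list[AnnotatedInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith(_RM_HEADER_TOKENS) or stripped.startswith(
                "there were no"
            ):
                continue
            cols = stripped.split()
            if len(cols) < 11:
                raise FormatError(f"{path}:{lineno}: short RepeatMasker row")
            try:
                score = float(cols[0])
                div = float(cols[1])
                start = int(cols[5]) - 1
                end = int(cols[6])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed RepeatMasker row") from exc
            strand = "-" if cols[8] == "C" else "+"
            out.append(
                AnnotatedInterval(
                    GenomicInterval(cols[4], start, end, strand),
                    feature="repeat",
                    name=cols[9],
                    score=score,
                    attributes={"family": cols[10], "divergence": div},
                )
            )
    return out


def write_repeatmasker_out(path: str, items: list[AnnotatedInterval]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "   SW   perc perc perc  query      position in query    matching repeat\n"
            "score   div. del. ins.  sequence   begin  end  (left)   repeat     class/family\n\n"
        )
        for it in items:
            iv = it.interval
            orient = "C" if iv.strand == "-" else "+"
            fh.write(
                "  ".join(
                    [
                        f"{it.score or 0:.0f}",
                        f"{it.attributes.get('divergence', 0.0):.1f}",
                        "0.0",
                        "0.0",
                        iv.chrom,
                        str(iv.start + 1),
                        str(iv.end),
                        "(0)",
                        orient,
                        it.name or "repeat",
                        it.attributes.get("family", "Unknown"),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# transcripts (GFF3 gene models)
# ---------------------------------------------------------------------------

def read_transcripts(path: str) -> list[Transcript]:
    """Assemble gene models from a GFF3 file (mRNA + exon + CDS features)."""
    feats = _read_gff3_intervals(path)
    transcripts: dict[str, Transcript] = {}
    for f in feats:
        if f.feature in ("mRNA", "transcript"):
            tid = f.attributes.get("ID", f.name)
            transcripts[tid] = Transcript(
                transcript_id=tid,
                gene_id=f.attributes.get("Parent", tid),
                interval=f.interval,
            )
    for f in feats:
        if f.feature in ("exon", "CDS"):
            parent = f.attributes.get("Parent", "")
            for tid in parent.split(","):
                tr = transcripts.get(tid)
                if tr is None:
                    continue
                (tr.exons if f.feature == "exon" else tr.cds).append(f.interval)
    for tr in transcripts.values():
        tr.exons.sort(key=lambda iv: iv.start)
        tr.cds.sort(key=lambda iv: iv.start)
    return list(transcripts.values())


def write_transcripts(path: str, transcripts: list[Transcript]) -> None:
    items: list[AnnotatedInterval] = []
    for tr in transcripts:
        items.append(
            AnnotatedInterval(
                tr.interval,
                feature="mRNA",
                name=tr.transcript_id,
                attributes={"ID": tr.transcript_id, "Parent": tr.gene_id},
            )
        )
        for i, ex in enumerate(tr.exons):
            items.append(
                AnnotatedInterval(
                    ex, feature="exon", name=f"{tr.transcript_id}.exon{i}",
                    attributes={"Parent": tr.transcript_id},
                )
            )
        for i, c in enumerate(tr.cds):
            items.append(
                AnnotatedInterval(
                    c, feature="CDS", name=f"{tr.transcript_id}.cds{i}",
                    attributes={"Parent": tr.transcript_id},
                )
            )
    write_gff3(path, items)


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------

def read_hit_table(path: str, format: str = "blast-tab-6") -> list[HitRecord]:
    fmt = format.lower()
    if fmt in ("blast-tab-6", "blast6", "outfmt6"):
        return _read_blast6(path)
    if fmt == "psl":
        return _read_psl(path)
    raise FormatError(f"unknown hit-table format {format!r}")


def _read_blast6(path: str) -> list[HitRecord]:
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
            (qid, sid, pident, alen, _mm, _go, qs, qe, ss, se, ev, sc) = cols
            s_start, s_end = int(ss), int(se)
            strand = "+"
            if s_start > s_end:
                s_start, s_end = s_end, s_start
                strand = "-"
            q_start, q_end = int(qs), int(qe)
            hits.append(
                HitRecord(
                    query=qid,
                    subject=GenomicInterval(sid, s_start - 1, s_end, strand),
                    identity=float(pident),
                    aln_length=int(alen),
                    evalue=float(ev),
                    score=float(sc),
                    query_start=q_start - 1,
                    query_end=q_end,
                )
            )
    return hits


def write_blast6(path: str, hits: list[HitRecord]) -> None:
    with open(path, "w") as fh:
        for h in hits:
            s = h.subject
            ss, se = (s.start + 1, s.end) if s.strand != "-" else (s.end, s.start + 1)
            fh.write(
                "\t".join(
                    [
                        h.query,
                        s.chrom,
                        f"{h.identity:.2f}",
                        str(h.aln_length),
                        "0",
                        "0",
                        str(h.query_start + 1),
                        str(h.query_end),
                        str(ss),
                        str(se),
                        f"{h.evalue if h.evalue is not None else 0:.2g}",
                        f"{h.score if h.score is not None else 0:.1f}",
                    ]
                )
                + "\n"
            )


def _read_psl(path: str) -> list[HitRecord]:
    hits = []
    with open(path) as fh:
        lines = fh.readlines()
    start_idx = 0
    # optional 5-line psLayout header
    for i, line in enumerate(lines[:6]):
        if line.startswith("-----"):
            start_idx = i + 1
            break
        if line.startswith(("psLayout", "match", "     ", "\t")) and not line[:1].isdigit():
            start_idx = i + 1
    for lineno, line in enumerate(lines[start_idx:], start_idx + 1):
        line = line.rstrip("\n")
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) < 21:
            raise FormatError(f"{path}:{lineno}: PSL needs 21 columns, got {len(cols)}")
        matches, mismatches = int(cols[0]), int(cols[1])
        rep_matches, ncount = int(cols[2]), int(cols[3])
        strand = cols[8]
        qname, qsize = cols[9], int(cols[10])
        qstart, qend = int(cols[11]), int(cols[12])
        tname = cols[13]
        tstart, tend = int(cols[15]), int(cols[16])
        span = matches + mismatches + rep_matches + ncount
        if span < 1:
            raise FormatError(f"{path}:{lineno}: empty PSL alignment")
        identity = 100.0 * (matches + rep_matches) / span
        hits.append(
            HitRecord(
                query=qname,
                subject=GenomicInterval(tname, tstart, tend, "-" if "-" in strand else "+"),
                identity=identity,
                aln_length=span,
                evalue=None,
                score=float(matches),
                query_coverage=min(1.0, (qend - qstart) / qsize) if qsize else 1.0,
                query_start=qstart,
                query_end=qend,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# cytosine report
# ---------------------------------------------------------------------------

def read_cytosine_report(path: str) -> list[CytosineCall]:
    """Bismark-style report: chrom, 1-based pos, strand, meth, unmeth, context."""
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(cols)}")
            chrom, pos, strand, meth, unmeth, context = cols[:6]
            try:
                pos_i, meth_i, unmeth_i = int(pos), int(meth), int(unmeth)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field") from exc
            if meth_i < 0 or unmeth_i < 0:
                raise FormatError(f"{path}:{lineno}: negative read count")
            if context not in ("CG", "CHG", "CHH"):
                raise FormatError(f"{path}:{lineno}: unknown context {context!r}")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            calls.append(
                CytosineCall(
                    position=GenomicInterval(chrom, pos_i - 1, pos_i, strand),
                    context=context,
                    methylated=meth_i,
                    total=meth_i + unmeth_i,
                )
            )
    return calls


def write_cytosine_report(path: str, calls: list[CytosineCall]) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                "\t".join(
                    [
                        c.position.chrom,
                        str(c.position.start + 1),
                        c.position.strand,
                        str(c.methylated),
                        str(c.total - c.methylated),
                        c.context,
                    ]
                )
                + "\n"
            )


def ensure_dir(path: str) -> None:
    os.makedirs(path, exist_ok=True)
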