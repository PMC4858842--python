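"""Region methylation, meta-profiles, TE content, TIR similarity, sRNA.

Methylation of a region is the pooled read-weighted level over cytosines
of one context covered by >= 3 reads; the region is undefined unless at
least half of its cytosines are mapped.  A site-binary mode (site
methylated iff >= 1 methylated read) is exposed as well, since region
summaries are reported both ways in the bisulfite literature.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .intervals import GenomicInterval, clip_to, merge_intervals
from .io import CytosineCall
from .seqs import revcomp

MIN_COVERAGE = 3
MIN_MAPPED_FRACTION = 0.5


@dataclass
class MethylationSummary:
    region: GenomicInterval
    context: str
    level: Optional[float]
    n_cytosines: int
    n_mapped: int
    undefined_reason: Optional[str] = None  # no_cytosines | low_coverage

    @property
    def mapped_fraction(self) -> float:
        return self.n_mapped / self.n_cytosines if self.n_cytosines else 0.0


@dataclass
class RegionPartition:
    """Element anatomy: flank / TIR / internal / TIR / flank."""

    upstream: Optional[GenomicInterval]
    left_tir: GenomicInterval
    internal: GenomicInterval
    right_tir: GenomicInterval
    downstream: Optional[GenomicInterval]

    @classmethod
    def from_element(cls, left_tir, internal, right_tir, flank: int = 500,
                     chrom_len: Optional[int] = None) -> "RegionPartition":
        chrom = left_tir.chrom
        up = None
        if left_tir.start > 0:
            up = GenomicInterval(chrom, max(0, left_tir.start - flank), left_tir.start)
        down_end = right_tir.end + flank if chrom_len is None else min(
            chrom_len, right_tir.end + flank
        )
        down = None
        if down_end > right_tir.end:
            down = GenomicInterval(chrom, right_tir.end, down_end)
        return cls(up, left_tir, internal, right_tir, down)


class CallIndex:
    """Per-chromosome sorted arrays for fast region queries on call tables."""

    def __init__(self, calls: Union[pd.DataFrame, Iterable[CytosineCall]]):
        df = calls_to_frame(calls)
        self._by_chrom: dict[str, dict[str, np.ndarray]] = {}
        for chrom, sub in df.groupby("chrom"):
            self._by_chrom[str(chrom)] = {
                "pos": sub["pos"].to_numpy(),
                "context": sub["context"].to_numpy(),
                "total": sub["total"].to_numpy(),
                "meth": sub["meth"].to_numpy(),
            }

    def region(self, region: GenomicInterval, context: str) -> tuple[np.ndarray, np.ndarray]:
        """(total, meth) arrays for cytosines of one context in the region."""
        data = self._by_chrom.get(region.chrom)
        if data is None:
            return np.array([], dtype=int), np.array([], dtype=int)
        lo = np.searchsorted(data["pos"], region.start, side="left")
        hi = np.searchsorted(data["pos"], region.end, side="left")
        mask = data["context"][lo:hi] == context
        return data["total"][lo:hi][mask], data["meth"][lo:hi][mask]


def calls_to_frame(calls: Union[pd.DataFrame, Iterable[CytosineCall]]) -> pd.DataFrame:
    """Normalise a call table (list of records or DataFrame) for querying."""
    if isinstance(calls, pd.DataFrame):
        df = calls
    else:
        rows = [
            (c.position.chrom, c.position.start, c.position.strand, c.context,
             c.total, c.methylated)
            for c in calls
        ]
        df = pd.DataFrame(
            rows, columns=["chrom", "pos", "strand", "context", "total", "meth"]
        )
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def methylation_level(
    region: GenomicInterval,
    calls: Union[pd.DataFrame, Iterable[CytosineCall]],
    context: str,
    min_coverage: int = MIN_COVERAGE,
    min_mapped_fraction: float = MIN_MAPPED_FRACTION,
    mode: str = "weighted",
) -> MethylationSummary:
    """Region methylation level for one context.

    weighted: sum(methylated reads) / sum(total reads) over mapped sites.
    site: fraction of mapped sites with >= 1 methylated read.
    """
    index = calls if isinstance(calls, CallIndex) else CallIndex(calls)
    total, meth = index.region(region, context)
    n_cyt = total.size
    if n_cyt == 0:
        return MethylationSummary(region, context, None, 0, 0, "no_cytosines")
    mapped = total >= min_coverage
    n_mapped = int(mapped.sum())
    if n_mapped / n_cyt < min_mapped_fraction:
        return MethylationSummary(
            region, context, None, n_cyt, n_mapped, "low_coverage"
        )
    if mode == "weighted":
        level = float(meth[mapped].sum() / total[mapped].sum())
    elif mode == "site":
        level = float((meth[mapped] >= 1).mean())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return MethylationSummary(region, context, level, n_cyt, n_mapped)


def _bin_interval(iv: GenomicInterval, n_bins: int) -> list[GenomicInterval]:
    edges = np.linspace(iv.start, iv.end, n_bins + 1).astype(int)
    out = []
    for s, e in zip(edges[:-1], edges[1:]):
        if e > s:
            out.append(GenomicInterval(iv.chrom, int(s), int(e)))
    return out


def _flank_bins(iv: GenomicInterval, width: int = 50) -> list[GenomicInterval]:
    out = []
    s = iv.start
    while s < iv.end:
        e = min(iv.end, s + width)
        if e > s:
            out.append(GenomicInterval(iv.chrom, s, e))
        s = e
    return out


def meta_profile(
    groups: dict[str, list[RegionPartition]],
    calls: Union[pd.DataFrame, Iterable[CytosineCall]],
    contexts: Sequence[str] = ("CG", "CHG", "CHH"),
    flank_bin: int = 50,
    tir_bins: int = 10,
    internal_bins: int = 20,
    min_elements: int = 10,
    **level_kw,
) -> pd.DataFrame:
    """Mean per-bin methylation over element anatomy, per age group.

    Flanks use fixed 50-bp windows; TIRs and internals are
    length-normalised into 10 and 20 proportional bins.  Bins supported by
    fewer than ``min_elements`` defined element levels are flagged.
    """
    df = calls if isinstance(calls, CallIndex) else CallIndex(calls)
    rows = []
    for group, parts in groups.items():
        for context in contexts:
            per_bin: dict[tuple[str, int], list[float]] = {}
            for part in parts:
                sections: list[tuple[str, list[GenomicInterval]]] = []
                if part.upstream is not None:
                    sections.append(("upstream", _flank_bins(part.upstream, flank_bin)))
                sections.append(("left_tir", _bin_interval(part.left_tir, tir_bins)))
                sections.append(("internal", _bin_interval(part.internal, internal_bins)))
                sections.append(("right_tir", _bin_interval(part.right_tir, tir_bins)))
                if part.downstream is not None:
                    sections.append(
                        ("downstream", _flank_bins(part.downstream, flank_bin))
                    )
                for name, bins in sections:
                    for b_idx, biv in enumerate(bins):
                        summ = methylation_level(biv, df, context, **level_kw)
                        if summ.level is not None:
                            per_bin.setdefault((name, b_idx), []).append(summ.level)
            for (name, b_idx), values in sorted(per_bin.items()):
                rows.append(
                    {
                        "group": group,
                        "context": context,
                        "section": name,
                        "bin": b_idx,
                        "mean_level": float(np.mean(values)),
                        "n_elements": len(values),
                        "flagged": len(values) < min_elements,
                    }
                )
    return pd.DataFrame(rows)


def te_content(
    internal: GenomicInterval, repeat_hits: Iterable[GenomicInterval]
) -> Optional[float]:
    """Masked fraction of the internal region (overlaps merged first)."""
    if len(internal) == 0:
        return None
    clipped = [c for c in (clip_to(h, internal) for h in repeat_hits) if c is not None]
    if not clipped:
        return 0.0
    covered = sum(len(iv) for iv in merge_intervals(clipped))
    return covered / len(internal)


_tir_aligner = Align.PairwiseAligner()
_tir_aligner.mode = "global"
_tir_aligner.match_score = 1
_tir_aligner.mismatch_score = -1
_tir_aligner.open_gap_score = -2
_tir_aligner.extend_gap_score = -0.5


def tir_similarity(left: str, right: str) -> float:
    """Identical aligned bases / left-TIR length.

    The right TIR is reverse-complemented onto the left orientation before
    the global alignment.
    """
    if not left or not right:
        raise ValueError("TIR sequences must be non-empty")
    rc = revcomp(right)
    aln = _tir_aligner.align(left.upper(), rc.upper())[0]
    a, b = aln[0], aln[1]
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches / len(left)


def srna_occupancy(
    groups: dict[str, list[GenomicInterval]],
    srna: pd.DataFrame,
    length: int = 24,
    unique_only: bool = True,
    mode: str = "reads",
) -> pd.DataFrame:
    """Mean summed sRNA abundance per region, by group (and tissue if given).

    Filters to records of the requested read length; with ``unique_only``
    keeps only records mapping to exactly one genomic location.  ``mode``
    'reads' sums abundance, 'species' counts distinct records.
    """
    df = srna[srna["length"] == length]
    if unique_only:
        df = df[df["n_locations"] == 1]
    tissues = sorted(df["tissue"].unique()) if "tissue" in df.columns else [None]
    rows = []
    for tissue in tissues:
        sub = df if tissue is None else df[df["tissue"] == tissue]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        chroms = sub["chrom"].to_numpy()
        abundance = sub["abundance"].to_numpy()
        for group, regions in groups.items():
            per_region = []
            for iv in regions:
                mask = (chroms == iv.chrom) & (starts < iv.end) & (ends > iv.start)
                if mode == "reads":
                    per_region.append(float(abundance[mask].sum()))
                elif mode == "species":
                    per_region.append(float(mask.sum()))
                else:
                    raise ValueError(f"unknown mode {mode!r}")
            rows.append(
                {
                    "group": group,
                    "tissue": tissue,
                    "mean_per_region": float(np.mean(per_region)) if per_region else 0.0,
                    "n_regions": len(per_region),
                    "values": per_region,
                }
            )
    return pd.DataFrame(rows)


def group_compare(
    a: Sequence[float],
    b: Sequence[float],
    test: str = "rank-sum",
) -> tuple[float, float, bool]:
    """Two-sided Wilcoxon rank-sum (normal approx., continuity-corrected,
    ties averaged) or Welch t-test.  Returns (statistic, p, degenerate)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0, True
    if test == "rank-sum":
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", use_continuity=True, method="asymptotic"
        )
        return float(res.statistic), float(res.pvalue), False
    if test == "t":
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue), False
    raise ValueError(f"unknown test {test!r}")
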