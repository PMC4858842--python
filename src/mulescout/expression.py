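"""Expression assignment, tissue-bias testing and recombination maps.

FPKM values are assigned to a gene only when the FPKM-bearing interval
overlaps >= 50 % of the gene length; the maximum is taken when several
intervals qualify.  Recombination rates come from a Marey map (genetic cM
vs physical bp marker positions): after automated cleaning, a local
quadratic LOESS with span 0.2 is fitted per chromosome and the local rate
is the analytic derivative of the fitted curve, clamped at >= 0.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval

FPKM_OVERLAP_FRACTION = 0.5
LOESS_SPAN = 0.2
OUTLIER_SD = 3.0
MIN_MARKERS = 10


@dataclass
class ExpressionRecord:
    gene_id: str
    tissue: str
    fpkm: float

    @property
    def expressed(self) -> bool:
        return self.fpkm > 0


@dataclass
class MareyMarker:
    marker_id: str
    chrom: str
    physical_bp: float
    genetic_cm: float
    retained: bool = True


def fpkm_from_counts(count: float, exonic_length_bp: float, library_size: float) -> float:
    """Fragments per kilobase of exon per million mapped fragments."""
    if exonic_length_bp <= 0 or library_size <= 0:
        raise ValueError("length and library size must be > 0")
    return count / ((exonic_length_bp / 1000.0) * (library_size / 1e6))


def assign_fpkm(
    gene_id: str,
    gene_interval: GenomicInterval,
    fpkm_intervals: Sequence[tuple[GenomicInterval, float]],
    tissue: str = "",
    min_overlap: float = FPKM_OVERLAP_FRACTION,
) -> ExpressionRecord:
    """Max FPKM among intervals overlapping >= 50 % of the gene length."""
    qualifying = [
        v
        for iv, v in fpkm_intervals
        if iv.overlap_len(gene_interval) >= min_overlap * len(gene_interval)
    ]
    return ExpressionRecord(gene_id, tissue, max(qualifying) if qualifying else 0.0)


def tissue_bias_test(
    gene_flags: Sequence[bool], background_flags: Sequence[bool]
) -> tuple[float, float, float]:
    """Fisher exact test of expressed-proportion difference.

    Returns (gene-set proportion, background proportion, two-sided p).
    """
    if len(gene_flags) == 0 or len(background_flags) == 0:
        raise ValueError("empty gene set")
    a = int(np.sum(gene_flags))
    b = len(gene_flags) - a
    c = int(np.sum(background_flags))
    d = len(background_flags) - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return a / len(gene_flags), c / len(background_flags), float(p)


# ---------------------------------------------------------------------------
# Marey map + LOESS recombination
# ---------------------------------------------------------------------------

def _loess_local_quadratic(
    x: np.ndarray, y: np.ndarray, x0: float, span: float, degree: int = 2
) -> tuple[float, float]:
    """Tricube-weighted local polynomial fit at x0 -> (value, derivative)."""
    n = len(x)
    m = max(degree + 2, int(np.ceil(span * n)))
    d = np.abs(x - x0)
    idx = np.argsort(d, kind="stable")[:m]
    xs, ys, ds = x[idx], y[idx], d[idx]
    dmax = ds.max()
    if dmax == 0:
        w = np.ones_like(ds)
    else:
        w = (1 - np.minimum(ds / dmax, 1.0) ** 3) ** 3
        w[w <= 0] = 1e-8
    # centred design so coefficients give value and derivative at x0 directly
    xc = xs - x0
    X = np.vander(xc, degree + 1, increasing=True)
    W = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * W[:, None], ys * W, rcond=None)
    value = coef[0]
    deriv = coef[1] if degree >= 1 else 0.0
    return float(value), float(deriv)


def loess_curve(
    x: np.ndarray, y: np.ndarray, span: float = LOESS_SPAN, degree: int = 2
):
    """Callable (value, derivative) LOESS evaluator over the marker cloud."""
    order = np.argsort(x, kind="stable")
    xs, ys = np.asarray(x, float)[order], np.asarray(y, float)[order]

    def evaluate(x0: float) -> tuple[float, float]:
        return _loess_local_quadratic(xs, ys, float(x0), span, degree)

    return evaluate


def build_marey_map(
    markers: pd.DataFrame,
    span: float = LOESS_SPAN,
    outlier_sd: float = OUTLIER_SD,
    max_iter: int = 10,
) -> list[MareyMarker]:
    """Clean a marker table into a monotone-consistent Marey map.

    ``markers`` columns: marker, chrom, cm, bp (bp = cDNA midpoint);
    optional ``n_positions`` marks multi-position markers, which are
    dropped.  Anomalous markers are removed iteratively when their
    residual from a preliminary LOESS fit exceeds ``outlier_sd`` robust
    (MAD-based) standard deviations; finally markers breaking strict
    monotonicity are dropped.
    """
    df = markers.copy()
    required = {"marker", "chrom", "cm", "bp"}
    if not required <= set(df.columns):
        raise ValueError(f"marker table needs columns {sorted(required)}")
    if "n_positions" in df.columns:
        df = df[df["n_positions"] == 1]
    multi = df["marker"].duplicated(keep=False)
    df = df[~multi]
    out: list[MareyMarker] = []
    for chrom, sub in df.groupby("chrom"):
        sub = sub.sort_values("bp", kind="stable")
        x = sub["bp"].to_numpy(float)
        y = sub["cm"].to_numpy(float)
        ids = sub["marker"].to_numpy()
        keep = np.ones(len(sub), dtype=bool)
        # drop the single worst residual per refit so one gross outlier
        # cannot drag the preliminary curve and take neighbours with it
        for _ in range(max_iter):
            if keep.sum() < MIN_MARKERS:
                break
            curve = loess_curve(x[keep], y[keep], span=span)
            resid = np.array([y[i] - curve(x[i])[0] for i in np.flatnonzero(keep)])
            centred = np.abs(resid - np.median(resid))
            mad = np.median(centred)
            rsd = 1.4826 * mad
            if rsd == 0:
                rsd = float(np.std(resid))
            # numeric floor: exactly collinear maps leave only float noise
            rsd = max(rsd, 1e-6 * (float(np.ptp(y)) + 1.0))
            worst = int(np.argmax(centred))
            if centred[worst] <= outlier_sd * rsd:
                break
            keep[np.flatnonzero(keep)[worst]] = False
        # enforce strictly increasing genetic position along bp
        run_max = -np.inf
        last_bp = -np.inf
        for i in np.flatnonzero(keep):
            if y[i] <= run_max or x[i] <= last_bp:
                keep[i] = False
            else:
                run_max, last_bp = y[i], x[i]
        if keep.sum() < MIN_MARKERS:
            raise ValueError(
                f"chromosome {chrom}: only {int(keep.sum())} markers survive cleaning"
            )
        for i in range(len(sub)):
            out.append(
                MareyMarker(str(ids[i]), str(chrom), float(x[i]), float(y[i]),
                            bool(keep[i]))
            )
    return out


def local_recombination_rate(
    marey: list[MareyMarker],
    query: GenomicInterval,
    span: float = LOESS_SPAN,
) -> tuple[float, bool]:
    """cM/Mb at the query midpoint from the LOESS derivative.

    Returns (rate, extrapolated_flag); rate is clamped at >= 0.
    """
    pts = [m for m in marey if m.retained and m.chrom == query.chrom]
    if len(pts) < MIN_MARKERS:
        raise ValueError(f"fewer than {MIN_MARKERS} markers on {query.chrom}")
    x = np.array([m.physical_bp for m in pts])
    y = np.array([m.genetic_cm for m in pts])
    mid = query.midpoint()
    extrapolated = mid < x.min() or mid > x.max()
    curve = loess_curve(x, y, span=span)
    _, deriv = curve(mid)  # cM per bp
    return max(0.0, deriv * 1e6), extrapolated
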