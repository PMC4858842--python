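"""Synthetic genomes with planted, ground-truthed MULEs.

The generator emulates a small clade of genomes that carry Mutator-like
DNA transposons: each planted element has paired terminal inverted repeats
(TIRs) in opposite orientation, a 7-11 bp target-site duplication (TSD)
immediately flanking both TIRs, and an internal sequence that is either
random (GC-controlled) or a captured slice of a donor ("parental") gene,
optionally forming an intact ORF so the element is a genic-MULE.  Elements
are assigned to branches of a species tree; every taxon descending from the
branch inherits the insertion at the orthologous position, so downstream
presence/absence dating can be scored against truth.

Sequence evolution is a Kimura two-parameter process applied recursively
down the tree (sister taxa share the substitutions of their common
ancestors).  Methylomes, 24-nt small-RNA occupancy and per-tissue
expression are simulated on top of the planted anatomy with binomial /
Poisson sampling, which makes every downstream statistic checkable against
a closed-form oracle.

Everything is reproducible from the single seed in :class:`PlantConfig`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .io import Transcript
from .phylo import DEFAULT_TREE_NEWICK, SpeciesTree
from .seqs import STOPS, encode_to_str, random_seq, revcomp, seq_to_array

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PlantConfig:
    """Parameters of the synthetic clade.

    Defaults describe the study conditions used throughout the test-suite:
    rice-like neutral rate r = 1.3e-8 substitutions/site/year, TSDs of
    7-11 bp, TIRs of 150 bp, ~50 elements per taxon on a 2 Mb chromosome.
    """

    seed: int = 0
    tree_newick: str = DEFAULT_TREE_NEWICK
    genome_length: int = 2_000_000
    chrom_name: str = "chr1"
    n_tir_families: int = 4
    tir_length: int = 150
    tsd_length_range: tuple[int, int] = (7, 11)
    internal_length_range: tuple[int, int] = (600, 1800)
    capture_fraction: float = 0.5
    chimera_fraction: float = 0.2     # of capture elements: capture >= 2 donors
    chimera_donors: int = 2           # donors per chimeric capture
    nested_te_fraction: float = 0.0   # of non-capture elements: carry a TE slice
    n_donor_genes: int = 30
    n_background_genes: int = 40
    donor_gc: float = 0.55
    internal_pad_gc: float = 0.47
    background_gc: float = 0.43
    elements_per_taxon: int = 50
    branch_insertions: Optional[dict[str, int]] = None  # overrides per-taxon default
    subst_rate: float = 1.3e-8        # r, substitutions/site/year
    ti_tv_ratio: float = 2.0
    mutate: bool = False              # evolve sequences along tree branches
    time_scale: float = 1e6           # years per unit branch length (MY)
    min_separation: int = 4000
    edge_margin: int = 3000
    max_retries: int = 3000
    tsd_mutations: int = 0            # corrupt the duplicated TSD copy (degradation)
    donor_zone: Optional[tuple[int, int]] = None       # confine donor genes
    background_zone: Optional[tuple[int, int]] = None  # confine background genes

    def __post_init__(self) -> None:
        lo, hi = self.tsd_length_range
        if not (7 <= lo <= hi <= 11):
            raise ValueError("TSD length range must lie within [7, 11]")
        if self.subst_rate <= 0:
            raise ValueError("substitution rate r must be > 0")
        if self.ti_tv_ratio <= 0:
            raise ValueError("ti:tv ratio must be > 0")


@dataclass
class TruthRecord:
    """Ground truth for one planted element in one genome."""

    element_id: str
    genome: str
    family: str
    left_tir: GenomicInterval
    internal: GenomicInterval
    right_tir: GenomicInterval
    tsd_seq: str
    origin_branch: str
    capture_donors: list[str] = field(default_factory=list)
    nested_te: Optional[GenomicInterval] = None
    transcript_id: Optional[str] = None
    element_seq: str = ""             # planted core (pre-mutation)
    methylation: dict = field(default_factory=dict)
    srna_counts: dict = field(default_factory=dict)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.left_tir.chrom, self.left_tir.start, self.right_tir.end
        )

    @property
    def tsd_length(self) -> int:
        return len(self.tsd_seq)


@dataclass
class GenomeBundle:
    """One taxon's assembly plus annotation and truth records."""

    taxon: str
    seqs: dict[str, str]
    genes: list[Transcript]
    truth: list[TruthRecord]


@dataclass
class SimulationResult:
    bundles: dict[str, GenomeBundle]
    tree: SpeciesTree
    tir_families: dict[str, str]
    te_library: dict[str, str]
    donor_gene_ids: list[str]
    config: PlantConfig


# ---------------------------------------------------------------------------
# neutral evolution (K2P process)
# ---------------------------------------------------------------------------


def evolve_sequence(
    seq: str,
    r: float,
    T_years: float,
    ti_tv_ratio: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> str:
    """Apply a K2P substitution process for ``T_years`` at rate ``r``.

    The expected number of substitution events is ``L * r * T`` (multiple
    hits at one site occur naturally), transitions being
    ``ti_tv_ratio``-fold as likely as each pair of transversions combined.
    """
    if T_years < 0:
        raise ValueError("T must be >= 0")
    if r <= 0 or ti_tv_ratio <= 0:
        raise ValueError("r and ti:tv ratio must be > 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    arr = seq_to_array(seq)
    L = arr.size
    n_events = rng.poisson(L * r * T_years)
    if n_events == 0:
        return seq
    pos = rng.integers(0, L, size=n_events)
    is_ti = rng.random(n_events) < ti_tv_ratio / (ti_tv_ratio + 1.0)
    tv_pick = rng.integers(0, 2, size=n_events)
    # apply events in rounds so repeated hits at one site compose correctly
    remaining = np.arange(n_events)
    while remaining.size:
        p = pos[remaining]
        _, first_idx = np.unique(p, return_index=True)
        batch = remaining[first_idx]
        bp = pos[batch]
        cur = arr[bp]
        # transition partner is base ^ 2 (A<->G, C<->T); transversions flip
        # purine/pyrimidine class via ^1 or ^3
        new = np.where(
            is_ti[batch], cur ^ 2, cur ^ np.where(tv_pick[batch] == 0, 1, 3)
        )
        arr[bp] = new
        mask = np.ones(remaining.size, dtype=bool)
        mask[first_idx] = False
        remaining = remaining[mask]
    return encode_to_str(arr)


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """Stop-free random coding sequence with approximately the target GC."""
    out = []
    while len(out) < n_codons:
        codon = random_seq(rng, 3, gc)
        if codon not in STOPS and codon != "ATG":
            out.append(codon)
    return "".join(out)


def _unambiguous_site(backbone: str, p: int, tsd_len: int, core: str) -> bool:
    """Reject target sites whose post-insertion junction admits a TSD call
    other than the planted one (e.g. a coincidental longer duplication)."""
    from .tsd import find_tsd

    ctx = 30
    site = backbone[p : p + tsd_len]
    left_ctx = backbone[max(0, p - ctx) : p + tsd_len]
    right_ctx = backbone[p + tsd_len : p + tsd_len + ctx]
    virtual = left_ctx + core + site + right_ctx
    ls = len(left_ctx)
    call = find_tsd(virtual, ls, ls + len(core))
    return (
        call is not None
        and call.length == tsd_len
        and call.mismatches == 0
        and call.left_offset == 0
        and call.right_offset == 0
        and call.left_seq == site
    )


@dataclass
class _Insertion:
    element_id: str
    branch: str
    backbone_pos: int
    family: str
    tsd_len: int
    core: str                       # TIR + internal + revcomp(TIR)
    tir_len: int
    capture_donors: list[str]
    orf_rel: Optional[tuple[int, int]]      # ORF span relative to core start
    nested_rel: Optional[tuple[int, int]]   # nested-TE span relative to core
    tsd_seq: str = ""                       # filled at insertion time
    tsd_right_seq: str = ""

    @property
    def added_len(self) -> int:
        return len(self.core) + self.tsd_len


class _Blocked:
    """Sorted disjoint blocked intervals for rejection sampling."""

    def __init__(self) -> None:
        self.spans: list[tuple[int, int]] = []

    def add(self, s: int, e: int) -> None:
        self.spans.append((s, e))
        self.spans.sort()

    def hits(self, s: int, e: int) -> bool:
        for bs, be in self.spans:
            if s < be and bs < e:
                return True
            if bs >= e:
                break
        return False


def simulate_genomes(config: PlantConfig) -> SimulationResult:
    """Build the clade: backbone, genes, planted elements, per-taxon genomes."""
    rng = np.random.default_rng(config.seed)
    tree = SpeciesTree.from_newick(config.tree_newick)
    L = config.genome_length
    chrom = config.chrom_name

    tir_families = {
        f"fam{i}": random_seq(rng, config.tir_length, 0.5)
        for i in range(config.n_tir_families)
    }
    te_library = {
        "teA": random_seq(rng, 400, 0.5),
        "teB": random_seq(rng, 350, 0.5),
    }

    backbone = list(random_seq(rng, L, config.background_gc))
    blocked = _Blocked()
    blocked.add(0, config.edge_margin)
    blocked.add(L - config.edge_margin, L)

    # --- genes written into the backbone -----------------------------------
    genes: list[Transcript] = []
    donor_ids: list[str] = []

    def _place_gene(
        gid: str, gc: float, zone: Optional[tuple[int, int]] = None
    ) -> Optional[Transcript]:
        n_codons = int(rng.integers(120, 260))
        cds = "ATG" + _random_cds(rng, n_codons, gc) + "TAA"
        glen = len(cds)
        zlo, zhi = zone or (config.edge_margin, L - config.edge_margin)
        zhi = min(zhi, L - config.edge_margin)
        for _ in range(config.max_retries):
            p = int(rng.integers(max(zlo, config.edge_margin), zhi - glen))
            if not blocked.hits(p - 500, p + glen + 500):
                backbone[p : p + glen] = list(cds)
                blocked.add(p - 500, p + glen + 500)
                iv = GenomicInterval(chrom, p, p + glen, "+")
                return Transcript(gid, gid, iv, exons=[iv], cds=[iv])
        return None

    for i in range(config.n_donor_genes):
        tr = _place_gene(f"donor{i}", config.donor_gc, config.donor_zone)
        if tr is not None:
            genes.append(tr)
            donor_ids.append(tr.gene_id)
    for i in range(config.n_background_genes):
        tr = _place_gene(f"bg{i}", config.background_gc, config.background_zone)
        if tr is not None:
            genes.append(tr)
    backbone_seq = "".join(backbone)
    donor_cds = {
        tr.gene_id: backbone_seq[tr.cds[0].start : tr.cds[0].end]
        for tr in genes
        if tr.gene_id in donor_ids
    }

    # --- insertion plan -----------------------------------------------------
    if config.branch_insertions is not None:
        plan = dict(config.branch_insertions)
        unknown = set(plan) - set(tree.branch_labels)
        if unknown:
            raise ValueError(f"unknown branches in insertion plan: {sorted(unknown)}")
    else:
        plan = {taxon: config.elements_per_taxon for taxon in tree.taxa}

    insertions: list[_Insertion] = []
    counter = 0
    fam_names = list(tir_families)
    # two branches conflict when they can co-occur in one genome, i.e. one
    # is ancestral to the other; only conflicting insertions must not
    # overlap on the backbone, so mutually exclusive lineages share space
    placed_spans: list[tuple[frozenset, int, int]] = []

    def _conflicts(leaves: frozenset, lo: int, hi: int, p: int, end: int) -> bool:
        # unrelated lineages may share backbone space (they never co-occur in
        # one genome) but still must not overlap, or orthologous flank
        # context would blur across elements
        margin = 200
        for other_leaves, os_, oe in placed_spans:
            related = leaves <= other_leaves or other_leaves <= leaves
            if related:
                if lo < oe and os_ < hi:
                    return True
            else:
                if p - margin < oe and os_ < end + margin:
                    return True
        return False

    for branch in tree.branches_preorder():
        for _ in range(plan.get(branch, 0)):
            eid = f"mule{counter:04d}"
            counter += 1
            fam = fam_names[int(rng.integers(0, len(fam_names)))]
            tir = tir_families[fam]
            tsd_len = int(rng.integers(*config.tsd_length_range, endpoint=True))
            inner_len = int(rng.integers(*config.internal_length_range))
            capture: list[str] = []
            orf_rel = None
            nested_rel = None
            if donor_cds and rng.random() < config.capture_fraction:
                n_donors = (
                    config.chimera_donors
                    if rng.random() < config.chimera_fraction
                    else 1
                )
                slices = []
                for _ in range(n_donors):
                    did = donor_ids[int(rng.integers(0, len(donor_ids)))]
                    while n_donors > 1 and did in capture and len(capture) < len(donor_ids):
                        did = donor_ids[int(rng.integers(0, len(donor_ids)))]
                    cds = donor_cds[did]
                    codons = (len(cds) - 6) // 3
                    # chimeric slices kept comparable in size so no single
                    # donor dominates the fused ORF
                    hi_take = 91 if n_donors > 1 else max(61, codons)
                    take = int(rng.integers(60, hi_take))
                    take = min(take, codons - 2)
                    start_codon = int(rng.integers(1, max(2, codons - take)))
                    slices.append(cds[3 + 3 * start_codon : 3 + 3 * (start_codon + take)])
                    capture.append(did)
                orf = "ATG" + "".join(slices) + "TAA"
                pad_total = max(60, inner_len - len(orf))
                lp = pad_total // 2
                left_pad = random_seq(rng, lp, config.internal_pad_gc)
                right_pad = random_seq(rng, pad_total - lp, config.internal_pad_gc)
                internal = left_pad + orf + right_pad
                orf_rel = (
                    config.tir_length + lp,
                    config.tir_length + lp + len(orf),
                )
            else:
                internal = random_seq(rng, inner_len, config.internal_pad_gc)
                if rng.random() < config.nested_te_fraction:
                    te = te_library["teA"]
                    at = int(rng.integers(50, max(51, len(internal) - len(te) - 50)))
                    internal = internal[:at] + te + internal[at:]
                    nested_rel = (config.tir_length + at, config.tir_length + at + len(te))
            core = tir + internal + revcomp(tir)
            leaves = tree.leaf_set(branch)
            for _ in range(config.max_retries):
                p = int(rng.integers(config.edge_margin, L - config.edge_margin))
                lo = p - config.min_separation
                hi = p + len(core) + config.min_separation
                if blocked.hits(lo, hi) or _conflicts(
                    leaves, lo, hi, p, p + len(core)
                ):
                    continue
                if not _unambiguous_site(backbone_seq, p, tsd_len, core):
                    continue
                placed_spans.append((leaves, p, p + len(core)))
                break
            else:
                raise RuntimeError(
                    "could not place insertion after retries; genome too crowded"
                )
            insertions.append(
                _Insertion(
                    element_id=eid,
                    branch=branch,
                    backbone_pos=p,
                    family=fam,
                    tsd_len=tsd_len,
                    core=core,
                    tir_len=config.tir_length,
                    capture_donors=capture,
                    orf_rel=orf_rel,
                    nested_rel=nested_rel,
                )
            )

    ins_by_branch: dict[str, list[_Insertion]] = {}
    for ins in insertions:
        ins_by_branch.setdefault(ins.branch, []).append(ins)

    # --- recursive growth down the tree -------------------------------------
    bundles: dict[str, GenomeBundle] = {}
    mut_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    tsd_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))

    def _cur_coord(p: int, placed: list[_Insertion]) -> int:
        return p + sum(i.added_len for i in placed if i.backbone_pos < p)

    def _corrupt(s: str) -> str:
        if config.tsd_mutations <= 0 or not s:
            return s
        chars = list(s)
        for _ in range(config.tsd_mutations):
            i = int(tsd_rng.integers(0, len(chars)))
            chars[i] = "ACGT"[int(tsd_rng.integers(0, 4))]
        return "".join(chars)

    def _grow(node, seq: str, placed: list[_Insertion]) -> None:
        label = node.taxon.label if node.is_leaf() else node.label
        edge_len = node.edge.length or 0.0
        if config.mutate and node.parent_node is not None and edge_len > 0:
            seq = evolve_sequence(
                seq,
                config.subst_rate,
                edge_len * config.time_scale,
                config.ti_tv_ratio,
                mut_rng,
            )
        new_placed = list(placed)
        for ins in sorted(
            ins_by_branch.get(label, []), key=lambda i: -i.backbone_pos
        ):
            cp = _cur_coord(ins.backbone_pos, new_placed)
            site = seq[cp : cp + ins.tsd_len]
            ins.tsd_seq = site
            ins.tsd_right_seq = _corrupt(site)
            seq = (
                seq[: cp + ins.tsd_len]
                + ins.core
                + ins.tsd_right_seq
                + seq[cp + ins.tsd_len :]
            )
            new_placed.append(ins)
        if node.is_leaf():
            bundles[label] = _emit_leaf(label, seq, new_placed)
        else:
            for child in node.child_nodes():
                _grow(child, seq, new_placed)

    def _emit_leaf(taxon: str, seq: str, placed: list[_Insertion]) -> GenomeBundle:
        truth: list[TruthRecord] = []
        leaf_genes: list[Transcript] = []
        for tr in genes:
            off = sum(
                i.added_len for i in placed if i.backbone_pos < tr.interval.start
            )
            iv = GenomicInterval(
                chrom, tr.interval.start + off, tr.interval.end + off, "+"
            )
            leaf_genes.append(
                Transcript(tr.transcript_id, tr.gene_id, iv, exons=[iv], cds=[iv])
            )
        for ins in sorted(placed, key=lambda i: i.backbone_pos):
            s0 = _cur_coord(ins.backbone_pos, [i for i in placed if i is not ins])
            core_start = s0 + ins.tsd_len
            lt = GenomicInterval(chrom, core_start, core_start + ins.tir_len)
            internal = GenomicInterval(
                chrom, lt.end, core_start + len(ins.core) - ins.tir_len
            )
            rt = GenomicInterval(chrom, internal.end, core_start + len(ins.core))
            tid = None
            if ins.orf_rel is not None:
                tid = f"{ins.element_id}_gene"
                os_, oe = ins.orf_rel
                giv = GenomicInterval(chrom, core_start + os_, core_start + oe, "+")
                leaf_genes.append(Transcript(tid, tid, giv, exons=[giv], cds=[giv]))
            nested = None
            if ins.nested_rel is not None:
                ns, ne = ins.nested_rel
                nested = GenomicInterval(chrom, core_start + ns, core_start + ne)
            truth.append(
                TruthRecord(
                    element_id=ins.element_id,
                    genome=taxon,
                    family=ins.family,
                    left_tir=lt,
                    internal=internal,
                    right_tir=rt,
                    tsd_seq=ins.tsd_seq,
                    origin_branch=ins.branch,
                    capture_donors=list(ins.capture_donors),
                    nested_te=nested,
                    transcript_id=tid,
                    element_seq=ins.core,
                )
            )
        leaf_genes.sort(key=lambda t: t.interval.start)
        return GenomeBundle(taxon, {chrom: seq}, leaf_genes, truth)

    root = tree._tree.seed_node
    _grow(root, backbone_seq, [])

    return SimulationResult(
        bundles=bundles,
        tree=tree,
        tir_families=tir_families,
        te_library=te_library,
        donor_gene_ids=donor_ids,
        config=config,
    )


# ---------------------------------------------------------------------------
# methylome simulation
# ---------------------------------------------------------------------------


def cytosine_sites(seq: str, chrom: str) -> pd.DataFrame:
    """All cytosines (both strands) with their CG/CHG/CHH context."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    pad = np.concatenate([arr, np.array([b"N", b"N"], dtype="S1")])
    frames = []
    # plus strand: C followed by G (CG), C-H-G (CHG), else CHH
    c_pos = np.flatnonzero(arr == b"C")
    n1 = pad[c_pos + 1] == b"G"
    n2 = pad[c_pos + 2] == b"G"
    ctx_p = np.where(n1, "CG", np.where(n2, "CHG", "CHH"))
    frames.append(
        pd.DataFrame({"chrom": chrom, "pos": c_pos, "strand": "+", "context": ctx_p})
    )
    # minus strand: G preceded (on +) by C mirrors the same contexts
    lpad = np.concatenate([np.array([b"N", b"N"], dtype="S1"), arr])
    g_pos = np.flatnonzero(arr == b"G")
    m1 = lpad[g_pos + 1] == b"C"   # base at g_pos-1
    m2 = lpad[g_pos] == b"C"       # base at g_pos-2
    ctx_m = np.where(m1, "CG", np.where(m2, "CHG", "CHH"))
    frames.append(
        pd.DataFrame({"chrom": chrom, "pos": g_pos, "strand": "-", "context": ctx_m})
    )
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def simulate_methylome(
    genome: dict[str, str],
    regions: list[tuple[GenomicInterval, dict[str, float]]],
    background_levels: Optional[dict[str, float]] = None,
    depth_mean: float = 10.0,
    seed: int = 0,
    regions_only: bool = False,
) -> pd.DataFrame:
    """Binomially sampled per-cytosine calls.

    ``regions`` pairs intervals with per-context target levels; later
    entries win on overlap.  With ``regions_only`` cytosines outside every
    region are skipped (keeps large-genome fixtures small).
    """
    bg = background_levels or {"CG": 0.05, "CHG": 0.03, "CHH": 0.02}
    for _, levels in regions:
        for v in levels.values():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"methylation level {v} outside [0, 1]")
    rng = np.random.default_rng(seed)
    frames = []
    for chrom, seq in genome.items():
        chrom_regions = [(iv, lv) for iv, lv in regions if iv.chrom == chrom]
        if regions_only and not chrom_regions:
            continue
        if regions_only:
            from .intervals import merge_intervals

            keep = merge_intervals([iv for iv, _ in chrom_regions])
            parts = []
            for kv in keep:
                sub = cytosine_sites(seq[kv.start : kv.end], chrom)
                sub["pos"] += kv.start
                # context near slice edges recomputed from full sequence
                parts.append(sub)
            sites = pd.concat(parts, ignore_index=True) if parts else None
            if sites is None:
                continue
        else:
            sites = cytosine_sites(seq, chrom)
        level = np.array(
            [bg.get(c, 0.0) for c in sites["context"]], dtype=float
        )
        pos = sites["pos"].to_numpy()
        for iv, lv in chrom_regions:
            mask = (pos >= iv.start) & (pos < iv.end)
            for ctx, val in lv.items():
                level[mask & (sites["context"] == ctx).to_numpy()] = val
        depth = rng.poisson(depth_mean, size=len(sites))
        meth = rng.binomial(depth, level)
        out = sites.copy()
        out["total"] = depth
        out["meth"] = meth
        frames.append(out[out["total"] > 0])
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "pos", "strand", "context", "total", "meth"]
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# small RNA + expression simulation
# ---------------------------------------------------------------------------


@dataclass
class OmicsProfiles:
    """Planted per-age-group signal strengths for sRNA and expression."""

    srna_mean_by_group: dict[str, float] = field(
        default_factory=lambda: {"Asian": 30.0, "AA": 15.0, "AB": 6.0, "other": 6.0,
                                 "species-specific": 40.0}
    )
    multi_map_fraction: float = 0.2
    tissues: tuple[str, ...] = ("leaf", "root", "panicle", "pollen")
    expressed_prob: dict[str, float] = field(
        default_factory=lambda: {"leaf": 0.4, "root": 0.4, "panicle": 0.4, "pollen": 0.3}
    )
    young_pollen_prob: float = 0.65   # pollen-expression probability, young genes
    fpkm_mean: float = 8.0


def simulate_srna_and_expression(
    bundle: GenomeBundle,
    age_group_of: dict[str, str],
    profiles: OmicsProfiles | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """24-nt sRNA occupancy table + per-gene per-tissue FPKM table.

    ``age_group_of`` maps element id -> age-group label; sRNA abundance per
    element region is Poisson with the group's planted mean; 'young'
    (Asian / species-specific) element-derived genes get pollen-biased
    expression.
    """
    prof = profiles or OmicsProfiles()
    rng = np.random.default_rng(seed)
    srna_rows = []
    for tr in bundle.truth:
        group = age_group_of.get(tr.element_id, "other")
        mean = prof.srna_mean_by_group.get(group, 5.0)
        for part, iv in (("tir", tr.left_tir), ("internal", tr.internal),
                         ("tir", tr.right_tir)):
            n_species = rng.poisson(max(mean / 4.0, 0.0))
            for _ in range(n_species):
                if len(iv) <= 24:
                    continue
                s = int(rng.integers(iv.start, iv.end - 24))
                abundance = 1 + rng.poisson(mean / max(n_species, 1))
                nloc = 2 if rng.random() < prof.multi_map_fraction else 1
                srna_rows.append(
                    (iv.chrom, s, s + 24, 24, int(abundance), nloc, tr.element_id, part)
                )
            # a little 21-nt noise so length filtering is exercised
            if rng.random() < 0.3:
                s = int(rng.integers(iv.start, max(iv.start + 1, iv.end - 21)))
                srna_rows.append((iv.chrom, s, s + 21, 21, 1, 1, tr.element_id, part))
    srna = pd.DataFrame(
        srna_rows,
        columns=["chrom", "start", "end", "length", "abundance",
                 "n_locations", "element_id", "part"],
    )

    young = {"Asian", "species-specific"}
    mule_gene_group = {
        tr.transcript_id: age_group_of.get(tr.element_id, "other")
        for tr in bundle.truth
        if tr.transcript_id
    }
    expr_rows = []
    for tr in bundle.genes:
        for tissue in prof.tissues:
            p = prof.expressed_prob.get(tissue, 0.4)
            if (
                tissue == "pollen"
                and mule_gene_group.get(tr.transcript_id) in young
            ):
                p = prof.young_pollen_prob
            fpkm = float(rng.exponential(prof.fpkm_mean)) if rng.random() < p else 0.0
            expr_rows.append(
                (
                    tr.gene_id,
                    tissue,
                    tr.interval.chrom,
                    tr.interval.start,
                    tr.interval.end,
                    fpkm,
                )
            )
    expr = pd.DataFrame(
        expr_rows, columns=["gene_id", "tissue", "chrom", "start", "end", "fpkm"]
    )
    return srna, expr


def default_methylome_regions(
    bundle: GenomeBundle,
    age_group_of: dict[str, str],
    flank: int = 500,
) -> list[tuple[GenomicInterval, dict[str, float]]]:
    """Planted methylation anatomy with the canonical age trends.

    Internal-region levels rise with element age in all contexts; TIR CHH
    levels fall with age; donor ("parental") gene bodies are hypomethylated
    relative to background gene bodies.
    """
    internal_levels = {
        "Asian": {"CG": 0.40, "CHG": 0.30, "CHH": 0.10},
        "species-specific": {"CG": 0.35, "CHG": 0.25, "CHH": 0.08},
        "AA": {"CG": 0.55, "CHG": 0.45, "CHH": 0.15},
        "AB": {"CG": 0.70, "CHG": 0.60, "CHH": 0.20},
        "other": {"CG": 0.70, "CHG": 0.60, "CHH": 0.20},
    }
    tir_chh = {"Asian": 0.30, "species-specific": 0.32, "AA": 0.20,
               "AB": 0.12, "other": 0.12}
    regions: list[tuple[GenomicInterval, dict[str, float]]] = []
    chrom_len = {c: len(s) for c, s in bundle.seqs.items()}
    for tr in bundle.genes:
        body = {"CG": 0.05, "CHG": 0.03, "CHH": 0.02} if tr.gene_id.startswith(
            "donor"
        ) else {"CG": 0.30, "CHG": 0.10, "CHH": 0.05}
        if tr.gene_id.startswith(("donor", "bg")):
            regions.append((tr.interval, body))
    for t in bundle.truth:
        group = age_group_of.get(t.element_id, "other")
        span = t.span.expanded(flank, chrom_len[t.span.chrom])
        regions.append((span, {"CG": 0.08, "CHG": 0.05, "CHH": 0.03}))
        for tir in (t.left_tir, t.right_tir):
            regions.append((tir, {"CG": 0.50, "CHG": 0.40, "CHH": tir_chh[group]}))
        regions.append((t.internal, internal_levels[group]))
    return regions
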