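"""Cross-species presence/absence, Dollo origin assignment and age groups.

Presence of an element in another genome requires both an identity
criterion (best hit of the element sequence covering >= 30 % of its
length) and a synteny criterion built from four flanking probes
(1 bp-1 kb and 1-2 kb, up- and downstream).  Origins are assigned under
Dollo parsimony (single gain, losses allowed): the origin branch is the
branch above the MRCA of the presence set.  Age groups follow the
default clade map: branches inside the Asian crown clade are "Asian",
the stem of the AA clade is "AA", the stem of the AA+BB clade is "AB".
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio import Align

from .intervals import GenomicInterval

from .phylo import (
    DEFAULT_AA_TAXA,
    DEFAULT_ASIAN_TAXA,
    DEFAULT_BB_TAXA,
    SpeciesTree,
)
from .scan import best_hits
from .seqs import find_orfs, translate

MIN_PRESENCE_COVERAGE = 0.30
SYNTENY_WINDOW = 4000
PEPTIDE_MIN_IDENTITY = 0.40
PEPTIDE_MIN_COVERAGE = 0.50


@dataclass
class ProbeSet:
    """Element sequence plus its four flanking probes from the home genome."""

    element_id: str
    home_chrom: str
    element_seq: str
    flanks: dict[str, str] = field(default_factory=dict)
    truncated: bool = False  # element at contig edge: some probes missing


@dataclass
class PresenceEvidence:
    identity_pass: bool
    synteny_pass: bool
    n_flanks_near: int
    coverage: float
    flagged: bool = False


@dataclass
class PresenceProfile:
    element_id: str
    taxa: list[str]
    flags: list[bool]
    evidence: dict[str, PresenceEvidence] = field(default_factory=dict)
    origin_branch: Optional[str] = None
    age_group: Optional[str] = None
    losses_flagged: bool = False

    @property
    def present_taxa(self) -> list[str]:
        return [t for t, f in zip(self.taxa, self.flags) if f]


def make_probes(
    element_id: str,
    span: GenomicInterval,
    genome: dict[str, str],
) -> ProbeSet:
    """Cut the element and its 1 bp-1 kb / 1-2 kb flank probes."""
    seq = genome[span.chrom]
    L = len(seq)
    flanks: dict[str, str] = {}
    truncated = False
    windows = {
        "up2": (span.start - 2000, span.start - 1000),
        "up1": (span.start - 1000, span.start),
        "down1": (span.end, span.end + 1000),
        "down2": (span.end + 1000, span.end + 2000),
    }
    for name, (s, e) in windows.items():
        s2, e2 = max(0, s), min(L, e)
        if e2 - s2 < 200:
            truncated = True
            continue
        flanks[name] = seq[s2:e2]
    return ProbeSet(element_id, span.chrom, seq[span.start : span.end], flanks, truncated)


def assess_presence(
    probes: ProbeSet,
    target_genome: dict[str, str],
    min_coverage: float = MIN_PRESENCE_COVERAGE,
    synteny_window: int = SYNTENY_WINDOW,
    min_identity: float = 0.6,
) -> tuple[bool, PresenceEvidence]:
    """Identity + synteny presence call of one element in one genome.

    Synteny passes when (a) the element's best hit lies on the home
    chromosome (conserved chromosome naming) with >= 1 flank best-hit
    within 4 kb of it, or (b) >= 2 flank best-hits lie within 4 kb.
    """
    queries = {"element": probes.element_seq}
    for name, seq in probes.flanks.items():
        queries[name] = seq
    hits = best_hits(
        queries, target_genome, min_identity=min_identity, min_coverage=0.0
    )
    el_hit = hits.get("element")
    if el_hit is None:
        ev = PresenceEvidence(False, False, 0, 0.0, probes.truncated)
        return False, ev
    coverage = el_hit.query_coverage
    identity_pass = coverage >= min_coverage
    n_near = 0
    for name in probes.flanks:
        fh = hits.get(name)
        if fh is None or fh.subject.chrom != el_hit.subject.chrom:
            continue
        if fh.subject.distance_to(el_hit.subject) <= synteny_window:
            n_near += 1
    rule_a = el_hit.subject.chrom == probes.home_chrom and n_near >= 1
    rule_b = n_near >= 2
    synteny_pass = rule_a or rule_b
    ev = PresenceEvidence(
        identity_pass, synteny_pass, n_near, coverage, probes.truncated
    )
    return identity_pass and synteny_pass, ev


def build_presence_profile(
    element_id: str,
    home_taxon: str,
    probes: ProbeSet,
    genomes: dict[str, dict[str, str]],
    tree: SpeciesTree,
    **kw,
) -> PresenceProfile:
    """Probe every other genome; the home taxon is present by construction."""
    taxa = tree.taxa
    flags = []
    evidence = {}
    for taxon in taxa:
        if taxon == home_taxon:
            flags.append(True)
            continue
        present, ev = assess_presence(probes, genomes[taxon].seqs
                                      if hasattr(genomes[taxon], "seqs")
                                      else genomes[taxon], **kw)
        flags.append(present)
        evidence[taxon] = ev
    return PresenceProfile(element_id, list(taxa), flags, evidence)


def assign_origin_branch(profile: PresenceProfile, tree: SpeciesTree) -> str:
    """Dollo single-gain origin: branch above the MRCA of the presence set.

    Absences inside the implied clade are interpreted as losses and
    flagged on the profile.
    """
    present = profile.present_taxa
    if not present:
        raise ValueError("all-absent profile has no origin branch")
    branch = tree.mrca_branch(present)
    profile.origin_branch = branch
    profile.losses_flagged = set(present) != set(tree.leaf_set(branch))
    profile.age_group = age_group_for_profile(profile, tree)
    return branch


def classify_age_group(
    branch: str,
    tree: SpeciesTree,
    asian_taxa: frozenset[str] = DEFAULT_ASIAN_TAXA,
    aa_taxa: frozenset[str] = DEFAULT_AA_TAXA,
    bb_taxa: frozenset[str] = DEFAULT_BB_TAXA,
) -> str:
    """Asian / AA / AB / other, by branch position in the clade map."""
    leaves = tree.leaf_set(branch)  # KeyError for unknown labels
    avail = set(tree.taxa)
    asian = asian_taxa & avail
    aa = aa_taxa & avail
    aabb = (aa_taxa | bb_taxa) & avail
    if asian and leaves <= asian:
        return "Asian"
    if aa and leaves == frozenset(aa):
        return "AA"
    if aabb and leaves == frozenset(aabb):
        return "AB"
    return "other"


def age_group_for_profile(profile: PresenceProfile, tree: SpeciesTree) -> str:
    present = profile.present_taxa
    if len(present) == 1:
        return "species-specific"
    branch = profile.origin_branch or tree.mrca_branch(present)
    return classify_age_group(branch, tree)


#: truth-side helper: group label for an element planted on a given branch
def age_group_for_branch(branch: str, tree: SpeciesTree) -> str:
    if tree.is_terminal(branch):
        return "species-specific"
    return classify_age_group(branch, tree)


# ---------------------------------------------------------------------------
# species-specific MULE-derived genes
# ---------------------------------------------------------------------------

_aligner = Align.PairwiseAligner()
_aligner.mode = "local"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -0.5


def peptide_similarity(query: str, target: str) -> tuple[float, float]:
    """(identity within aligned span, aligned fraction of the query)."""
    if not query or not target:
        return 0.0, 0.0
    aln = _aligner.align(query, target)
    if len(aln) == 0:
        return 0.0, 0.0
    best = aln[0]
    a, b = best[0], best[1]
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    cols = sum(1 for x, y in zip(a, b) if x != "-" or y != "-")
    q_span = sum(1 for x in a if x != "-")
    if cols == 0:
        return 0.0, 0.0
    return matches / cols, q_span / len(query)


def gene_present_in_taxon(
    gene_seq: str,
    peptide: str,
    target_genome: dict[str, str],
    min_identity: float = 0.6,
    orf_min_len: int = 150,
) -> bool:
    """Presence of a MULE-derived gene in one other taxon.

    The gene sequence is mapped to the target genome; the best-hit region
    is re-annotated with a six-frame ORF scan and the gene's peptide is
    compared with every ORF peptide (>= 40 % identity over >= 50 % of the
    query peptide).  No genomic hit anywhere means absent.
    """
    hits = best_hits({"g": gene_seq}, target_genome, min_identity=min_identity)
    hit = hits.get("g")
    if hit is None:
        return False
    chrom_seq = target_genome[hit.subject.chrom]
    pad = 500
    region = chrom_seq[
        max(0, hit.subject.start - pad) : min(len(chrom_seq), hit.subject.end + pad)
    ]
    for s, e, strand in find_orfs(region, min_len=orf_min_len):
        orf = region[s:e]
        if strand == "-":
            from .seqs import revcomp

            orf = revcomp(orf)
        pep = translate(orf).rstrip("*")
        ident, cov = peptide_similarity(peptide, pep)
        if ident >= PEPTIDE_MIN_IDENTITY and cov >= PEPTIDE_MIN_COVERAGE:
            return True
    return False


def species_specific_gene(
    gene_seq: str,
    peptide: str,
    home_taxon: str,
    genomes: dict[str, dict[str, str]],
    **kw,
) -> tuple[bool, dict[str, bool]]:
    """True iff the gene is absent from every other taxon."""
    presence = {}
    for taxon, genome in genomes.items():
        if taxon == home_taxon:
            continue
        presence[taxon] = gene_present_in_taxon(gene_seq, peptide, genome, **kw)
    return not any(presence.values()), presence


def origination_rate(n_species_specific: int, divergence_my: float) -> float:
    """New genes per million years: count / divergence time."""
    if divergence_my <= 0:
        raise ValueError("divergence time must be > 0")
    return n_species_specific / divergence_my
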