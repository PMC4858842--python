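# Methods

`mulescout` re-implements, as a tested library and CLI, a complete analysis
pipeline for non-autonomous Mutator-like transposable elements (MULEs):
discovery from terminal-inverted-repeat (TIR) evidence, classification into
genic and nongenic elements, cross-species presence/absence dating on a
species tree, molecular-evolution statistics, and epigenomic/expression
profiling. Because the genome-scale inputs such an analysis normally
consumes are large external datasets, the package ships a first-class
synthetic-genome generator that plants elements with full ground truth, so
every stage of the pipeline is verifiable end to end.

## Element model and calling rules

A complete non-autonomous MULE is modelled as

```
TSD  [left TIR]  internal sequence  [right TIR (reverse complement)]  TSD
```

with a 7–11 bp target-site duplication (TSD) immediately outside both TIRs.
Calling proceeds from per-family TIR hits (imported RepeatMasker/BLAST
tables, or the internal k-mer-seeded scan on synthetic genomes):

- two hits pair into an element when they share a family, lie in opposite
  orientations, and their inner edges are less than 20 kb apart;
- a valid TSD must flank the pair: all lengths 7–11 and all offsets within
  ±10 bp of the putative TIR ends are searched, and the two copies must
  agree within the length-dependent allowance (0 mismatches/indels for
  7 bp, 1 for 8 bp, 2 for 9–11 bp). "Mismatches/indels" is implemented as
  Levenshtein distance with unit costs. Ties break on fewest mismatches,
  then longest TSD, then smallest total offset. Candidate copies may not
  overlap each other.
- elements overlapping a transposase hit (E < 1e-9 for imported tables;
  an identity ≥ 80 % / coverage ≥ 50 % proxy when the table carries no
  E-values, e.g. PSL) are autonomous and drop out of all downstream sets;
- a non-autonomous element is *genic* when a transcript with ≥ 150 bp of
  coding sequence — intact ATG start, stop codon, no internal stop — and no
  transposase overlap covers ≥ 30 % of its own transcript length (sum of
  exon lengths, not genomic span) inside the element. Such transcripts are
  the MULE-derived putative genes.

Candidate TIR families are accepted only with ≥ 20 genomic copies, < 30 %
of the consensus masked by known non-MULE repeats, and ≥ 5 TSD-validated
paired elements.

Pairing is a deterministic greedy left-to-right sweep taking the nearest
valid partner first, and a TIR hit joins at most one element; the source
data do not dictate a conflict-resolution rule, so determinism was the
deciding criterion. Distance is measured between inner edges
(configurable).

## Parental tracing

MULE-derived genes are mapped back to their own genome after masking
non-MULE repeat content (replaced by N). Surviving hits are parental
candidates unless they overlap an annotated TE (≥ 1 bp), have a MULE TIR
within 500 bp on either side (the flanking window is not externally fixed;
500 bp is the package default and configurable), or coincide with the
gene's own locus (≥ 50 % reciprocal overlap). Among survivors passing
E < 1e-10 (or the identity filter for internal scans), the highest-identity
hit(s) are the parental sequence(s); annotated genes overlapping them are
the parental genes, and ≥ 2 distinct parental genes flag a chimera.

## Presence/absence and Dollo dating

For each element, the element sequence plus four flank probes (1 bp–1 kb
and 1–2 kb, up- and downstream) are searched against every other genome.
Presence requires the identity criterion (best hit covering ≥ 30 % of the
element length) *and* a synteny criterion: either the best element hit lies
on the home chromosome with ≥ 1 flank best-hit within 4 kb (closest edges),
or ≥ 2 flank best-hits lie within 4 kb.

Origins follow Dollo parsimony (single gain, unlimited losses): the origin
branch is the branch above the MRCA of the presence set; absences inside
that clade are flagged as losses. A consequence worth stating explicitly:
simulated losses can only shrink the presence set, so the inferred origin
is never *older* than the truth — it stays within the true clade and may
move toward the leaves when every taxon of a subclade loses the element.

The default 11-taxon tree mirrors a rice-like phylogeny (ages in MY,
ultrametric): an Asian crown clade of four taxa (crown 0.8 MY), an
AA-genome clade (crown 2.5 MY), a BB outgroup splitting 6.8 MY ago, a
distant outgroup at 26 MY and an outgroup genus at 30 MY. Age groups map
branches to the field's labels: any branch inside the Asian crown clade is
"Asian" (< 0.8 MY), the AA-clade stem (2.5–6.8 MY) is "AA", the stem of
the AA+BB clade (6.8–26 MY) is "AB", single-taxon presence is
species-specific, everything else "other".

Species-specificity of a MULE-derived gene probes each other genome with
the gene sequence; the best-hit region is re-annotated with a six-frame ORF
scan (≥ 150 bp, intact start/stop — this replaces an external gene-finder
binary) and the gene's peptide is compared against every ORF peptide
(≥ 40 % identity over ≥ 50 % of the query when no E-value is available).
Note that a gene captured intact from a single parental locus is
legitimately detected as "present" in other taxa through that parental
locus; clean species-specific calls therefore arise for chimeric captures,
whose per-donor peptide coverage falls below the 50 % rule. The
origination rate is simply count / divergence time (genes per MY).

## Divergence, dating and selection

Each element is paired with its best-scoring non-self paralog of the same
TIR family (ties break to the lexicographically smaller id). Divergence k
comes from the Kimura two-parameter closed form

    k = 1/2 ln(1/(1-2P-Q)) + 1/4 ln(1/(1-2Q))

on gap-free aligned columns, and the amplification time is T = k/(2r) with
the rice-calibrated neutral rate r = 1.3e-8 substitutions/site/year
(configurable). Saturated pairs (log argument ≤ 0) are reported undefined
rather than clamped.

Selection is tested with Nei–Gojobori (1986) counting: synonymous and
nonsynonymous sites averaged over the two sequences (changes to stop
codons count as nonsynonymous), multi-substitution codons averaged over
substitution pathways (pathways through stops excluded), Jukes–Cantor
correction of the proportions, and a two-sided normal test on Ka − Ks
using the NG86 large-sample variances. Before counting, the CDS is
globally aligned to the partner and every CDS codon whose bases do not
align 3-to-3 (frameshifts) or whose column contains a premature stop is
removed pairwise; fewer than 30 surviving codons is untestable. Multiple
testing is controlled with Benjamini–Hochberg (no tuning parameter), and
calls are made at q ≤ 0.05: purifying (Ka < Ks), positive (Ka > Ks),
neutral otherwise. These closed-form estimators deliberately replace ML
machinery (baseml/codeml likelihood-ratio tests); the CLI output labels
them as such so results cannot be mistaken for ML estimates. The in-package
NG86 implementation is cross-checked in the test-suite against Biopython's
independent implementation.

One calibration note: NG86 Ka/Ks equals 1 under *uniform* substitution
(every target base equally likely, ti:tv = 0.5). A transition-biased
neutral process (ti:tv = 2) yields Ka/Ks < 1 without any selection,
because transitions at third positions are disproportionately synonymous —
the neutrality sanity checks therefore use the uniform process.

## Methylation, TE content, TIR similarity, sRNA

Per-region methylation uses only cytosines covered by ≥ 3 reads (the
robustness checks at ≥ 5 and ≥ 7 are a config knob) and is undefined
unless ≥ 50 % of the region's cytosines of that context are mapped; a
region with no cytosines of the context is flagged distinctly. The level
itself is read-weighted pooling (Σ methylated / Σ total over mapped
sites) by default — the standard choice for bisulfite region summaries —
with a site-binary mode (site methylated iff ≥ 1 methylated read) exposed
because both conventions occur in the literature.

Meta-profiles over element anatomy bin 500-bp flanks into fixed 50-bp
windows and length-normalise TIRs and internals into 10 and 20
proportional bins (the bin scheme is a package choice); per-bin values are
means of defined per-element levels, flagged when < 10 elements
contribute.

TE content of an internal region is the union length of overlapping
non-MULE repeat hits divided by the internal length. TIR similarity
reverse-complements the right TIR onto the left orientation, aligns
globally (match 1, mismatch −1, gap open −2, extend −0.5) and reports
identical aligned bases divided by the *left* TIR length.

24-nt sRNA occupancy filters records to the requested read length and, by
default, to reads mapping to exactly one genomic location; a record counts
toward a region it overlaps. Summed read abundance is the default measure,
with a distinct-species mode also reported since either reading of
"number of small RNAs" is defensible. Group comparisons use the Wilcoxon
rank-sum test (normal approximation, continuity-corrected, ties averaged)
or Welch's t-test; a fully degenerate comparison returns p = 1 with a
flag.

## Expression and recombination

FPKM = count / ((exon-kb) · (library/1e6)). An FPKM-bearing interval is
assigned to a gene only when it overlaps ≥ 50 % of the gene length; when
several intervals qualify the maximum is taken (conservative and
deterministic; summing would double-count overlapping segments).
Expressed means FPKM > 0, and tissue bias is a two-sided Fisher exact test
of expressed proportions against a background gene set.

The Marey map takes markers with genetic (cM) and physical (bp, cDNA
midpoint) positions, drops markers with multiple genomic positions, and
replaces manual outlier inspection with an explicit rule: iteratively
remove the single worst marker whose residual from a preliminary LOESS fit
exceeds 3 robust (MAD-based) SDs, then drop any marker breaking strict
monotonicity. Fewer than 10 surviving markers on a chromosome is an
error. The recombination rate is the analytic derivative (from the local
quadratic coefficients, not finite differences) of a tricube-weighted
local quadratic LOESS with span 0.2, clamped at ≥ 0, in cM/Mb; queries
outside the marker range are flagged as extrapolation.

## The synthetic clade

`simulate_genomes` builds one ancestral backbone chromosome, writes donor
(GC 0.55) and background (GC 0.43) gene CDSs into it, and plants elements
on chosen branches of the species tree. Each element takes a family
consensus TIR (default 150 bp), a TSD length drawn from 7–11, and an
internal sequence that is random GC-controlled (0.47), carries a nested
non-MULE TE slice, or captures one or more donor-CDS slices fused into an
intact ORF (the planted MULE-derived gene). Genomes grow recursively down
the tree so sister taxa share ancestral state; insertions duplicate the
current target site, and every coordinate is recorded per leaf as a truth
record. Optional K2P evolution (ti:tv 2.0 by default, rate r, branch
lengths in MY) runs along each branch; indels are not simulated, which is
what makes "exact boundary" assertions meaningful. Insertion sites are
rejection-sampled away from genes and from other insertions on the same
root-to-leaf path (4 kb default separation, so flank probes stay clean),
while mutually exclusive lineages may share backbone space; a site whose
post-insertion junction would admit a TSD call other than the planted one
(e.g. a coincidental longer duplication) is re-drawn, so planted TSDs are
unambiguous by construction.

Methylomes are binomial: per-cytosine depth ~ Poisson (default mean 10),
methylated reads ~ Binomial(depth, level), with levels set per region and
context. The default anatomy plants the canonical trends: internal-region
levels rising with element age, TIR CHH levels falling with age, donor
gene bodies hypomethylated relative to background gene bodies. sRNA tables
draw 24-nt records per element region with Poisson abundance decreasing
with age plus 21-nt noise and a configurable multi-mapping fraction;
expression tables draw per-tissue FPKM with pollen-biased expression
probability for young-element genes. All sampling flows from the single
config seed.

What the generator does *not* emulate — read-level sequencing error,
indel-rich evolution, segmental duplication, selection, population
structure — bounds what passing tests show: they validate the rules and
estimators against a model in which those rules are exactly true, not the
pipeline's robustness to messy real genomes.

## Problem sizes and numerical choices

The test-suite and the acceptance script run, by choice, at desk scale:
element calling on 2 Mb × 11 taxa with 50 elements per taxon; origin
recovery with 2 elements on each of the 21 branches of a 400-kb clade;
dating on 50-kb ancestor/descendant pairs at planted ages 0.5/2/6 MY;
neutrality over 120–200 replicate 400-codon CDSs; the end-to-end profile
study on one 3.2-Mb genome with 100 elements per age group and 100 genes
per control set. The internal similarity search is k-mer-seeded (k = 13,
step 5, diagonal clustering, edlib verification, default ≥ 80 % identity
over ≥ 80 % of the query for TIR scans; presence assessment relaxes
identity to 60 % and evaluates coverage explicitly). Edit distances use
edlib; pairwise alignments Biopython's PairwiseAligner; trees dendropy;
statistics scipy/statsmodels.

## Known limitations

- The greedy nearest-partner pairing can in principle mis-pair interleaved
  same-family elements; planted elements are spaced, so the suite does not
  exercise that regime.
- Presence assessment assumes conserved chromosome naming for synteny rule
  (a); rule (b) (two near flanks) covers renamed assemblies.
- NG86 + normal approximation is less powerful than codeml's LRT for weak
  selection; q-values are BH, not Storey's estimator.
- The LOESS span (0.2) follows the stated setting; cross-validated span
  selection is exposed but off by default, and rates within half a window
  of a sharp rate change are smoothed.
- Single-donor captures are indistinguishable from their parental locus in
  cross-species gene-presence checks (see above); this mirrors the
  underlying procedure rather than a bug.
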