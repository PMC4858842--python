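# mulescout

Discovery, classification, cross-species dating and epigenomic profiling of
**Mutator-like transposable elements (MULEs)** — the class II cut-and-paste
DNA transposons whose non-autonomous derivatives ("Pack-MULEs") capture host
gene fragments and seed new genes in plant genomes.

`mulescout` is for researchers studying TE-derived gene origination in
plant clades (the rice genus being the motivating system): it takes genome
sequences, repeat/TIR hit tables, gene annotations, bisulfite cytosine
reports, small-RNA tables and genetic maps, and produces called elements,
parental-gene assignments, presence/absence origin dating, Ka/Ks selection
tests, region methylation statistics and local recombination rates. A
built-in synthetic-clade generator plants elements with full ground truth,
so the whole pipeline is testable without any external downloads.

## The rules and models at the core

- **Element calling.** Two TIR hits of one family in opposite orientations,
  < 20 kb apart, flanked by a 7–11 bp target-site duplication (TSD) found
  within a ±10 bp swing of the TIR ends — allowing 0/1/2 mismatches-or-indels
  for 7/8/9–11 bp TSDs. Transposase-bearing elements (TBLASTN-style hits,
  E < 1e-9) are autonomous and removed; a non-autonomous element is *genic*
  when a transcript with ≥ 150 bp intact CDS overlaps ≥ 30 % of its own
  length inside the element.
- **Dating.** Dollo parsimony (single gain, losses allowed) on an 11-taxon
  species tree assigns each element's origin branch from its
  identity-plus-synteny presence pattern; amplification times come from the
  Kimura two-parameter distance *k* to the nearest same-family paralog via
  **T = k / (2r)**, r = 1.3 × 10⁻⁸ substitutions · site⁻¹ · year⁻¹.
- **Selection.** Nei–Gojobori (1986) counting with Jukes–Cantor correction
  and a normal-approximation test of Ka ≠ Ks, Benjamini–Hochberg FDR,
  calls at q ≤ 0.05 (explicitly substituting codeml's likelihood machinery).
- **Epigenome.** Region methylation = Σ methylated / Σ total reads over
  cytosines covered by ≥ 3 reads, defined only when ≥ 50 % of cytosines are
  mapped, per CG/CHG/CHH context; 24-nt uniquely-mapping sRNA occupancy;
  TE content by interval union; TIR similarity by global alignment.
- **Recombination.** Marey map (cM vs bp) with automated outlier removal,
  local-quadratic LOESS (span 0.2), rate = analytic derivative in cM/Mb.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
from mulescout.synthetic import PlantConfig, simulate_genomes
from mulescout.caller import scan_tir_hits, call_mules
from mulescout.molevol import amplification_time

cfg = PlantConfig(seed=42, genome_length=300_000,
                  branch_insertions={"Osj": 10},
                  n_donor_genes=10, n_background_genes=10)
res = simulate_genomes(cfg)                      # 11 genomes, truth records
bundle = res.bundles["Osj"]
hits = scan_tir_hits(bundle.seqs, res.tir_families)
result = call_mules(bundle.seqs, hits, bundle.genes)
print("rejection log:", result.rejection_log)
el = result.elements[0]
print(f"{el.element_id}: {el.span.chrom}:{el.span.start}-{el.span.end} "
      f"family={el.family} TSD={el.tsd.left_seq} ({el.tsd.length} bp) "
      f"class={el.element_class}/{el.gene_class}")
t = amplification_time(0.026)
print(f"k = 0.026  ->  T = {t.time_years:.0f} years = {t.time_my:.1f} MY")
```

prints

```
rejection log: {'tir_hits': 20, 'elements_called': 10, 'autonomous_removed': 0, 'genic': 4, 'nongenic': 6, 'putative_genes': 4}
el00000: chr1:10864-11941 family=fam0 TSD=CCCATAGT (8 bp) class=non-autonomous/nongenic
k = 0.026  ->  T = 1000000 years = 1.0 MY
```

All 20 scanned TIR copies pair into the 10 planted elements; none carries a
transposase, 4 carry an intact captured ORF (genic-MULEs with their
MULE-derived putative genes), and a divergence of k = 0.026 dates an
element pair to 1.0 MY under the default rate.

The same stages are available from the shell:

```bash
mulescout simulate --seed 5 --out-prefix sim
mulescout call-mules --genome sim.Osj.fasta --tir-fasta fams.fasta \
    --gff sim.Osj.genes.gff3 --out-prefix called
mulescout recomb-map --markers markers.tsv --out rates.tsv
```

(plus `trace-parents`, `compare-species`, `date-elements`, `kaks`,
`methylation-profile`, `srna-occupancy`, `expression`).

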