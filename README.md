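# qresplice

Integration of alternative-splicing calls and QKI response element (QRE)
motif enrichment, for knockout-vs-control RNA-seq comparisons of the
splicing regulator QKI (and, structurally, any RNA-binding protein with a
consensus element).

QKI binds a bipartite RNA element,

```
ACUAAY-(N1–20)-UAAY        Y ∈ {C, U};  minimal core: ACUAA
```

mostly in introns near the exons it regulates. Given rMATS-style event
tables (JC and JCEC variants), DEXSeq-style exon-bin results, a GTF
annotation, a genome FASTA and a coverage table, `qresplice`:

1. merges the two rMATS quantification variants so each event is one
   record, then intersects with significant DEXSeq bins (≥ 1 bp overlap)
   into a high-confidence **stringent** set, and unions into a
   **comprehensive** set;
2. classifies each target exon against the annotation as **cassette**
   (internal in every isoform), **mixed** (internal in ≥ 1 isoform,
   terminal in another) or **first/last** (terminal in all; excluded from
   motif analysis);
3. extracts ≤ 200-nt intronic windows flanking each exon on the
   transcribed strand and scans them for the ACUAA core, and arbitrary
   regions for the full bipartite QRE with 0–1 mismatches over the 10
   constrained positions;
4. tests motif enrichment by resampling: each of 1,000 iterations draws as
   many control exons — non-alternatively-spliced cassette/mixed exons
   ≥ 15 nt with coverage above the lowest quartile — as there are events,
   and the empirical p-value is

   ```
   p = (1 + #{null fraction ≥ observed fraction}) / (1 + n_iter)
   ```

   reported for six subsets: stringent/comprehensive × all SE /
   higher-inclusion (QKI-repressed) / higher-exclusion (QKI-activated);
5. generates fully synthetic datasets (genome, GTF, result tables,
   coverage) with planted events, planted motifs and recorded ground
   truth, so every stage is testable end to end.

See `docs/methods.md` for the model, filters and numerical choices.

## Worked example

Everything below runs on synthetic data, so it works from a clean checkout:

```bash
qresplice simulate --outdir demo --seed 42
# wrote demo: 20 planted events, 102 control members

qresplice integrate --rmats-dir demo/rmats --dexseq demo/dexseq.tsv \
    --gtf demo/annotation.gtf --outdir demo/out
# stringent: 20 events in 20 genes
# comprehensive: 26 events in 24 genes

qresplice enrich --rmats-dir demo/rmats --dexseq demo/dexseq.tsv \
    --gtf demo/annotation.gtf --genome demo/genome.fa \
    --coverage demo/coverage.tsv --n-iter 1000 --seed 42 --out demo/enrich.json
# stringent:all_SE: n=20 observed=0.5 p=0.000999000999000999
# stringent:higher_inclusion: n=10 observed=0.5 p=0.000999000999000999
# ...

qresplice scan-region --region "chrQ:300-20300:+" --genome demo/genome.fa \
    --out-bed demo/qre.bed
# 114 QRE hits (24 perfect) -> demo/qre.bed
```

Reading the numbers: the generator planted 20 skipped-exon events
significant in both tools, and the stringent intersection recovered all 20
across 20 genes (the comprehensive union adds six rMATS-only events of
other types). Motifs were planted near 50% of events but only 10% of
control exons, so the observed motif-bearing fraction is 0.5 while 1,000
control resamples almost never reach it — the p-value sits at the plus-one
floor 1/1001 ≈ 0.001. The region scan recovers exactly the 24 perfect
QREs planted on the `chrQ` locus; the remaining hits are single-mismatch
matches arising from random background, as expected at this tolerance.

The same steps are available as library calls (`qresplice.generate`,
`build_stringent`, `run_subsets`, …); see the module docstrings.

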