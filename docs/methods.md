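# Methods

## Problem setting

QKI is a KH-domain RNA-binding protein that regulates pre-mRNA splicing in
oligodendrocytes and other tissues. Its STAR-domain dimer recognises a
bipartite RNA element, the QKI response element (QRE),

    ACUAAY-(N1–20)-UAAY        (Y = pyrimidine; core half-site ACUAA)

predominantly in intronic sequence near regulated exons. Loss of QKI shifts
the inclusion of a set of cassette exons; exons with *higher* inclusion in
the knockout are read as QKI-repressed, exons with higher exclusion as
QKI-activated.

`qresplice` implements the downstream analysis of such a knockout RNA-seq
comparison: integration of splicing calls from two complementary tools
(rMATS-style event tables and DEXSeq-style exon-bin tables), classification
of target exons against the gene annotation, extraction of flanking
intronic windows, QRE/core motif scanning, and a resampling test for motif
enrichment against a matched control-exon universe. Upstream read
processing (trimming, alignment, the splicing callers themselves) is out of
scope; the package starts from their result tables.

## Event integration

rMATS produces one table per event type (SE, A5SS, A3SS, RI) and per
quantification variant — junction reads only (JC) or junction plus
exon-body reads (JCEC). The two variants are first merged so each event is
one record; the merge key is the full coordinate tuple (target exon plus
both flanking exons), so alternative flanking structures remain distinct
events. Both variants' statistics are kept; the event's headline p-value is
the minimum of the two, labelled by source. A *putative* event has FDR
< 0.05 in either variant.

Two event sets are then built:

* **stringent** — rMATS events (p < 0.05) whose target exon overlaps, by at
  least 1 bp on the same chromosome, a DEXSeq bin with adjusted p < 0.05
  and length ≥ 15 nt. The rMATS record is kept. Overlap is strand-agnostic
  by default, mirroring a default BEDTools-style intersect; a `--stranded`
  flag is available.
* **comprehensive** — the union of significant calls from both tools
  (rMATS by FDR < 0.05, DEXSeq by adjusted p < 0.05), deduplicated by
  target-exon coordinates. Significant DEXSeq bins without an rMATS
  counterpart are promoted to SE-like events; they carry no flanking
  coordinates and no inclusion direction.

Because the stringent filter uses the raw rMATS p while the comprehensive
filter uses FDR, the subset relation stringent ⊆ comprehensive is
guaranteed whenever the two significance columns agree on the 0.05
threshold (as in the synthetic tables, where the FDR column mirrors p);
with discordant columns a stringent event is still covered in the
comprehensive set through its significant DEXSeq bin whenever the bin
shares the exon's coordinates. Both thresholds are configurable.

Inclusion-level difference is PSI(knockout) − PSI(control); positive means
higher inclusion without the regulator (a repressed exon). rMATS's sign
depends on the sample-group order given to the caller, so the readers
expose a `flip_sign` switch.

## Exon classification

The annotation is read from GENCODE-dialect GTF into an exon catalog:
coordinates become 0-based half-open at the parsing boundary, exons with
identical coordinates within a gene merge their transcript memberships, and
only `exon` features are used. Classification is per (exon, gene), over all
isoforms of that gene:

* **cassette** — internal (neither first nor last) in every containing
  isoform;
* **mixed** — internal in at least one isoform, terminal in another;
* **first_last** — terminal in all isoforms (single-exon transcripts count
  their exon as both first and last).

"First/last" is transcriptional and hence strand-dependent, but the
internal-vs-terminal distinction is orientation-invariant, so genomic
order is used internally. SE events that exactly match a catalog exon take
its class; SE events absent from the annotation are counted as mixed.
Events on exons that are terminal in all isoforms are excluded from the
motif analysis, since alternative promoter/terminator usage is generally
not splicing-regulated. When an exon matching an event is shared by
several overlapping genes, the event is called cassette only if every
per-gene copy is cassette — the conservative reading of a per-gene rule
the underlying definition leaves open.

## Motif scanning

Sequences are handled as DNA (U≡T) on the transcribed strand; minus-strand
windows and regions are reverse-complemented before scanning. Ambiguity
codes other than N are rejected.

* `scan_core` reports every start offset of an exact `ACTAA`, overlapping
  occurrences included; N never matches.
* `scan_qre` enumerates every (offset, spacer length) combination of the
  bipartite element with spacer 1–20 nt. The mismatch budget (0 or 1)
  counts substitutions over the 10 constrained positions only — `ACTAAY`
  plus `TAAY` — the spacer is unconstrained, and a purine at a Y position
  counts as one ordinary mismatch, so relaxing both Y positions costs two.
* `scan_region_qre` maps hits of an arbitrary genomic region back to
  genomic coordinates (for minus-strand regions, from the region end) and
  exports BED6.

Flanking windows abut the target exon's splice sites, extend up to 200 nt
(default) into the adjacent introns, and are clipped at the neighbouring
exon boundary and chromosome ends — never padded, so a 50-nt intron yields
a 50-nt window, keeping the scanned context strictly intronic. For events
the neighbouring boundary comes from the event's own flanking-exon
coordinates; for bare control exons it comes from the nearest catalog exon
on each side. An event "has the motif" if either side window contains at
least one core hit; per-side flags are kept for the positional summary
(repressed exons tend to carry the motif upstream, activated exons
downstream).

## Control universe and enrichment

Control exons must be: cassette or mixed; ≥ 15 nt; well covered — exon-
and gene-level coverage per nucleotide strictly above the respective 25th
percentile, computed over the candidate universe *after* the class and
length filters (the order is fixed for reproducibility, as the percentile
base is otherwise ambiguous); and not alternatively spliced — no
overlapping DEXSeq bin with adjusted p ≤ 0.99 and no overlapping rMATS
target with p ≤ 0.05. An exon with no DEXSeq bin at all is treated as
untested, not as spliced. Candidates without coverage entries are excluded
and counted separately; a filter log records removals per criterion.

The non-AS rMATS criterion is implemented as p > 0.05: a control set
required to be rMATS-*significant* would contradict its own "not
alternatively spliced" definition, so the opposite inequality is taken as
the intended reading (threshold configurable).

Enrichment of a set of events is tested by resampling: the observed
statistic is the fraction of events with a core hit in either flanking
window; each of `n_iter` (default 1,000) iterations draws, without
replacement, as many control exons as there are events and records the
same fraction. The empirical p-value uses the plus-one correction

    p = (1 + #{null ≥ observed}) / (1 + n_iter)

so p is never zero and 1/1001 is the floor at 1,000 iterations. Six
subsets are analysed per run — stringent/comprehensive × all SE /
higher-inclusion / higher-exclusion — sharing one control universe and one
set of precomputed control flags; per-subset seeds are derived from the
master seed through `numpy.random.SeedSequence.generate_state`, reduced
mod 2³¹. Empty subsets are flagged not-computed rather than erroring.
Results are reported raw, without correction across subsets.

A statistical caveat: events are an independent sample while the null
resamples a finite universe without replacement, so the null variance
carries a finite-population factor (1 − k/N). The test is therefore
calibrated only when the control universe is comfortably larger than the
event set (N ≫ k), which the filters are designed to ensure; the
calibration check runs at N/k ≈ 10.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, not
RNA-seq itself (no reads, no junction counts, no expression model):

* **Gene models** — by default 60 genes on 2 chromosomes, 4–8 exons per
  gene (80–300 nt), introns 450–900 nt so that 200-nt windows usually fit
  unclipped, with a 10% fraction of short introns (60–150 nt) to exercise
  clipping; 1–3 isoforms per gene derived from the full exon chain by
  skipping an internal exon or dropping a terminal one, which yields all
  three exon classes. Intended classes are recorded from index positions
  in the generator's own transcript lists — an independent path from the
  package's classifier.
* **Events** — 20 skipped-exon events by default (more in the power
  configuration), at most one per gene, on cassette/mixed exons; direction
  split 50/50; all events significant in both tools by default, with
  configurable rMATS-only/DEXSeq-only fractions. Significant rows draw
  p from Uniform(0, 0.01), null rows from Uniform(0.2, 1), and the FDR
  column mirrors p — thresholds, not distributions, drive the pipeline.
* **Motifs** — every candidate window is first scrubbed of accidental
  transcribed-strand `ACTAA` occurrences (the occurrence's middle base is
  set to a base absent from the motif, which provably cannot create a new
  occurrence), then the 5-mer is planted at rate `r_as` near events
  (upstream-biased for repressed, downstream-biased for activated,
  bias 0.7) and `r_control` near other candidate exons, at offsets chosen
  to avoid other tracked windows and previously planted sites. Realized
  per-exon presence is recorded geometrically from planted coordinates
  against window intervals, so ground truth stays exact even when short
  introns force two exons to share a window. Default rates are
  `r_as = 0.5`, `r_control = 0.1` — the planted-enrichment condition the
  power analysis uses.
* **QRE locus** — a separate 20-kb chromosome carries exactly 24 perfect
  bipartite QREs at recorded coordinates (configurable count, strand and
  length); accidental perfect matches are scrubbed with a vectorised
  enumerator until the perfect-hit set equals the planted set, while
  single-mismatch decoys from the random background remain.
* **Coverage** — exon and gene values are drawn in well-separated bands,
  Uniform(5, 10) high and Uniform(0.01, 0.2) low, with 35% of non-event
  candidates (and of non-event genes) assigned to the low band by exact
  count so the lowest-quartile filter reliably separates them. A 15%
  "ambiguous" fraction of non-event exons receives mid-range DEXSeq
  adjusted p (0.2–0.9) to exercise the > 0.99 control criterion.
  Ground-truth control membership is recomputed inside the generator from
  its own drawn values with the same quartile rule.

What passing on this data does *not* show: robustness to misannotated or
incomplete gene models, to coordinate disagreements between the two
callers (the generator emits concordant coordinates), to non-uniform base
composition or clustered motifs, or to the scale of a real mammalian
genome. The published mouse counts (e.g. the 88,217-exon control universe
or the 190-event stringent list) depend on the study's raw sequencing data
and are not reproducible at this scale.

## Problem sizes and numerical choices

Default analyses run at desk scale by design: ~60–260 genes (≤ 2 Mb of
genome), 20–150 events, control universes of ~100–400 exons, 1,000
resampling iterations. The calibration and power checks use 50 generator
seeds each. All randomness flows through `numpy.random.default_rng` seeded
explicitly; identical seeds give byte-identical generator output and
bit-identical enrichment results. Ties in the empirical p (null fraction
exactly equal to the observed) count against the events, via ≥ in the
exceedance count. Degenerate inputs are defined rather than accidental:
zero-length introns give empty windows (scanned as motif-free), empty
event subsets are flagged not-computed, an empty GTF yields an empty
catalog, and a control universe smaller than the event set is an error.

## Known limitations

* Event/bin matching is purely coordinate-based; fuzzy matching of
  slightly shifted exon boundaries is not attempted.
* The A5SS/A3SS/RI tables are parsed with the same column dialect as SE;
  only SE events receive flanking-window motif analysis.
* The QRE scanner reports all (offset, spacer) combinations, so one
  genomic site can yield several hits; consumers that need site-level
  counts should collapse by offset (perfect planted sites are recovered
  one hit per site because spacers are recorded).
* No PWM scoring, RNA secondary structure, or CLIP integration — the
  element is treated as a consensus with a hard mismatch budget.
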