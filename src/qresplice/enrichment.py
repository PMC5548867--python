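"""Control-exon universe and resampled motif-enrichment p-values.

The enrichment question: do flanking intronic windows of skipped-exon
events carry the ACUAA core more often than windows of comparable exons
that are *not* alternatively spliced? The null is built by resampling: in
each of ``n_iter`` iterations, draw (without replacement) as many control
exons as there are events, and record the fraction whose flanking windows
contain the core. The empirical p-value uses the plus-one correction

    p = (1 + #{null fractions >= observed fraction}) / (1 + n_iter)

so p is never zero and with 1,000 iterations the smallest attainable value
is 1/1001.

Control exons must be cassette or mixed, at least 15 nt long, well covered
(exon- and gene-level coverage per nucleotide strictly above the respective
25th percentile of the candidate universe, computed after the class and
length filters), and not alternatively spliced (no overlapping DEXSeq bin
with adjusted p ≤ 0.99 and no overlapping rMATS target with p ≤ 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from pyfaidx import Fasta

from .annotation import ExonCatalog, ExonClass, ExonRecord
from .events import DexseqBin, EventSet, SpliceEvent
from .motifs import FlankWindow, event_has_core, flanking_windows

logger = logging.getLogger(__name__)

COVERAGE_COLUMNS = ["exon_id", "gene_id", "exon_cov_per_nt", "gene_cov_per_nt"]


class CoverageTable:
    """Per-exon and per-gene coverage, already normalised per nucleotide."""

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in COVERAGE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"coverage table missing columns {missing}")
        if (df["exon_cov_per_nt"] < 0).any() or (df["gene_cov_per_nt"] < 0).any():
            raise ValueError("coverage values must be non-negative")
        self._exon = dict(zip(df["exon_id"], df["exon_cov_per_nt"]))
        self._gene = dict(zip(df["exon_id"], df["gene_cov_per_nt"]))

    @classmethod
    def read(cls, path: str | Path) -> "CoverageTable":
        return cls(pd.read_csv(path, sep="\t"))

    def exon_coverage(self, exon_id: str) -> float | None:
        return self._exon.get(exon_id)

    def gene_coverage(self, exon_id: str) -> float | None:
        return self._gene.get(exon_id)


@dataclass
class ControlExonSet:
    exons: list[ExonRecord]
    filter_log: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.exons)


@dataclass
class EnrichmentResult:
    label: str
    n_events: int
    observed_fraction: float | None
    null_fractions: np.ndarray | None
    p_value: float | None
    n_iter: int
    seed: int
    computed: bool = True

    def to_dict(self) -> dict:
        return {"label": self.label, "n_events": self.n_events,
                "observed_fraction": self.observed_fraction,
                "p_value": self.p_value, "n_iter": self.n_iter,
                "seed": self.seed, "computed": self.computed}


def empirical_p(observed: float, null: np.ndarray) -> float:
    """Plus-one empirical p-value of an observed fraction against a null."""
    return (1 + int(np.sum(null >= observed))) / (1 + len(null))


def _interval_trees(items: Iterable, chrom, start, end) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for it in items:
        trees.setdefault(chrom(it), IntervalTree()).addi(start(it), end(it), it)
    return trees


def build_control_set(catalog: ExonCatalog, coverage: CoverageTable,
                      dexseq: Sequence[DexseqBin],
                      rmats: Sequence[SpliceEvent],
                      min_length: int = 15,
                      dexseq_padj_min: float = 0.99,
                      rmats_p_min: float = 0.05,
                      coverage_quantile: float = 0.25) -> ControlExonSet:
    """Apply the control-exon filters conjunctively, logging removals.

    Order: exon class → length → coverage quantile → non-AS. The coverage
    percentiles are computed over the candidate universe surviving the class
    and length filters, and membership requires strictly greater values.
    Candidates without a coverage entry are excluded and counted separately.
    """
    log: dict[str, int] = {}
    classes = catalog.classify_all()
    candidates = [e for e in catalog.exons
                  if classes[e.key] in (ExonClass.CASSETTE, ExonClass.MIXED)]
    log["not_cassette_or_mixed"] = len(catalog) - len(candidates)

    survivors = [e for e in candidates if e.length >= min_length]
    log["below_min_length"] = len(candidates) - len(survivors)

    cov_pairs, missing = [], 0
    for e in survivors:
        ec, gc = coverage.exon_coverage(e.exon_id), coverage.gene_coverage(e.exon_id)
        if ec is None or gc is None:
            missing += 1
            continue
        cov_pairs.append((e, ec, gc))
    log["coverage_missing"] = missing
    if cov_pairs:
        exon_q = float(np.percentile([p[1] for p in cov_pairs],
                                     100 * coverage_quantile))
        gene_q = float(np.percentile([p[2] for p in cov_pairs],
                                     100 * coverage_quantile))
        kept = [(e, ec, gc) for e, ec, gc in cov_pairs
                if ec > exon_q and gc > gene_q]
    else:
        kept = []
    log["low_coverage"] = len(cov_pairs) - len(kept)

    dex_trees = _interval_trees(
        (b for b in dexseq if b.adjusted_p <= dexseq_padj_min),
        lambda b: b.chrom, lambda b: b.start, lambda b: b.end)
    rmats_trees = _interval_trees(
        (ev for ev in rmats if ev.p_value is not None
         and ev.p_value <= rmats_p_min),
        lambda e: e.chrom, lambda e: e.target[0], lambda e: e.target[1])

    final = []
    n_as = 0
    for e, _, _ in kept:
        dex_hit = e.chrom in dex_trees and dex_trees[e.chrom].overlap(e.start, e.end)
        rm_hit = (e.chrom in rmats_trees
                  and rmats_trees[e.chrom].overlap(e.start, e.end))
        if dex_hit or rm_hit:
            n_as += 1
            continue
        final.append(e)
    log["alternatively_spliced"] = n_as
    log["retained"] = len(final)
    return ControlExonSet(final, log)


# ---------------------------------------------------------------------------
# resampling

def _exon_windows(exon: ExonRecord, catalog: ExonCatalog, genome: Fasta,
                  window_size: int) -> tuple[FlankWindow, FlankWindow]:
    """Flanking windows of a bare catalog exon, clipped at the nearest
    neighbouring exon boundary on each side."""
    left_lo = max(0, exon.start - window_size)
    right_hi = min(len(genome[exon.chrom]), exon.end + window_size)
    for nb in catalog.overlapping(exon.chrom, left_lo, exon.start):
        if nb.end <= exon.start:
            left_lo = max(left_lo, nb.end)
    for nb in catalog.overlapping(exon.chrom, exon.end, right_hi):
        if nb.start >= exon.end:
            right_hi = min(right_hi, nb.start)
    ev = SpliceEvent(event_type="SE", chrom=exon.chrom, strand=exon.strand,
                     target=(exon.start, exon.end),
                     upstream=None, downstream=None, gene_id=exon.gene_id)
    # reuse the event window extractor with precomputed clip bounds
    up = (left_lo, exon.start) if exon.strand == "+" else (exon.end, right_hi)
    down = (exon.end, right_hi) if exon.strand == "+" else (left_lo, exon.start)
    from .motifs import _fetch
    w_up = FlankWindow("upstream", exon.chrom, up[0], up[1], exon.strand,
                       _fetch(genome, exon.chrom, up[0], up[1], exon.strand))
    w_down = FlankWindow("downstream", exon.chrom, down[0], down[1],
                         exon.strand,
                         _fetch(genome, exon.chrom, down[0], down[1],
                                exon.strand))
    return w_up, w_down


def control_motif_flags(controls: ControlExonSet, catalog: ExonCatalog,
                        genome: Fasta, window_size: int = 200) -> np.ndarray:
    """Either-side core presence for each control exon (computed once)."""
    flags = np.zeros(len(controls.exons), dtype=bool)
    for i, exon in enumerate(controls.exons):
        up, down = _exon_windows(exon, catalog, genome, window_size)
        flags[i] = event_has_core(up, down)[2]
    return flags


def event_motif_flags(events: Iterable[SpliceEvent], genome: Fasta,
                      window_size: int = 200) -> np.ndarray:
    flags = []
    for ev in events:
        up, down = flanking_windows(ev, genome, window_size)
        flags.append(event_has_core(up, down)[2])
    return np.asarray(flags, dtype=bool)


def empirical_enrichment(events: Sequence[SpliceEvent] | EventSet,
                         controls: ControlExonSet, catalog: ExonCatalog,
                         genome: Fasta, n_iter: int = 1000,
                         seed: int = 0, window_size: int = 200,
                         label: str = "all_SE",
                         control_flags: np.ndarray | None = None) -> EnrichmentResult:
    """Resampled enrichment of the ACUAA core near events vs control exons.

    Each iteration samples ``len(events)`` control exons without
    replacement; iterations are independent draws from the seeded generator.
    ``control_flags`` may be passed to amortise window scanning across
    subsets sharing one control universe.
    """
    evs = list(events)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if len(controls.exons) < len(evs):
        raise ValueError(f"control universe ({len(controls.exons)}) smaller "
                         f"than event set ({len(evs)})")
    if not evs:
        return EnrichmentResult(label, 0, None, None, None, n_iter, seed,
                                computed=False)
    observed = float(np.mean(event_motif_flags(evs, genome, window_size)))
    if control_flags is None:
        control_flags = control_motif_flags(controls, catalog, genome,
                                            window_size)
    rng = np.random.default_rng(seed)
    k = len(evs)
    null = np.empty(n_iter)
    for i in range(n_iter):
        idx = rng.choice(len(control_flags), size=k, replace=False)
        null[i] = control_flags[idx].mean()
    return EnrichmentResult(label, k, observed, null,
                            empirical_p(observed, null), n_iter, seed)


def subset_seeds(master_seed: int, n: int = 6) -> list[int]:
    """Deterministic per-subset seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def run_subsets(stringent: EventSet, comprehensive: EventSet,
                controls: ControlExonSet, catalog: ExonCatalog, genome: Fasta,
                n_iter: int = 1000, seed: int = 0,
                window_size: int = 200) -> list[EnrichmentResult]:
    """Enrichment for stringent/comprehensive × all / higher-inclusion /
    higher-exclusion SE subsets, sharing one control universe."""
    flags = control_motif_flags(controls, catalog, genome, window_size)
    seeds = subset_seeds(seed, 6)
    results = []
    i = 0
    for es in (stringent, comprehensive):
        se = es.subset(event_type="SE")
        for direction, tag in ((None, "all_SE"),
                               ("higher_inclusion", "higher_inclusion"),
                               ("higher_exclusion", "higher_exclusion")):
            sub = se if direction is None else se.subset(direction=direction)
            results.append(empirical_enrichment(
                sub.events, controls, catalog, genome, n_iter=n_iter,
                seed=seeds[i], window_size=window_size,
                label=f"{es.label}:{tag}", control_flags=flags))
            i += 1
    return results


def results_to_tsv(results: Sequence[EnrichmentResult],
                   path: str | Path) -> None:
    pd.DataFrame([r.to_dict() for r in results]).to_csv(path, sep="\t",
                                                        index=False)
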