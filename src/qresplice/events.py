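"""Integration of rMATS-style and DEXSeq-style splicing results.

The two callers see different evidence — rMATS models junction (JC) or
junction-plus-exon-body (JCEC, "reads on target") read counts per event,
DEXSeq tests differential usage of disjoint exon bins — so events supported
by both form a high-confidence "stringent" set, while their union forms a
"comprehensive" set. Both sets are deduplicated by genomic coordinates and
annotated against a gene-model catalog with the cassette/mixed/terminal exon
class of the target exon.

Conventions:

* intervals are 0-based half-open (the rMATS ``exonStart_0base`` column is
  already in this convention and is kept as-is);
* inclusion-level difference is PSI(knockout) − PSI(control), so a positive
  value means higher inclusion when the regulator is absent (a repressed
  exon); the sign convention can be flipped in the readers;
* overlap between an rMATS target exon and a DEXSeq bin is ≥1 bp on the same
  chromosome, strand-agnostic by default (mirroring a default BEDTools-style
  intersect), with an optional stranded mode.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotation import ExonCatalog, ExonClass

logger = logging.getLogger(__name__)

RMATS_JC = "rmats_jc"
RMATS_JCEC = "rmats_jcec"
DEXSEQ = "dexseq"

EVENT_TYPES = ("SE", "A5SS", "A3SS", "RI")

RMATS_COLUMNS = ["GeneID", "chr", "strand", "exonStart_0base", "exonEnd",
                 "upstreamES", "upstreamEE", "downstreamES", "downstreamEE",
                 "PValue", "FDR", "IncLevelDifference"]

DEXSEQ_COLUMNS = ["gene_id", "bin_id", "chrom", "start", "end", "strand", "padj"]


@dataclass
class SpliceEvent:
    """One unified alternative-splicing event."""

    event_type: str
    chrom: str
    strand: str
    target: tuple[int, int]
    upstream: tuple[int, int] | None = None
    downstream: tuple[int, int] | None = None
    gene_id: str = ""
    stats: dict[str, tuple[float, float]] = field(default_factory=dict)  # source -> (p, fdr)
    inclusion_level_difference: float | None = None
    sources: frozenset[str] = frozenset()
    exon_class: ExonClass | None = None

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        for iv in (self.target, self.upstream, self.downstream):
            if iv is not None and not iv[0] < iv[1]:
                raise ValueError(f"invalid interval {iv} in {self}")

    @property
    def key(self) -> tuple:
        """Merge key: all defining coordinates, so alternative flanking
        structures remain distinct events."""
        return (self.event_type, self.chrom, self.strand, self.target,
                self.upstream, self.downstream)

    @property
    def coord_key(self) -> tuple:
        """Deduplication key on the target exon alone."""
        return (self.chrom, self.strand, self.target)

    @property
    def p_value(self) -> float | None:
        """Headline p: the minimum across source variants."""
        ps = [p for p, _ in self.stats.values() if not math.isnan(p)]
        return min(ps) if ps else None

    @property
    def fdr(self) -> float | None:
        fs = [f for _, f in self.stats.values() if not math.isnan(f)]
        return min(fs) if fs else None

    @property
    def direction(self) -> str | None:
        """higher_inclusion / higher_exclusion in the knockout, by the sign
        of the inclusion-level difference; None when unknown or zero."""
        d = self.inclusion_level_difference
        if d is None or d == 0:
            return None
        return "higher_inclusion" if d > 0 else "higher_exclusion"


@dataclass(frozen=True)
class DexseqBin:
    gene_id: str
    bin_id: str
    chrom: str
    start: int
    end: int
    strand: str
    adjusted_p: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"invalid bin interval {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def eligible(self, min_length: int = 15) -> bool:
        return self.length >= min_length


@dataclass
class EventSet:
    label: str  # "stringent" or "comprehensive"
    events: list[SpliceEvent]

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def subset(self, direction: str | None = None,
               event_type: str | None = None) -> "EventSet":
        evs = self.events
        if event_type is not None:
            evs = [e for e in evs if e.event_type == event_type]
        if direction is not None:
            evs = [e for e in evs if e.direction == direction]
        return EventSet(self.label, list(evs))

    def tally(self) -> pd.DataFrame:
        """Counts by event type and, for SE, by target-exon class."""
        rows = []
        for e in self.events:
            cls = e.exon_class.value if e.exon_class is not None else "unannotated"
            rows.append({"event_type": e.event_type, "exon_class": cls})
        if not rows:
            return pd.DataFrame(columns=["event_type", "exon_class", "count"])
        df = pd.DataFrame(rows)
        return (df.groupby(["event_type", "exon_class"]).size()
                  .rename("count").reset_index())

    def to_tsv(self, path: str | Path) -> None:
        cols = ["event_type", "chrom", "strand", "target_start", "target_end",
                "upstream_start", "upstream_end", "downstream_start",
                "downstream_end", "gene_id", "p_value", "fdr",
                "inclusion_level_difference", "direction", "sources",
                "exon_class"]
        rows = []
        for e in sorted(self.events, key=lambda e: (e.chrom, e.target, e.gene_id)):
            rows.append({
                "event_type": e.event_type, "chrom": e.chrom, "strand": e.strand,
                "target_start": e.target[0], "target_end": e.target[1],
                "upstream_start": e.upstream[0] if e.upstream else "",
                "upstream_end": e.upstream[1] if e.upstream else "",
                "downstream_start": e.downstream[0] if e.downstream else "",
                "downstream_end": e.downstream[1] if e.downstream else "",
                "gene_id": e.gene_id, "p_value": e.p_value, "fdr": e.fdr,
                "inclusion_level_difference": e.inclusion_level_difference,
                "direction": e.direction or "",
                "sources": ",".join(sorted(e.sources)),
                "exon_class": e.exon_class.value if e.exon_class else "",
            })
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in sorted(self.events, key=lambda e: (e.chrom, e.target)):
                name = f"{e.gene_id}|{e.event_type}"
                fh.write(f"{e.chrom}\t{e.target[0]}\t{e.target[1]}\t{name}\t0\t"
                         f"{e.strand}\n")


# ---------------------------------------------------------------------------
# readers

def read_rmats(path: str | Path, event_type: str, variant: str,
               flip_sign: bool = False) -> list[SpliceEvent]:
    """Read one rMATS-style result table.

    ``variant`` is ``rmats_jc`` (junction reads only) or ``rmats_jcec``
    (junction plus reads on target). Rows with non-numeric p-values are
    rejected and logged. ``flip_sign`` negates the inclusion-level difference
    for outputs produced with the opposite sample-group order.
    """
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event type {event_type!r}")
    if variant not in (RMATS_JC, RMATS_JCEC):
        raise ValueError(f"unknown rMATS variant {variant!r}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RMATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing rMATS columns {missing}")
    events: list[SpliceEvent] = []
    for idx, row in df.iterrows():
        try:
            p = float(row["PValue"])
            fdr = float(row["FDR"])
            ild = float(row["IncLevelDifference"])
        except (TypeError, ValueError):
            logger.warning("%s row %d: non-numeric statistic; row rejected",
                           path, idx)
            continue
        if flip_sign:
            ild = -ild
        events.append(SpliceEvent(
            event_type=event_type,
            chrom=str(row["chr"]),
            strand=str(row["strand"]),
            target=(int(row["exonStart_0base"]), int(row["exonEnd"])),
            upstream=(int(row["upstreamES"]), int(row["upstreamEE"])),
            downstream=(int(row["downstreamES"]), int(row["downstreamEE"])),
            gene_id=str(row["GeneID"]),
            stats={variant: (p, fdr)},
            inclusion_level_difference=ild,
            sources=frozenset({variant}),
        ))
    return events


def read_rmats_dir(directory: str | Path,
                   flip_sign: bool = False) -> dict[str, dict[str, list[SpliceEvent]]]:
    """Read an rMATS output directory laid out as ``<TYPE>.MATS.<JC|JCEC>.txt``."""
    directory = Path(directory)
    out: dict[str, dict[str, list[SpliceEvent]]] = {}
    for event_type in EVENT_TYPES:
        for suffix, variant in (("JC", RMATS_JC), ("JCEC", RMATS_JCEC)):
            f = directory / f"{event_type}.MATS.{suffix}.txt"
            if f.exists():
                out.setdefault(event_type, {})[variant] = read_rmats(
                    f, event_type, variant, flip_sign=flip_sign)
    return out


def read_dexseq(path: str | Path) -> list[DexseqBin]:
    """Read a DEXSeq-style results table (TSV) into exon bins."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DEXSEQ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing DEXSeq columns {missing}")
    bins = []
    for _, row in df.iterrows():
        bins.append(DexseqBin(
            gene_id=str(row["gene_id"]), bin_id=str(row["bin_id"]),
            chrom=str(row["chrom"]), start=int(row["start"]),
            end=int(row["end"]), strand=str(row["strand"]),
            adjusted_p=float(row["padj"])))
    return bins


# ---------------------------------------------------------------------------
# merging and set construction

def merge_rmats_variants(jc: Sequence[SpliceEvent],
                         jcec: Sequence[SpliceEvent]) -> list[SpliceEvent]:
    """Collapse JC and JCEC calls so each event is represented once.

    Events sharing the full coordinate key merge into one record keeping both
    variants' statistics. Identical coordinates with conflicting strands are
    an input error.
    """
    seen_coords: dict[tuple, str] = {}
    merged: dict[tuple, SpliceEvent] = {}
    for ev in list(jc) + list(jcec):
        ck = (ev.event_type, ev.chrom, ev.target, ev.upstream, ev.downstream)
        prev_strand = seen_coords.get(ck)
        if prev_strand is not None and prev_strand != ev.strand:
            raise ValueError(f"conflicting strand for event at "
                             f"{ev.chrom}:{ev.target}")
        seen_coords[ck] = ev.strand
        cur = merged.get(ev.key)
        if cur is None:
            merged[ev.key] = replace(ev, stats=dict(ev.stats))
        else:
            cur.stats.update(ev.stats)
            cur.sources = cur.sources | ev.sources
            if cur.inclusion_level_difference is None:
                cur.inclusion_level_difference = ev.inclusion_level_difference
    return list(merged.values())


def putative_events(merged: Iterable[SpliceEvent],
                    fdr_threshold: float = 0.05) -> list[SpliceEvent]:
    """Putative list: FDR below threshold in either quantification variant."""
    return [e for e in merged
            if any(f < fdr_threshold for _, f in e.stats.values()
                   if not math.isnan(f))]


def _bin_trees(bins: Iterable[DexseqBin]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for b in bins:
        trees.setdefault(b.chrom, IntervalTree()).addi(b.start, b.end, b)
    return trees


def _dedup_by_coords(events: Iterable[SpliceEvent]) -> list[SpliceEvent]:
    out: dict[tuple, SpliceEvent] = {}
    for ev in events:
        cur = out.get(ev.coord_key)
        if cur is None:
            out[ev.coord_key] = ev
        else:
            cur.stats.update({k: v for k, v in ev.stats.items()
                              if k not in cur.stats})
            cur.sources = cur.sources | ev.sources
    return list(out.values())


def build_stringent(rmats: Sequence[SpliceEvent], dexseq: Sequence[DexseqBin],
                    p_rmats: float = 0.05, padj_dexseq: float = 0.05,
                    min_bin_length: int = 15,
                    stranded: bool = False) -> EventSet:
    """Intersect rMATS events with significant DEXSeq bins by location.

    Keeps rMATS events (p below ``p_rmats``) whose target exon overlaps, by
    at least 1 bp on the same chromosome, an eligible DEXSeq bin with
    adjusted p below ``padj_dexseq``; the rMATS information is kept. The
    result is deduplicated by target-exon coordinates.
    """
    sig_bins = [b for b in dexseq
                if b.eligible(min_bin_length) and b.adjusted_p < padj_dexseq]
    trees = _bin_trees(sig_bins)
    kept = []
    for ev in rmats:
        p = ev.p_value
        if p is None or p >= p_rmats:
            continue
        tree = trees.get(ev.chrom)
        if tree is None:
            continue
        hits = tree.overlap(*ev.target)
        if stranded:
            hits = {h for h in hits if h.data.strand == ev.strand}
        if hits:
            kept.append(replace(ev, stats=dict(ev.stats),
                                sources=ev.sources | {DEXSEQ}))
    return EventSet("stringent", _dedup_by_coords(kept))


def build_comprehensive(rmats: Sequence[SpliceEvent],
                        dexseq: Sequence[DexseqBin],
                        fdr_rmats: float = 0.05, padj_dexseq: float = 0.05,
                        min_bin_length: int = 15) -> EventSet:
    """Union of significant calls from both tools, coordinate-deduplicated.

    Significant DEXSeq bins without an rMATS counterpart are promoted to
    SE-like events (no flanking coordinates, no inclusion direction).
    """
    sig_rmats = [replace(e, stats=dict(e.stats)) for e in rmats
                 if e.fdr is not None and e.fdr < fdr_rmats]
    events = _dedup_by_coords(sig_rmats)
    covered = {e.coord_key for e in events}
    covered_unstranded = {(c, t) for c, _, t in covered}
    for b in dexseq:
        if not b.eligible(min_bin_length) or b.adjusted_p >= padj_dexseq:
            continue
        if (b.chrom, (b.start, b.end)) in covered_unstranded:
            continue
        ev = SpliceEvent(event_type="SE", chrom=b.chrom, strand=b.strand,
                         target=(b.start, b.end), gene_id=b.gene_id,
                         stats={DEXSEQ: (math.nan, b.adjusted_p)},
                         sources=frozenset({DEXSEQ}))
        if ev.coord_key not in covered:
            events.append(ev)
            covered.add(ev.coord_key)
            covered_unstranded.add((b.chrom, (b.start, b.end)))
    return EventSet("comprehensive", events)


def annotate_events(event_set: EventSet, catalog: ExonCatalog) -> EventSet:
    """Attach the catalog exon class to each SE event.

    Events whose target exactly matches a catalog exon take that exon's
    class; SE events absent from the annotation are counted as mixed.
    """
    annotated = []
    for ev in event_set.events:
        ev = replace(ev, stats=dict(ev.stats))
        if ev.event_type == "SE":
            matches = [e for e in catalog.overlapping(ev.chrom, *ev.target)
                       if (e.start, e.end) == ev.target and e.strand == ev.strand]
            if matches:
                classes = {catalog.classify_exon(m) for m in matches}
                # cassette only if cassette in every containing gene copy
                if classes == {ExonClass.CASSETTE}:
                    ev.exon_class = ExonClass.CASSETTE
                elif ExonClass.CASSETTE in classes or ExonClass.MIXED in classes:
                    ev.exon_class = ExonClass.MIXED
                else:
                    ev.exon_class = ExonClass.FIRST_LAST
            else:
                ev.exon_class = ExonClass.MIXED
        annotated.append(ev)
    return EventSet(event_set.label, annotated)


def exclude_terminal_events(event_set: EventSet) -> EventSet:
    """Drop SE events whose exon is first/last in all isoforms."""
    return EventSet(event_set.label,
                    [e for e in event_set.events
                     if e.exon_class is not ExonClass.FIRST_LAST])


def count_event_genes(event_set: EventSet) -> int:
    """Number of distinct genes carrying at least one event."""
    return len({e.gene_id for e in event_set.events if e.gene_id})
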