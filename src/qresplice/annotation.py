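"""Gene-model exon catalog and cassette/mixed/terminal exon classification.

A catalog is built from a GENCODE-dialect GTF. Exons with identical genomic
coordinates within a gene are merged into a single record carrying the union
of their transcript memberships. Each exon is then classified by its position
across all isoforms of its gene:

* ``cassette``   — internal (neither first nor last) in every containing isoform;
* ``mixed``      — internal in at least one isoform but first/last in another;
* ``first_last`` — first or last exon in every containing isoform.

"First" and "last" are transcriptional, i.e. strand-dependent, although for
the internal-vs-terminal distinction the two orientations agree. Single-exon
transcripts count their exon as both first and last. Exons shared by
overlapping genes are kept as per-gene copies and classified per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

import gffutils
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)


class GtfParseError(ValueError):
    """Raised when a GTF line cannot be interpreted."""


class ExonClass(str, Enum):
    CASSETTE = "cassette"
    MIXED = "mixed"
    FIRST_LAST = "first_last"


@dataclass(frozen=True)
class ExonRecord:
    """A deduplicated exon of one gene, 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"exon start must precede end: {self}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-': {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int, int, str, str]:
        return (self.chrom, self.start, self.end, self.strand, self.gene_id)

    @property
    def exon_id(self) -> str:
        """Stable identifier used in coverage tables and exports."""
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})|{self.gene_id}"


class ExonCatalog:
    """Exon set with per-transcript ordering and per-chromosome interval index."""

    def __init__(self) -> None:
        self._exons: dict[tuple, ExonRecord] = {}
        self.transcript_index: dict[str, list[ExonRecord]] = {}
        self.gene_index: dict[str, list[str]] = {}
        self._trees: dict[str, IntervalTree] | None = None

    # -- construction ------------------------------------------------------

    def add_exon(self, chrom: str, start: int, end: int, strand: str,
                 gene_id: str, transcript_id: str) -> None:
        key = (chrom, start, end, strand, gene_id)
        prev = self._exons.get(key)
        if prev is None:
            # reject coordinate duplicates that disagree on strand
            alt = (chrom, start, end, "-" if strand == "+" else "+", gene_id)
            if alt in self._exons:
                raise GtfParseError(
                    f"conflicting strands for exon {chrom}:{start}-{end} in {gene_id}")
            rec = ExonRecord(chrom, start, end, strand, gene_id, (transcript_id,))
        else:
            if transcript_id in prev.transcript_ids:
                rec = prev
            else:
                rec = ExonRecord(chrom, start, end, strand, gene_id,
                                 prev.transcript_ids + (transcript_id,))
        self._exons[key] = rec
        self._trees = None

    def finalize(self) -> None:
        """Rebuild transcript/gene indices from the exon set."""
        self.transcript_index = {}
        self.gene_index = {}
        per_tx: dict[str, list[ExonRecord]] = {}
        for rec in self._exons.values():
            for tx in rec.transcript_ids:
                per_tx.setdefault(tx, []).append(rec)
            self.gene_index.setdefault(rec.gene_id, [])
        for tx, exons in per_tx.items():
            exons.sort(key=lambda e: (e.start, e.end))
            prev_end = None
            for e in exons:
                if prev_end is not None and e.start < prev_end:
                    raise GtfParseError(
                        f"overlapping exons within transcript {tx}: {e.chrom}:{e.start}")
                prev_end = e.end
            self.transcript_index[tx] = exons
            gene = exons[0].gene_id
            if tx not in self.gene_index[gene]:
                self.gene_index[gene].append(tx)
        for txs in self.gene_index.values():
            txs.sort()

    # -- access ------------------------------------------------------------

    @property
    def exons(self) -> list[ExonRecord]:
        return sorted(self._exons.values(),
                      key=lambda e: (e.chrom, e.start, e.end, e.gene_id))

    def __len__(self) -> int:
        return len(self._exons)

    def __contains__(self, exon: ExonRecord) -> bool:
        return exon.key in self._exons

    def get(self, chrom: str, start: int, end: int, strand: str,
            gene_id: str) -> ExonRecord | None:
        return self._exons.get((chrom, start, end, strand, gene_id))

    def trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees over all exons (built lazily)."""
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for rec in self._exons.values():
                trees.setdefault(rec.chrom, IntervalTree()).addi(
                    rec.start, rec.end, rec)
            self._trees = trees
        return self._trees

    def overlapping(self, chrom: str, start: int, end: int) -> list[ExonRecord]:
        tree = self.trees().get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]

    # -- classification ----------------------------------------------------

    def classify_exon(self, exon: ExonRecord) -> ExonClass:
        """Classify an exon by its position across all isoforms of its gene."""
        if exon.key not in self._exons:
            raise KeyError(f"exon not in catalog: {exon.exon_id}")
        exon = self._exons[exon.key]
        internal = terminal = 0
        for tx in exon.transcript_ids:
            exons = self.transcript_index[tx]
            idx = exons.index(exon)
            # genomic order; on the minus strand first/last swap but the
            # terminal-vs-internal distinction is orientation-invariant
            if 0 < idx < len(exons) - 1:
                internal += 1
            else:
                terminal += 1
        if terminal == 0:
            return ExonClass.CASSETTE
        if internal == 0:
            return ExonClass.FIRST_LAST
        return ExonClass.MIXED

    def classify_all(self) -> dict[tuple, ExonClass]:
        return {rec.key: self.classify_exon(rec) for rec in self._exons.values()}

    def exclude_terminal(self, exons: Iterable[ExonRecord]) -> list[ExonRecord]:
        """Drop exons that are first/last in every isoform; order-stable."""
        return [e for e in exons
                if self.classify_exon(e) is not ExonClass.FIRST_LAST]

    # -- export ------------------------------------------------------------

    def to_bed(self, path: str | Path) -> None:
        """BED6 export; the name column is ``gene|class``."""
        with open(path, "w") as fh:
            for rec in self.exons:
                cls = self.classify_exon(rec).value
                fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t"
                         f"{rec.gene_id}|{cls}\t0\t{rec.strand}\n")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("exon_id\tchrom\tstart\tend\tstrand\tgene_id\t"
                     "transcripts\texon_class\n")
            for rec in self.exons:
                cls = self.classify_exon(rec).value
                fh.write(f"{rec.exon_id}\t{rec.chrom}\t{rec.start}\t{rec.end}\t"
                         f"{rec.strand}\t{rec.gene_id}\t"
                         f"{','.join(sorted(rec.transcript_ids))}\t{cls}\n")


def _validate_gtf_lines(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                raise GtfParseError(f"{path}: malformed GTF line {lineno}: "
                                    f"expected 9 tab-separated fields")


def parse_gtf(path: str | Path) -> ExonCatalog:
    """Parse a GENCODE-dialect GTF into an :class:`ExonCatalog`.

    GTF 1-based inclusive coordinates are converted to 0-based half-open at
    this boundary. Only ``exon`` features are used; CDS/UTR lines are ignored.
    Exon features lacking a ``transcript_id`` are rejected and logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    catalog = ExonCatalog()
    _validate_gtf_lines(path)
    if path.stat().st_size == 0:
        catalog.finalize()
        return catalog
    try:
        db = gffutils.create_db(str(path), ":memory:", force=True,
                                keep_order=True, disable_infer_genes=True,
                                disable_infer_transcripts=True)
    except Exception as exc:  # pragma: no cover - backstop for dialect issues
        raise GtfParseError(f"{path}: {exc}") from exc
    for feat in db.features_of_type("exon"):
        gene = feat.attributes.get("gene_id")
        tx = feat.attributes.get("transcript_id")
        if not tx or not gene:
            logger.warning("exon at %s:%s-%s missing gene_id/transcript_id; skipped",
                           feat.seqid, feat.start, feat.end)
            continue
        catalog.add_exon(feat.seqid, feat.start - 1, feat.end, feat.strand,
                         gene[0], tx[0])
    catalog.finalize()
    return catalog


def write_gtf(catalog: ExonCatalog, path: str | Path,
              source: str = "qresplice") -> None:
    """Emit the catalog as exon features in GENCODE attribute dialect."""
    lines = []
    for tx, exons in sorted(catalog.transcript_index.items()):
        for rec in exons:
            attrs = f'gene_id "{rec.gene_id}"; transcript_id "{tx}";'
            lines.append((rec.chrom, rec.start,
                          f"{rec.chrom}\t{source}\texon\t{rec.start + 1}\t"
                          f"{rec.end}\t.\t{rec.strand}\t.\t{attrs}\n"))
    lines.sort()
    with open(path, "w") as fh:
        for _, _, line in lines:
            fh.write(line)
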