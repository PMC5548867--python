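"""QKI response element (QRE) scanning and flanking-window extraction.

The QKI STAR-domain dimer recognises a bipartite RNA element,
``ACUAAY-(N1–20)-UAAY`` with Y a pyrimidine, of which ``ACUAA`` is the
minimal core half-site. Sequences are handled as DNA internally (U≡T), on
the transcribed strand: windows and regions on the minus strand are
reverse-complemented before scanning.

Core scanning reports every start offset of an exact ``ACTAA`` match,
overlaps included; ``N`` never matches. Full-QRE scanning enumerates every
(offset, spacer length) combination whose 10 constrained positions —
``ACTAAY`` plus ``TAAY`` — differ from the consensus by at most
``max_mismatch`` substitutions; the spacer is unconstrained. A mismatch at a
Y position counts like any other single mismatch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from pyfaidx import Fasta

from .events import EventSet, SpliceEvent

logger = logging.getLogger(__name__)

CORE = "ACTAA"
HALF1 = "ACTAAY"  # positions 0-5
HALF2 = "TAAY"    # positions 0-3 after the spacer
PYRIMIDINES = frozenset("CT")
VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_sequence(seq: str) -> str:
    """Uppercase, U→T; reject ambiguity codes other than N."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - VALID_BASES
    if bad:
        raise ValueError(f"unsupported nucleotide codes: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    """One core or bipartite-QRE occurrence within a scanned sequence."""

    kind: str                 # "core" or "qre"
    offset: int               # 0-based start in the scanned sequence
    spacer_len: int = 0       # qre only
    mismatches: int = 0       # qre only

    @property
    def span(self) -> int:
        if self.kind == "core":
            return len(CORE)
        return len(HALF1) + self.spacer_len + len(HALF2)


@dataclass(frozen=True)
class GenomicMotifHit(MotifHit):
    """A motif hit mapped back to genomic coordinates."""

    chrom: str = ""
    genomic_start: int = 0    # 0-based half-open, leftmost genomic base
    genomic_end: int = 0
    strand: str = "+"


@dataclass
class FlankWindow:
    """Intronic window on one side of a target exon, transcribed strand."""

    side: str                 # "upstream" or "downstream" (transcript orientation)
    chrom: str
    start: int                # genomic, 0-based half-open; start == end → empty
    end: int
    strand: str
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


def scan_core(seq: str) -> list[MotifHit]:
    """All exact ACUAA core occurrences, overlapping hits included."""
    s = normalize_sequence(seq)
    hits = []
    pos = s.find(CORE)
    while pos != -1:
        hits.append(MotifHit("core", pos))
        pos = s.find(CORE, pos + 1)
    return hits


def _half_mismatches(segment: str, template: str, budget: int) -> int | None:
    """Mismatch count of a half-site against its template, or None if over
    budget. Y matches any pyrimidine; N matches nothing."""
    mm = 0
    for base, t in zip(segment, template):
        if t == "Y":
            if base not in PYRIMIDINES:
                mm += 1
        elif base != t:
            mm += 1
        if mm > budget:
            return None
    return mm


def scan_qre(seq: str, max_mismatch: int = 1, spacer_min: int = 1,
             spacer_max: int = 20) -> list[MotifHit]:
    """All bipartite-QRE matches within ``max_mismatch`` substitutions.

    Every (offset, spacer length) combination is reported, so one genomic
    site can yield several hits with different spacers.
    """
    if spacer_min > spacer_max:
        raise ValueError("spacer_min must not exceed spacer_max")
    if spacer_min < 1:
        raise ValueError("spacer_min must be >= 1")
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    s = normalize_sequence(seq)
    n = len(s)
    h1, h2 = len(HALF1), len(HALF2)
    hits = []
    for offset in range(n - h1 - spacer_min - h2 + 1):
        mm1 = _half_mismatches(s[offset:offset + h1], HALF1, max_mismatch)
        if mm1 is None:
            continue
        budget2 = max_mismatch - mm1
        for spacer in range(spacer_min, spacer_max + 1):
            tail = offset + h1 + spacer
            if tail + h2 > n:
                break
            mm2 = _half_mismatches(s[tail:tail + h2], HALF2, budget2)
            if mm2 is None:
                continue
            hits.append(MotifHit("qre", offset, spacer, mm1 + mm2))
    return hits


# ---------------------------------------------------------------------------
# window extraction

def _chrom_length(genome: Fasta, chrom: str) -> int:
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome FASTA")
    return len(genome[chrom])


def _fetch(genome: Fasta, chrom: str, start: int, end: int, strand: str) -> str:
    if start >= end:
        return ""
    seq = str(genome[chrom][start:end])
    seq = normalize_sequence(seq)
    return reverse_complement(seq) if strand == "-" else seq


def flanking_windows(event: SpliceEvent, genome: Fasta,
                     window_size: int = 200) -> tuple[FlankWindow, FlankWindow]:
    """Intronic windows abutting the target exon's splice sites.

    Returns (upstream, downstream) in transcript orientation. Windows are
    clipped at the neighbouring exon boundary (when the event carries
    flanking-exon coordinates) and at chromosome ends, and never padded: a
    short intron yields a short window. Minus-strand windows are
    reverse-complemented and the genomically rightward window is the
    transcript-upstream one.
    """
    chrom_len = _chrom_length(genome, event.chrom)
    t_start, t_end = event.target
    # flanking exons in genomic order: rMATS "upstream" is transcript-upstream
    if event.strand == "+":
        left_exon, right_exon = event.upstream, event.downstream
    else:
        left_exon, right_exon = event.downstream, event.upstream

    left_lo = max(0, t_start - window_size)
    if left_exon is not None:
        left_lo = max(left_lo, left_exon[1])
    left_lo = min(left_lo, t_start)
    right_hi = min(chrom_len, t_end + window_size)
    if right_exon is not None:
        right_hi = min(right_hi, right_exon[0])
    right_hi = max(right_hi, t_end)

    left = FlankWindow(side="", chrom=event.chrom, start=left_lo, end=t_start,
                       strand=event.strand,
                       sequence=_fetch(genome, event.chrom, left_lo, t_start,
                                       event.strand))
    right = FlankWindow(side="", chrom=event.chrom, start=t_end, end=right_hi,
                        strand=event.strand,
                        sequence=_fetch(genome, event.chrom, t_end, right_hi,
                                        event.strand))
    if left.length == 0 or right.length == 0:
        logger.info("zero-length intron window at %s:%s-%s",
                    event.chrom, t_start, t_end)
    if event.strand == "+":
        left.side, right.side = "upstream", "downstream"
        return left, right
    left.side, right.side = "downstream", "upstream"
    return right, left


def event_has_core(upstream: FlankWindow,
                   downstream: FlankWindow) -> tuple[bool, bool, bool]:
    """(upstream, downstream, either) presence of the ACUAA core."""
    up = bool(scan_core(upstream.sequence)) if upstream.sequence else False
    down = bool(scan_core(downstream.sequence)) if downstream.sequence else False
    return up, down, up or down


def positional_summary(event_set: EventSet, genome: Fasta,
                       window_size: int = 200):
    """Contingency of inclusion direction against motif side.

    Rows: higher_inclusion (repressed when the regulator is absent) and
    higher_exclusion (activated). Columns: upstream-only / downstream-only /
    both / neither. Events without a direction are excluded and counted in
    the returned ``n_no_direction``.
    """
    import pandas as pd

    counts = {d: {"upstream_only": 0, "downstream_only": 0,
                  "both": 0, "neither": 0}
              for d in ("higher_inclusion", "higher_exclusion")}
    n_no_direction = 0
    for ev in event_set:
        d = ev.direction
        if d is None:
            n_no_direction += 1
            continue
        up_w, down_w = flanking_windows(ev, genome, window_size)
        up, down, _ = event_has_core(up_w, down_w)
        if up and down:
            cell = "both"
        elif up:
            cell = "upstream_only"
        elif down:
            cell = "downstream_only"
        else:
            cell = "neither"
        counts[d][cell] += 1
    table = pd.DataFrame(counts).T
    table.index.name = "direction"
    table.attrs["n_no_direction"] = n_no_direction
    return table


def scan_region_qre(chrom: str, start: int, end: int, strand: str,
                    genome: Fasta, max_mismatch: int = 1,
                    spacer_min: int = 1,
                    spacer_max: int = 20) -> list[GenomicMotifHit]:
    """Scan a genomic region's transcribed strand for bipartite QREs.

    Hit offsets are mapped back to genomic coordinates: for minus-strand
    regions the hit's leftmost genomic base is computed from the region end.
    """
    chrom_len = _chrom_length(genome, chrom)
    if start < 0 or end > chrom_len or start >= end:
        raise ValueError(f"region {chrom}:{start}-{end} out of bounds "
                         f"(chromosome length {chrom_len})")
    seq = _fetch(genome, chrom, start, end, strand)
    out = []
    for hit in scan_qre(seq, max_mismatch, spacer_min, spacer_max):
        if strand == "+":
            g_start = start + hit.offset
        else:
            g_start = end - hit.offset - hit.span
        out.append(GenomicMotifHit(kind=hit.kind, offset=hit.offset,
                                   spacer_len=hit.spacer_len,
                                   mismatches=hit.mismatches, chrom=chrom,
                                   genomic_start=g_start,
                                   genomic_end=g_start + hit.span,
                                   strand=strand))
    return out


def hits_to_bed(hits: Sequence[GenomicMotifHit], path: str | Path) -> None:
    """BED6 export of genomic motif hits; score column = mismatch count."""
    with open(path, "w") as fh:
        for h in sorted(hits, key=lambda h: (h.chrom, h.genomic_start)):
            name = f"{h.kind}_sp{h.spacer_len}"
            fh.write(f"{h.chrom}\t{h.genomic_start}\t{h.genomic_end}\t{name}\t"
                     f"{h.mismatches}\t{h.strand}\n")
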