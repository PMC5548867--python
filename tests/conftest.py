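"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import re

import numpy as np
import pytest
from pyfaidx import Fasta

from qresplice.simulate import SyntheticConfig, generate

# ---------------------------------------------------------------------------
# independent oracles


def regex_core_offsets(seq: str) -> list[int]:
    """Overlap-aware regex oracle for ACUAA core offsets (DNA alphabet)."""
    s = seq.upper().replace("U", "T")
    return [m.start() for m in re.finditer(r"(?=ACTAA)", s)]


def numpy_qre_hits(seq: str, max_mismatch: int = 1, spacer_min: int = 1,
                   spacer_max: int = 20) -> set[tuple[int, int, int]]:
    """Vectorised mismatch-counting oracle for the bipartite QRE.

    Counts per-position disagreements with the ACUAAY / UAAY half-site
    templates via shifted array comparisons — a different algorithmic route
    from the scanning loop under test. Returns {(offset, spacer, mismatches)}.
    """
    s = np.frombuffer(seq.upper().replace("U", "T").encode(), dtype="S1")
    n = len(s)
    py = (s == b"C") | (s == b"T")

    def mismatch_profile(template: str) -> np.ndarray:
        L = len(template)
        m = n - L + 1
        if m <= 0:
            return np.zeros(0, dtype=int)
        mm = np.zeros(m, dtype=int)
        for i, ch in enumerate(template):
            if ch == "Y":
                mm += ~py[i:i + m]
            else:
                mm += s[i:i + m] != ch.encode()
        return mm

    mm1 = mismatch_profile("ACTAAY")
    mm2 = mismatch_profile("TAAY")
    hits = set()
    for spacer in range(spacer_min, spacer_max + 1):
        shift = 6 + spacer
        span = min(len(mm1), len(mm2) - shift if len(mm2) > shift else 0)
        if span <= 0:
            continue
        total = mm1[:span] + mm2[shift:shift + span]
        for off in np.nonzero(total <= max_mismatch)[0]:
            hits.add((int(off), spacer, int(total[off])))
    return hits


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def gtf_positional_oracle(gtf_path) -> dict:
    """Brute-force exon classification straight from GTF text.

    Rebuilds each transcript's exon list by sorting raw coordinate lines and
    labels every (chrom, start0, end, strand, gene) key cassette / mixed /
    first_last from index positions alone.
    """
    tx_exons: dict[tuple, list] = {}
    for line in open(gtf_path):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if f[2] != "exon":
            continue
        gene = re.search(r'gene_id "([^"]+)"', f[8]).group(1)
        tx = re.search(r'transcript_id "([^"]+)"', f[8]).group(1)
        tx_exons.setdefault((gene, tx), []).append(
            (int(f[3]) - 1, int(f[4]), f[0], f[6]))
    per_exon: dict[tuple, list[bool]] = {}
    for (gene, tx), exons in tx_exons.items():
        exons = sorted(set(exons))
        for i, (s, e, chrom, strand) in enumerate(exons):
            internal = 0 < i < len(exons) - 1
            per_exon.setdefault((chrom, s, e, strand, gene), []).append(internal)
    oracle = {}
    for key, flags in per_exon.items():
        if all(flags):
            oracle[key] = "cassette"
        elif not any(flags):
            oracle[key] = "first_last"
        else:
            oracle[key] = "mixed"
    return oracle


# ---------------------------------------------------------------------------
# shared synthetic dataset


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """One default-scale synthetic dataset shared across tests."""
    outdir = tmp_path_factory.mktemp("synth")
    cfg = SyntheticConfig(seed=101, qre_region_length=4000, n_qre=6)
    truth = generate(cfg, outdir)
    return outdir, truth


@pytest.fixture(scope="session")
def genome(dataset):
    outdir, _ = dataset
    return Fasta(str(outdir / "genome.fa"))


def write_fasta(path, sequences: dict[str, str]) -> Fasta:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")
    return Fasta(str(path))
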