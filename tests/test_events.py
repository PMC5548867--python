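"""rMATS/DEXSeq readers, variant merging and stringent/comprehensive sets."""

import csv
import math

import numpy as np
import pandas as pd
import pytest

from qresplice.annotation import parse_gtf
from qresplice.events import (DEXSEQ, RMATS_COLUMNS, RMATS_JC, RMATS_JCEC,
                              DexseqBin, EventSet, SpliceEvent,
                              annotate_events, build_comprehensive,
                              build_stringent, count_event_genes,
                              merge_rmats_variants, putative_events,
                              read_dexseq, read_rmats, read_rmats_dir)
from qresplice.simulate import SyntheticConfig, generate


def make_event(target=(999, 1100), chrom="chr1", strand="+", gene="g1",
               p=0.001, fdr=0.001, ild=0.3, variant=RMATS_JC,
               upstream=(500, 600), downstream=(1500, 1600),
               event_type="SE"):
    return SpliceEvent(event_type=event_type, chrom=chrom, strand=strand,
                       target=target, upstream=upstream, downstream=downstream,
                       gene_id=gene, stats={variant: (p, fdr)},
                       inclusion_level_difference=ild,
                       sources=frozenset({variant}))


def rmats_df(rows):
    return pd.DataFrame(rows, columns=RMATS_COLUMNS)


class TestReadRmats:
    def test_header_only_gives_empty_list(self, tmp_path):
        p = tmp_path / "SE.txt"
        rmats_df([]).to_csv(p, sep="\t", index=False)
        assert read_rmats(p, "SE", RMATS_JC) == []

    def test_zero_based_exon_start_kept_as_is(self, tmp_path):
        p = tmp_path / "SE.txt"
        rmats_df([{"GeneID": "g", "chr": "chr1", "strand": "+",
                   "exonStart_0base": 999, "exonEnd": 1100,
                   "upstreamES": 500, "upstreamEE": 600,
                   "downstreamES": 1500, "downstreamEE": 1600,
                   "PValue": 0.01, "FDR": 0.02,
                   "IncLevelDifference": 0.4}]).to_csv(p, sep="\t", index=False)
        (ev,) = read_rmats(p, "SE", RMATS_JC)
        assert ev.target == (999, 1100)
        assert ev.sources == {RMATS_JC}
        assert ev.direction == "higher_inclusion"

    def test_non_numeric_pvalue_row_rejected(self, tmp_path):
        p = tmp_path / "SE.txt"
        rows = [{"GeneID": "g", "chr": "chr1", "strand": "+",
                 "exonStart_0base": 10, "exonEnd": 20, "upstreamES": 1,
                 "upstreamEE": 5, "downstreamES": 30, "downstreamEE": 40,
                 "PValue": pv, "FDR": 0.5, "IncLevelDifference": 0.1}
                for pv in (0.2, "broken")]
        rmats_df(rows).to_csv(p, sep="\t", index=False)
        assert len(read_rmats(p, "SE", RMATS_JC)) == 1

    def test_unknown_event_type_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            read_rmats(tmp_path / "x.txt", "NOPE", RMATS_JC)

    def test_synthetic_table_matches_naive_csv_parser(self, dataset):
        """Field-by-field agreement with an independent csv-module parser."""
        outdir, _ = dataset
        path = outdir / "rmats" / "SE.MATS.JC.txt"
        events = read_rmats(path, "SE", RMATS_JC)
        with open(path) as fh:
            naive = list(csv.DictReader(fh, delimiter="\t"))
        assert len(events) == len(naive)
        for ev, row in zip(sorted(events, key=lambda e: (e.chrom, e.target)),
                           sorted(naive, key=lambda r: (r["chr"],
                                  (int(r["exonStart_0base"]),
                                   int(r["exonEnd"]))))):
            assert ev.chrom == row["chr"]
            assert ev.target == (int(row["exonStart_0base"]), int(row["exonEnd"]))
            assert ev.upstream == (int(row["upstreamES"]), int(row["upstreamEE"]))
            assert ev.p_value == pytest.approx(float(row["PValue"]))
            assert ev.inclusion_level_difference == pytest.approx(
                float(row["IncLevelDifference"]))


class TestMergeVariants:
    def test_identical_event_in_both_variants_collapses(self):
        jc = [make_event(variant=RMATS_JC, p=0.01)]
        jcec = [make_event(variant=RMATS_JCEC, p=0.02)]
        (m,) = merge_rmats_variants(jc, jcec)
        assert m.sources == {RMATS_JC, RMATS_JCEC}
        assert m.p_value == 0.01  # headline p is the minimum

    def test_disjoint_events_stay_separate(self):
        a = make_event(target=(100, 200))
        b = make_event(target=(300, 400), upstream=(10, 50),
                       downstream=(500, 550))
        assert len(merge_rmats_variants([a], [b])) == 2

    def test_conflicting_strand_same_coordinates_raises(self):
        a = make_event(strand="+")
        b = make_event(strand="-", variant=RMATS_JCEC)
        with pytest.raises(ValueError, match="strand"):
            merge_rmats_variants([a], [b])

    def test_merge_idempotent(self):
        jc = [make_event(target=(100, 200)), make_event(target=(300, 400),
                                                        upstream=(1, 50),
                                                        downstream=(500, 600))]
        jcec = [make_event(target=(100, 200), variant=RMATS_JCEC)]
        once = merge_rmats_variants(jc, jcec)
        again = merge_rmats_variants(once, [])
        assert {e.key for e in once} == {e.key for e in again}
        assert len(once) == len(again)

    def test_random_tables_match_brute_force_group_count(self):
        rng = np.random.default_rng(0)
        def rand_events(variant, n):
            out = []
            for _ in range(n):
                s = int(rng.integers(0, 50)) * 100
                out.append(make_event(target=(s + 10, s + 60),
                                      upstream=(s, s + 5),
                                      downstream=(s + 70, s + 90),
                                      variant=variant,
                                      p=float(rng.random())))
            return out
        jc, jcec = rand_events(RMATS_JC, 80), rand_events(RMATS_JCEC, 80)
        merged = merge_rmats_variants(jc, jcec)
        distinct = {e.key for e in jc} | {e.key for e in jcec}
        # keys differ only in absent-variant stats, so compare coordinates
        brute = {(e.event_type, e.chrom, e.strand, e.target, e.upstream,
                  e.downstream) for e in jc + jcec}
        assert len(merged) == len(brute)

    def test_putative_uses_fdr_in_either_variant(self):
        good = make_event(p=0.5, fdr=0.01)
        bad = make_event(target=(5000, 5100), p=0.001, fdr=0.5)
        assert putative_events([good, bad]) == [good]


class TestReadDexseq:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "dex.tsv"
        pd.DataFrame(columns=["gene_id", "bin_id", "chrom", "start", "end",
                              "strand", "padj"]).to_csv(p, sep="\t", index=False)
        assert read_dexseq(p) == []

    def test_bin_below_15nt_not_eligible(self):
        assert not DexseqBin("g", "b", "chr1", 100, 114, "+", 0.01).eligible()
        assert DexseqBin("g", "b", "chr1", 100, 115, "+", 0.01).eligible()

    def test_missing_columns_raise(self, tmp_path):
        p = tmp_path / "dex.tsv"
        pd.DataFrame({"gene_id": ["g"], "bin_id": ["b"]}).to_csv(
            p, sep="\t", index=False)
        with pytest.raises(ValueError, match="missing"):
            read_dexseq(p)

    def test_eligibility_matches_length_check_on_synthetic_bins(self, tmp_path):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(200):
            start = int(rng.integers(0, 10000))
            length = int(rng.integers(5, 40))
            rows.append({"gene_id": f"g{i}", "bin_id": f"b{i}", "chrom": "chr1",
                         "start": start, "end": start + length, "strand": "+",
                         "padj": float(rng.random())})
        p = tmp_path / "dex.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        for b, row in zip(read_dexseq(p), rows):
            assert b.eligible() == (row["end"] - row["start"] >= 15)


class TestBuildSets:
    def test_no_significant_bins_gives_empty_stringent(self):
        events = [make_event(p=0.001)]
        bins = [DexseqBin("g", "b", "chr1", 999, 1100, "+", 0.9)]
        assert len(build_stringent(events, bins)) == 0

    def test_single_bp_overlap_retained(self):
        events = [make_event(target=(999, 1100), p=0.001)]
        bins = [DexseqBin("g", "b", "chr1", 1099, 1200, "+", 0.001)]
        s = build_stringent(events, bins)
        assert len(s) == 1
        assert s.events[0].sources >= {RMATS_JC, DEXSEQ}

    def test_adjacent_but_not_overlapping_excluded(self):
        events = [make_event(target=(999, 1100), p=0.001)]
        bins = [DexseqBin("g", "b", "chr1", 1100, 1200, "+", 0.001)]
        assert len(build_stringent(events, bins)) == 0

    def test_stranded_mode_requires_matching_strand(self):
        events = [make_event(strand="+", p=0.001)]
        bins = [DexseqBin("g", "b", "chr1", 999, 1100, "-", 0.001)]
        assert len(build_stringent(events, bins, stranded=True)) == 0
        assert len(build_stringent(events, bins, stranded=False)) == 1

    def test_membership_matches_all_pairs_overlap_oracle(self):
        rng = np.random.default_rng(7)
        events, bins = [], []
        for i in range(300):
            s = int(rng.integers(0, 20000))
            events.append(make_event(target=(s, s + int(rng.integers(20, 200))),
                                     upstream=None, downstream=None,
                                     p=float(rng.random())))
        for i in range(300):
            s = int(rng.integers(0, 20000))
            bins.append(DexseqBin(f"g{i}", f"b{i}", "chr1", s,
                                  s + int(rng.integers(15, 200)), "+",
                                  float(rng.random())))
        got = {e.coord_key for e in build_stringent(events, bins)}
        sig_bins = [b for b in bins if b.adjusted_p < 0.05 and b.eligible()]
        expect = set()
        for ev in events:
            if ev.p_value >= 0.05:
                continue
            for b in sig_bins:  # naive O(n*m) scan
                if b.chrom == ev.chrom and \
                        max(ev.target[0], b.start) < min(ev.target[1], b.end):
                    expect.add(ev.coord_key)
                    break
        assert got == expect

    def test_empty_inputs_give_empty_comprehensive(self):
        assert len(build_comprehensive([], [])) == 0

    def test_dexseq_only_bins_promoted_to_se_events(self):
        bins = [DexseqBin("g", "b", "chr1", 100, 200, "+", 0.001)]
        c = build_comprehensive([], bins)
        assert len(c) == 1
        assert c.events[0].event_type == "SE"
        assert c.events[0].sources == {DEXSEQ}
        assert c.events[0].direction is None

    def test_stringent_subset_of_comprehensive_on_synthetic_data(self, dataset):
        outdir, _ = dataset
        rmats = read_rmats_dir(outdir / "rmats")
        merged = []
        for etype, variants in rmats.items():
            merged.extend(merge_rmats_variants(variants[RMATS_JC],
                                               variants[RMATS_JCEC]))
        bins = read_dexseq(outdir / "dexseq.tsv")
        stringent = build_stringent(merged, bins)
        comp = build_comprehensive(merged, bins)
        comp_keys = {e.coord_key for e in comp}
        assert {e.coord_key for e in stringent} <= comp_keys

    def test_unique_count_matches_dedup_oracle(self, dataset):
        outdir, _ = dataset
        rmats = read_rmats_dir(outdir / "rmats")
        merged = []
        for etype, variants in rmats.items():
            merged.extend(merge_rmats_variants(variants[RMATS_JC],
                                               variants[RMATS_JCEC]))
        bins = read_dexseq(outdir / "dexseq.tsv")
        comp = build_comprehensive(merged, bins)
        sig = {(e.chrom, e.strand, e.target) for e in merged
               if e.fdr is not None and e.fdr < 0.05}
        sig |= {(b.chrom, b.strand, (b.start, b.end)) for b in bins
                if b.adjusted_p < 0.05 and b.eligible()
                and not any(c == b.chrom and t == (b.start, b.end)
                            for c, _, t in sig)}
        assert len(comp) == len(sig)


class TestAnnotateAndCount:
    def test_exact_cassette_match_gets_cassette_class(self, dataset):
        outdir, truth = dataset
        catalog = parse_gtf(outdir / "annotation.gtf")
        truth_cls = {e["exon_id"]: e["exon_class"] for e in truth.as_events}
        rmats = read_rmats_dir(outdir / "rmats")
        merged = merge_rmats_variants(rmats["SE"][RMATS_JC],
                                      rmats["SE"][RMATS_JCEC])
        bins = read_dexseq(outdir / "dexseq.tsv")
        annotated = annotate_events(build_stringent(merged, bins), catalog)
        assert len(annotated) > 0
        for ev in annotated:
            eid = f"{ev.chrom}:{ev.target[0]}-{ev.target[1]}({ev.strand})|{ev.gene_id}"
            if eid in truth_cls:
                assert ev.exon_class.value == truth_cls[eid]

    def test_event_absent_from_catalog_classed_mixed(self, dataset):
        outdir, _ = dataset
        catalog = parse_gtf(outdir / "annotation.gtf")
        orphan = make_event(target=(10, 90), chrom="chr1", upstream=None,
                            downstream=None)
        out = annotate_events(EventSet("stringent", [orphan]), catalog)
        assert out.events[0].exon_class.value == "mixed"

    def test_gene_count(self):
        evs = [make_event(gene="gA"), make_event(gene="gA",
                                                 target=(2000, 2100)),
               make_event(gene="gB", target=(3000, 3100))]
        assert count_event_genes(EventSet("x", evs)) == 2
        assert count_event_genes(EventSet("x", [])) == 0

    def test_tally_counts_match_recount(self, dataset):
        outdir, _ = dataset
        catalog = parse_gtf(outdir / "annotation.gtf")
        rmats = read_rmats_dir(outdir / "rmats")
        merged = []
        for etype, variants in rmats.items():
            merged.extend(merge_rmats_variants(variants[RMATS_JC],
                                               variants[RMATS_JCEC]))
        bins = read_dexseq(outdir / "dexseq.tsv")
        comp = annotate_events(build_comprehensive(merged, bins), catalog)
        tally = comp.tally()
        assert tally["count"].sum() == len(comp)
        se_total = tally.loc[tally.event_type == "SE", "count"].sum()
        assert se_total == sum(1 for e in comp if e.event_type == "SE")


def test_rerun_produces_byte_identical_tsv(dataset, tmp_path):
    outdir, _ = dataset
    rmats = read_rmats_dir(outdir / "rmats")
    merged = merge_rmats_variants(rmats["SE"][RMATS_JC], rmats["SE"][RMATS_JCEC])
    bins = read_dexseq(outdir / "dexseq.tsv")
    for i in (1, 2):
        build_stringent(merged, bins).to_tsv(tmp_path / f"s{i}.tsv")
    assert (tmp_path / "s1.tsv").read_bytes() == (tmp_path / "s2.tsv").read_bytes()
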