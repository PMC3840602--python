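"""TxPos arithmetic, containment, compartment labels and table construction."""

import numpy as np
import pytest

from promstr import (
    STRRecord,
    build_repeat_table,
    classify_compartments,
    contained_in_regulatory,
    overlaps_entity,
    regulatory_window,
    tx_pos,
)
from promstr.mapping import TABLE_COLUMNS
from promstr.records import compute_entropy, round_half_up

from conftest import make_gene


def make_str(chrom="chr1", start=0, end=30, period=2, purity=100, motif="AC"):
    length = end - start
    return STRRecord(
        chrom=chrom,
        srStart=start,
        srEnd=end,
        period=period,
        numRepeats=round_half_up(length / period, 1),
        consensusSize=period,
        perMatch=purity,
        perIndel=0,
        score=2 * length,
        baseA=50,
        baseC=50,
        baseG=0,
        baseT=0,
        entropy=compute_entropy(0.5, 0.5, 0, 0),
        sequence=motif,
    )


class TestTxPos:
    def test_plus_strand_upstream(self):
        gene = make_gene(strand="+", tx=(1102483, 1102578))
        rec = make_str(start=1101897, end=1101928, period=6)
        assert tx_pos(rec, gene) == -586

    def test_minus_strand_uses_transcript_orientation_start(self):
        gene = make_gene(strand="-", tx=(28218048, 28241236))
        rec = make_str(start=28243107, end=28243146)
        assert tx_pos(rec, gene) == -1910

    def test_str_at_tss_is_zero(self):
        gene = make_gene(strand="+", tx=(5_000, 9_000))
        assert tx_pos(make_str(start=5_000, end=5_030), gene) == 0

    def test_chromosome_mismatch_rejected(self):
        gene = make_gene(chrom="chr2", tx=(5_000, 9_000))
        with pytest.raises(ValueError, match="mismatch"):
            tx_pos(make_str(chrom="chr1"), gene)

    def test_round_trip_reconstructs_start_on_both_strands(self):
        for strand in "+-":
            gene = make_gene(strand=strand, tx=(50_000, 60_000))
            rec = make_str(start=49_000, end=49_040)
            t = tx_pos(rec, gene)
            if strand == "+":
                assert gene.txStart + t == rec.srStart
            else:
                assert gene.txEnd - t - rec.srLength == rec.srStart

    def test_reverse_complement_leaves_txpos_unchanged(self, sim):
        """Mirroring the whole chromosome (reverse complement plus flipped
        annotations) preserves every TxPos."""
        L = sim.config.chrom_length
        checked = 0
        genes = {g.transcriptId: g for g in sim.genes}
        for t in sim.truth:
            if t.gene_id is None:
                continue
            gene = genes[t.gene_id]
            rec = t.record
            flipped_gene = make_gene(
                strand="-" if gene.strand == "+" else "+",
                chrom=gene.chrom,
                tx=(L - gene.txEnd, L - gene.txStart),
                cds=(L - gene.cdsEnd, L - gene.cdsStart),
                exons=[(L - e, L - s) for s, e in reversed(gene.exons)],
            )
            flipped_rec = make_str(
                chrom=rec.chrom, start=L - rec.srEnd, end=L - rec.srStart
            )
            assert tx_pos(rec, gene) == tx_pos(flipped_rec, flipped_gene)
            checked += 1
        assert checked >= 100


class TestContainment:
    def test_fully_inside_window(self):
        gene = make_gene(strand="+", tx=(1102483, 1102578))
        region = regulatory_window(gene)
        assert contained_in_regulatory(make_str(start=1101897, end=1101928), region)

    def test_straddling_window_start_excluded(self):
        gene = make_gene(strand="+", tx=(10_000, 20_000))
        region = regulatory_window(gene)  # [8000, 11000)
        assert not contained_in_regulatory(make_str(start=7_999, end=8_029), region)

    def test_str_equal_to_window_included(self):
        gene = make_gene(strand="+", tx=(10_000, 20_000))
        region = regulatory_window(gene)
        assert contained_in_regulatory(make_str(start=8_000, end=11_000), region)


class TestOverlap:
    def test_single_base_intersection(self):
        assert overlaps_entity(make_str(start=100, end=130), [(129, 200)])

    def test_adjacent_half_open_intervals_do_not_overlap(self):
        assert not overlaps_entity(make_str(start=100, end=130), [(130, 200)])

    def test_contained_interval_overlaps(self):
        assert overlaps_entity(make_str(start=100, end=130), [(50, 500)])


class TestClassify:
    def test_span_touching_core_window(self):
        gene = make_gene(strand="+", tx=(10_000, 20_000))
        rec = make_str(start=9_900, end=9_941)  # TxPos span [-100, -60]
        labels = classify_compartments(-100, rec, gene)
        assert {
            "upstream",
            "proximal_promoter",
            "core_promoter",
            "regulatory_region",
        } <= labels

    def test_upstream_only_outside_proximal(self):
        gene = make_gene(strand="+", tx=(1102483, 1102578), cds=(1102483, 1102483))
        rec = make_str(start=1101897, end=1101928)  # TxPos [-586, -556]
        labels = classify_compartments(-586, rec, gene)
        assert "upstream" in labels and "regulatory_region" in labels
        assert "proximal_promoter" not in labels
        assert "core_promoter" not in labels

    def test_exonic_utr_str_downstream_of_tss(self):
        # STR at TxPos [183, 207] inside the first exon, CDS starts later
        gene = make_gene(
            strand="+",
            tx=(2487804, 2495188),
            cds=(2488050, 2495000),
            exons=[(2487804, 2488100), (2494000, 2495188)],
        )
        rec = make_str(start=2487987, end=2488012, period=6)
        labels = classify_compartments(183, rec, gene)
        assert labels >= {
            "regulatory_region",
            "proximal_promoter",
            "five_prime_utr",
            "exon",
        }
        assert "upstream" not in labels and "intron" not in labels


class TestBuildTable:
    def test_str_in_two_windows_yields_two_rows(self):
        g1 = make_gene(
            "NR_029639", symbol="MIR200B", strand="+",
            tx=(1102483, 1102578), cds=(1102578, 1102578),
        )
        g2 = make_gene(
            "NR_029834", symbol="MIR200A", strand="+",
            tx=(1103242, 1103332), cds=(1103332, 1103332),
        )
        rec = make_str(start=1101897, end=1101928, period=6)
        table, counts = build_repeat_table(
            [rec], [regulatory_window(g) for g in (g1, g2)]
        )
        assert len(table) == 2
        assert sorted(table["txPos"]) == [-1345, -586]
        assert counts["rows"] == 2 and counts["after_containment"] == 1

    def test_low_purity_excluded(self):
        gene = make_gene(tx=(10_000, 20_000))
        rec = make_str(start=9_000, end=9_030, purity=89)
        table, counts = build_repeat_table([rec], [regulatory_window(gene)])
        assert len(table) == 0 and counts["after_purity"] == 0

    def test_two_strs_one_gene(self):
        gene = make_gene("NM_025106", symbol="SPSB1", strand="+", tx=(9352940, 9429590))
        recs = [
            make_str(start=9351235, end=9351260, period=1),
            make_str(start=9352783, end=9352812, period=7),
        ]
        table, counts = build_repeat_table(recs, [regulatory_window(gene)])
        assert len(table) == 2
        assert sorted(table["txPos"]) == [-1705, -157]
        assert counts["genes"] == 1

    def test_column_order_matches_contract(self, truth_table):
        table, _ = truth_table
        assert list(table.columns) == TABLE_COLUMNS

    def test_rows_satisfy_containment_invariant(self, truth_table):
        table, _ = truth_table
        assert (table["txPos"] >= -2000).all()
        assert (table["txPos"] + table["srLength"] <= 1000).all()
        assert (table["srEnd"] - table["srStart"] == table["srLength"]).all()

    def test_row_count_invariant_to_input_order(self, sim):
        recs = sim.truth_records()
        fwd, _ = build_repeat_table(recs, sim.regions)
        rev, _ = build_repeat_table(recs[::-1], list(reversed(sim.regions)))
        assert fwd.equals(rev)

    def test_filter_counts_monotone(self, truth_table):
        _, counts = truth_table
        chain = ["input_strs", "after_purity", "after_period", "after_containment"]
        values = [counts[k] for k in chain]
        assert values == sorted(values, reverse=True)
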