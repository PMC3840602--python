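"""Gene sets, intron density quartile, hypergeometric test and BH-FDR."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from promstr import (
    GeneSet,
    bh_fdr,
    exonic_gene_set,
    high_density_quartile,
    hypergeometric_enrichment,
    intron_kb_per_str,
    majority_consensus,
    random_gene_samples,
    table_gene_set,
)
from promstr.enrichment import intron_density_table

from conftest import make_gene
from test_mapping import make_str


class TestGeneSets:
    def test_duplicate_rows_collapse_to_one_gene(self, truth_table):
        table, counts = truth_table
        gs = table_gene_set(table)
        assert len(gs) == counts["genes"] <= counts["rows"]

    def test_empty_table_empty_set(self):
        assert len(table_gene_set(pd.DataFrame(columns=["hgncSymbol"]))) == 0

    def test_exonic_set_ignores_purity(self):
        gene = make_gene(symbol="G1", tx=(1_000, 2_000), exons=[(1_000, 2_000)])
        low = make_str(start=1_100, end=1_130, purity=85)
        assert "G1" in exonic_gene_set([low], [gene]).genes

    def test_intron_only_gene_excluded_from_exonic_set(self):
        gene = make_gene(
            symbol="G1", tx=(1_000, 3_000), exons=[(1_000, 1_200), (2_800, 3_000)]
        )
        intronic = make_str(start=1_500, end=1_530)
        assert len(exonic_gene_set([intronic], [gene])) == 0

    def test_boundary_spanning_str_included(self):
        gene = make_gene(
            symbol="G1", tx=(1_000, 3_000), exons=[(1_000, 1_200), (2_800, 3_000)]
        )
        spanning = make_str(start=1_190, end=1_220)
        assert "G1" in exonic_gene_set([spanning], [gene]).genes


class TestIntronDensity:
    def gene_with_intron(self, width=14_640):
        return make_gene(
            symbol="G1",
            tx=(10_000, 10_000 + width + 400),
            exons=[(10_000, 10_200), (10_200 + width, 10_400 + width)],
            cds=(10_050, 10_300 + width),
        )

    def test_kb_per_str_arithmetic(self):
        gene = self.gene_with_intron(14_640)
        strs = [
            make_str(start=12_000, end=12_030),
            make_str(start=14_000, end=14_030),
        ]
        assert intron_kb_per_str(gene, strs) == pytest.approx(7.32)

    def test_low_purity_intronic_strs_not_counted(self):
        gene = self.gene_with_intron(5_000)
        strs = [
            make_str(start=12_000, end=12_030, purity=100),
            make_str(start=13_000, end=13_030, purity=85),
        ]
        assert intron_kb_per_str(gene, strs) == pytest.approx(5.0)

    def test_gene_without_qualifying_strs_absent(self):
        gene = self.gene_with_intron(5_000)
        assert intron_kb_per_str(gene, []) is None
        assert len(intron_density_table([gene], [])) == 0


class TestQuartile:
    def test_interpolated_threshold_on_1_to_8(self):
        dens = pd.Series({f"G{i}": float(i) for i in range(1, 9)})
        gs = high_density_quartile(dens)
        assert gs.genes == {"G1", "G2"}  # 25th percentile of 1..8 is 2.75

    def test_all_equal_densities_selects_all(self):
        dens = pd.Series({f"G{i}": 3.0 for i in range(6)})
        assert len(high_density_quartile(dens)) == 6

    def test_fewer_than_four_genes_returns_all_with_warning(self, caplog):
        dens = pd.Series({"G0": 1.0, "G1": 2.0})
        with caplog.at_level("WARNING"):
            assert len(high_density_quartile(dens)) == 2

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_selection_fraction_bound(self, seed):
        """Selected fraction lies in [25%, 25% + tie share] (n % 4 == 0)."""
        rng = np.random.default_rng(seed)
        n = 40
        values = rng.integers(1, 10, size=n).astype(float)
        dens = pd.Series(values, index=[f"G{i}" for i in range(n)])
        gs = high_density_quartile(dens)
        threshold = gs.provenance["threshold"]
        ties = (values == threshold).sum()
        frac = len(gs) / n
        assert 0.25 - 1e-9 <= frac <= 0.25 + ties / n + 1e-9


class TestRandomSamples:
    POOL = GeneSet("pool", frozenset(f"G{i:03d}" for i in range(100)))

    def test_full_size_sample_equals_pool(self):
        for s in random_gene_samples(self.POOL, 100, k=3, seed=5):
            assert s.genes == self.POOL.genes

    def test_same_seed_reproduces_samples(self):
        a = random_gene_samples(self.POOL, 10, k=10, seed=11)
        b = random_gene_samples(self.POOL, 10, k=10, seed=11)
        assert [s.genes for s in a] == [s.genes for s in b]

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            random_gene_samples(self.POOL, 101)

    def test_inclusion_frequency_binomial(self):
        """Per-gene inclusion over 1000 draws of 10 from 100 is 0.10
        within three standard errors."""
        samples = random_gene_samples(self.POOL, 10, k=1000, seed=42)
        freq = pd.Series(
            [g for s in samples for g in s.genes]
        ).value_counts() / 1000.0
        se = math.sqrt(0.1 * 0.9 / 1000)
        assert ((freq - 0.10).abs() <= 3 * se).all()


def exhaustive_hypergeom_tail(N, K, n, k):
    """P(X >= k) by enumerating all C(N, n) draws (oracle, N <= 12)."""
    items = [1] * K + [0] * (N - K)
    hits = total = 0
    for combo in itertools.combinations(range(N), n):
        total += 1
        if sum(items[i] for i in combo) >= k:
            hits += 1
    return hits / total


class TestHypergeometric:
    BG = GeneSet("bg", frozenset(f"G{i}" for i in range(20)))

    def run_one(self, set_genes, term_genes):
        gs = GeneSet("s", frozenset(set_genes))
        res = hypergeometric_enrichment(gs, self.BG, {"T": set(term_genes)})
        return res.iloc[0]

    def test_term_covering_background_is_null(self):
        row = self.run_one([f"G{i}" for i in range(5)], self.BG.genes)
        assert row["fold"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(1.0)

    def test_perfect_overlap_matches_closed_form(self):
        genes = [f"G{i}" for i in range(5)]
        row = self.run_one(genes, genes)
        assert row["fold"] == pytest.approx(4.0)
        assert row["p"] == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_zero_hits_has_p_one(self):
        row = self.run_one([f"G{i}" for i in range(5)], [f"G{i}" for i in range(10, 15)])
        assert row["k"] == 0 and row["fold"] == 0.0
        assert row["p"] == pytest.approx(1.0)

    def test_non_subset_rejected(self):
        outside = GeneSet("s", frozenset(["NOT_IN_BG"]))
        with pytest.raises(ValueError):
            hypergeometric_enrichment(outside, self.BG, {"T": set()})

    @pytest.mark.parametrize(
        "N,K,n", [(8, 3, 4), (10, 5, 5), (12, 4, 6), (11, 6, 3)]
    )
    def test_matches_exhaustive_enumeration(self, N, K, n):
        """p-values equal exact enumeration over all C(N, n) draws."""
        rng = np.random.default_rng(N * 100 + K)
        symbols = [f"G{i}" for i in range(N)]
        bg = GeneSet("bg", frozenset(symbols))
        term = set(rng.choice(symbols, size=K, replace=False))
        chosen = frozenset(rng.choice(symbols, size=n, replace=False))
        res = hypergeometric_enrichment(GeneSet("s", chosen), bg, {"T": term})
        k = res.iloc[0]["k"]
        assert res.iloc[0]["p"] == pytest.approx(
            exhaustive_hypergeom_tail(N, K, n, int(k)), rel=1e-12
        )


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]).tolist() == [0.03]

    def test_step_up_hand_example(self):
        # q_i = min_{j>=i} p_j * m / j over the sorted values
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_matches_reference_implementation(self):
        """Agreement with the statsmodels BH routine to 1e-12 on 100
        random p-vectors."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(123)
        for _ in range(100):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m)
            ours = bh_fdr(p)
            _, ref, _, _ = multipletests(p, method="fdr_bh")
            assert np.max(np.abs(ours - ref)) < 1e-12


class TestMajorityConsensus:
    @staticmethod
    def frame(sig_terms, all_terms=("T0", "T1", "T2")):
        return pd.DataFrame(
            {
                "term": all_terms,
                "fdr": [0.01 if t in sig_terms else 0.5 for t in all_terms],
            }
        )

    def test_six_of_ten_reported(self):
        results = [self.frame(["T0"])] * 6 + [self.frame([])] * 4
        assert majority_consensus(results) == ["T0"]

    def test_five_of_ten_not_reported(self):
        results = [self.frame(["T0"])] * 5 + [self.frame([])] * 5
        assert majority_consensus(results) == []

    def test_degenerate_single_list_is_plain_filter(self):
        results = [self.frame(["T1", "T2"])]
        assert majority_consensus(results, min_agree=1) == ["T1", "T2"]
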