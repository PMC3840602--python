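"""Gene-set construction and hypergeometric over-representation.

Gene sets mirror the comparison design of the study: genes with a
table-qualifying STR in the TSS window, genes with any exonic STR
(regardless of purity), the highest-density quartile of intronic-STR
genes (fewest kb of intron per high-purity STR), and random intron-gene
samples of matched size.  Over-representation uses the hypergeometric
upper tail with Benjamini-Hochberg FDR and a majority-consensus rule
across the random samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .genes import GeneModel, gene_compartments
from .mapping import overlaps_entity
from .records import STRRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "table_gene_set",
    "exonic_gene_set",
    "intron_kb_per_str",
    "intron_density_table",
    "high_density_quartile",
    "random_gene_samples",
    "hypergeometric_enrichment",
    "bh_fdr",
    "majority_consensus",
]

RESULT_COLUMNS = ["term", "k", "K", "n", "N", "fold", "p", "fdr"]


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]
    provenance: dict = field(default_factory=dict, compare=False)

    def __len__(self) -> int:
        return len(self.genes)


def table_gene_set(table: pd.DataFrame, name: str = "regulatory") -> GeneSet:
    """Unique gene loci with at least one repeat-table row."""
    genes = frozenset(table["hgncSymbol"].unique()) if len(table) else frozenset()
    return GeneSet(name=name, genes=genes, provenance={"rows": int(len(table))})


def exonic_gene_set(
    strs: list[STRRecord], genes: list[GeneModel], name: str = "exonic"
) -> GeneSet:
    """Genes whose exons overlap >= 1 STR, with NO purity filter."""
    hit = set()
    for gene in genes:
        exons = gene_compartments(gene)["exons"]
        for rec in strs:
            if rec.chrom == gene.chrom and overlaps_entity(rec, exons):
                hit.add(gene.geneSymbol)
                break
    return GeneSet(name=name, genes=frozenset(hit), provenance={"purity_filter": None})


def intron_kb_per_str(
    gene: GeneModel, strs: list[STRRecord], min_purity: float = 90.0
) -> float | None:
    """Kilobases of intron per high-purity intronic STR; None without STRs.

    Smaller values mean denser intronic repeat content.
    """
    introns = gene_compartments(gene)["introns"]
    width = sum(e - s for s, e in introns)
    n = sum(
        1
        for rec in strs
        if rec.chrom == gene.chrom
        and rec.perMatch >= min_purity
        and overlaps_entity(rec, introns)
    )
    if n == 0:
        return None
    return (width / 1000.0) / n


def intron_density_table(
    genes: list[GeneModel], strs: list[STRRecord], min_purity: float = 90.0
) -> pd.Series:
    """kb-per-STR for every gene with >= 1 qualifying intronic STR."""
    data = {}
    by_chrom: dict[str, list[STRRecord]] = {}
    for rec in strs:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    for gene in genes:
        kb = intron_kb_per_str(gene, by_chrom.get(gene.chrom, []), min_purity)
        if kb is not None:
            data[gene.geneSymbol] = kb
    return pd.Series(data, dtype=float, name="kb_per_str").sort_index()


def high_density_quartile(
    gene_densities: pd.Series, quartile: float = 0.25, name: str = "intron_dense"
) -> GeneSet:
    """Genes at or below the 25th percentile of kb-per-STR (densest quartile).

    The percentile uses linear interpolation; boundary ties are included,
    so the selected fraction lies in [quartile, quartile + tie share].
    """
    if len(gene_densities) < 4:
        logger.warning(
            "fewer than 4 genes in the intron density table; returning all"
        )
        return GeneSet(
            name=name,
            genes=frozenset(gene_densities.index),
            provenance={"quartile": quartile, "threshold": None},
        )
    threshold = float(gene_densities.quantile(quartile, interpolation="linear"))
    sel = gene_densities[gene_densities <= threshold]
    return GeneSet(
        name=name,
        genes=frozenset(sel.index),
        provenance={"quartile": quartile, "threshold": threshold},
    )


def random_gene_samples(
    pool: GeneSet, size: int, k: int = 10, seed: int = 0
) -> list[GeneSet]:
    """k uniform without-replacement samples of `size` genes from the pool."""
    if size > len(pool):
        raise ValueError(f"sample size {size} exceeds pool size {len(pool)}")
    rng = np.random.default_rng(seed)
    ordered = sorted(pool.genes)
    out = []
    for i in range(k):
        draw = rng.choice(len(ordered), size=size, replace=False)
        out.append(
            GeneSet(
                name=f"{pool.name}_sample{i}",
                genes=frozenset(ordered[j] for j in draw),
                provenance={"pool": pool.name, "size": size, "seed": seed, "index": i},
            )
        )
    return out


def hypergeometric_enrichment(
    gene_set: GeneSet,
    background: GeneSet,
    term_map: dict[str, set[str]],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per term.

    For a term annotating K of N background genes with k hits in the
    n-gene set: fold = (k/n)/(K/N) and p = P(X >= k) for
    X ~ Hypergeom(N, K, n).  Terms with no background genes are skipped.
    The fdr column is the BH adjustment over the tested terms.
    """
    if not gene_set.genes <= background.genes:
        raise ValueError("gene set is not a subset of the background")
    N = len(background)
    n = len(gene_set)
    rows = []
    for term in sorted(term_map):
        annotated = term_map[term] & background.genes
        K = len(annotated)
        if K == 0:
            continue
        k = len(gene_set.genes & annotated)
        fold = (k / n) / (K / N) if n else 0.0
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "fold": fold, "p": p})
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-1])
    df["fdr"] = bh_fdr(df["p"].to_numpy()) if len(df) else []
    return df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def majority_consensus(
    results: list[pd.DataFrame], alpha: float = 0.05, min_agree: int = 6
) -> list[str]:
    """Terms significant (fdr < alpha) in at least min_agree result lists."""
    tally: dict[str, int] = {}
    for df in results:
        sig = df.loc[df["fdr"] < alpha, "term"]
        for term in sig:
            tally[term] = tally.get(term, 0) + 1
    return sorted(t for t, c in tally.items() if c >= min_agree)
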