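"""Join STRs to TSS regulatory windows and build the repeat table.

TxPos is the STR start relative to the TSS in transcript orientation
(negative = upstream): srStart - txStart on the + strand and
txEnd - srEnd on the - strand.  Table membership requires the STR to be
fully contained in the window; compartment subsets (exon, intron, 5'-UTR,
promoter windows) use the any-overlap rule.  Both rules are implemented
separately and never mixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .genes import GeneModel, RegulatoryRegion, gene_compartments
from .records import STRRecord, ScoringParams

logger = logging.getLogger(__name__)

__all__ = [
    "TABLE_COLUMNS",
    "PROMOTER_LABELS",
    "tx_pos",
    "contained_in_regulatory",
    "overlaps_entity",
    "classify_compartments",
    "build_repeat_table",
]

#: Output column order of the repeat table.
TABLE_COLUMNS = [
    "Chrom",
    "chromStart",
    "chromEnd",
    "cdsStart",
    "cdsEnd",
    "Strand",
    "knownGeneId",
    "refSeqId",
    "ensGeneId",
    "sourceAcc",
    "hgncSymbol",
    "U133Id",
    "U133Plus2Id",
    "Category",
    "txPos",
    "srStart",
    "srEnd",
    "Period",
    "numRepeats",
    "srLength",
    "consensusSize",
    "perMatch",
    "perIndel",
    "Score",
    "A",
    "C",
    "G",
    "T",
    "Entropy",
    "Sequence",
]

#: Promoter compartments as inclusive TxPos windows; upstream/regulatory
#: bounds adapt to the configured window size.
PROMOTER_LABELS = ("upstream", "proximal_promoter", "core_promoter", "regulatory_region")


def tx_pos(rec: STRRecord, gene: GeneModel) -> int:
    """TSS-relative start of the STR in transcript orientation."""
    if rec.chrom != gene.chrom:
        raise ValueError(
            f"chromosome mismatch: STR on {rec.chrom}, gene on {gene.chrom}"
        )
    if gene.strand == "+":
        return rec.srStart - gene.txStart
    return gene.txEnd - rec.srEnd


def contained_in_regulatory(rec: STRRecord, region: RegulatoryRegion) -> bool:
    """Full containment: both STR ends inside the half-open window."""
    if rec.chrom != region.gene.chrom:
        return False
    return rec.srStart >= region.windowStart and rec.srEnd <= region.windowEnd


def overlaps_entity(rec: STRRecord, intervals) -> bool:
    """Any-overlap rule: >= 1 bp intersection with any half-open interval."""
    return any(
        min(rec.srEnd, e) > max(rec.srStart, s) for s, e in intervals
    )


def _promoter_windows(up: int, down: int) -> dict[str, tuple[int, int]]:
    return {
        "upstream": (-up, -1),
        "proximal_promoter": (-250, 250),
        "core_promoter": (-60, 40),
        "regulatory_region": (-up, down),
    }


def classify_compartments(
    txpos: int,
    rec: STRRecord,
    gene: GeneModel,
    up: int = 2000,
    down: int = 1000,
) -> set[str]:
    """Non-exclusive compartment labels for one (STR, gene) pair.

    Promoter labels compare the inclusive TxPos span
    [txPos, txPos + srLength - 1] with the inclusive promoter windows;
    genic labels (exon, intron, five_prime_utr) use genomic overlap with
    the gene's compartment intervals.
    """
    labels: set[str] = set()
    span = (txpos, txpos + rec.srLength - 1)
    for name, (lo, hi) in _promoter_windows(up, down).items():
        if span[0] <= hi and span[1] >= lo:
            labels.add(name)
    comps = gene_compartments(gene)
    if overlaps_entity(rec, comps["exons"]):
        labels.add("exon")
    if overlaps_entity(rec, comps["introns"]):
        labels.add("intron")
    if overlaps_entity(rec, comps["five_utr"]):
        labels.add("five_prime_utr")
    return labels


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=TABLE_COLUMNS)


def build_repeat_table(
    strs: list[STRRecord],
    regions: list[RegulatoryRegion],
    params: ScoringParams | None = None,
    id_map: dict[str, dict[str, str]] | None = None,
    up: int = 2000,
    down: int = 1000,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Build the repeat table: one row per (STR, canonical transcript) pair.

    STRs are filtered to period <= max_period and purity >= min_purity,
    then joined to every regulatory window that fully contains them (an
    STR inside two genes' windows yields two rows).  Returns the table in
    the documented 30-column order plus per-stage filter counts.
    """
    params = params or ScoringParams()
    id_map = id_map or {}
    counts = {"input_strs": len(strs)}
    kept = [s for s in strs if s.perMatch >= params.min_purity]
    counts["after_purity"] = len(kept)
    kept = [s for s in kept if s.period <= params.max_period]
    counts["after_period"] = len(kept)

    by_chrom: dict[str, list[RegulatoryRegion]] = {}
    for region in regions:
        by_chrom.setdefault(region.gene.chrom, []).append(region)
    for group in by_chrom.values():
        group.sort(key=lambda r: (r.windowStart, r.gene.transcriptId))

    rows = []
    contained = 0
    for rec in kept:
        hit = False
        for region in by_chrom.get(rec.chrom, ()):
            if not contained_in_regulatory(rec, region):
                continue
            hit = True
            gene = region.gene
            ids = id_map.get(gene.transcriptId, {})
            rows.append(
                {
                    "Chrom": gene.chrom,
                    "chromStart": gene.txStart,
                    "chromEnd": gene.txEnd,
                    "cdsStart": gene.cdsStart,
                    "cdsEnd": gene.cdsEnd,
                    "Strand": gene.strand,
                    "knownGeneId": ids.get("knownGeneId", ""),
                    "refSeqId": gene.transcriptId,
                    "ensGeneId": ids.get("ensGeneId", ""),
                    "sourceAcc": ids.get("sourceAcc", ""),
                    "hgncSymbol": gene.geneSymbol,
                    "U133Id": ids.get("U133Id", ""),
                    "U133Plus2Id": ids.get("U133Plus2Id", ""),
                    "Category": gene.category,
                    "txPos": tx_pos(rec, gene),
                    "srStart": rec.srStart,
                    "srEnd": rec.srEnd,
                    "Period": rec.period,
                    "numRepeats": rec.numRepeats,
                    "srLength": rec.srLength,
                    "consensusSize": rec.consensusSize,
                    "perMatch": rec.perMatch,
                    "perIndel": rec.perIndel,
                    "Score": rec.score,
                    "A": rec.baseA,
                    "C": rec.baseC,
                    "G": rec.baseG,
                    "T": rec.baseT,
                    "Entropy": rec.entropy,
                    "Sequence": rec.sequence,
                }
            )
        contained += int(hit)
    counts["after_containment"] = contained
    counts["rows"] = len(rows)
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS) if rows else _empty_table()
    if len(table):
        table = table.sort_values(
            ["Chrom", "chromStart", "srStart", "refSeqId"], kind="mergesort"
        ).reset_index(drop=True)
    counts["genes"] = int(table["hgncSymbol"].nunique()) if len(table) else 0
    logger.info("repeat table filter counts: %s", counts)
    return table, counts
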