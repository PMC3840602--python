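"""Gene models, canonical transcript selection and TSS regulatory windows.

Coordinates are 0-based half-open throughout.  The transcription start
site (TSS) is txStart on the + strand and txEnd on the - strand; the
regulatory window spans `up` bases upstream to `down` bases downstream of
the TSS in transcript orientation (-2000..+1000 at defaults).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "RegulatoryRegion",
    "GeneTableError",
    "read_gene_table",
    "exclude_nonprimary",
    "select_canonical",
    "regulatory_window",
    "gene_compartments",
    "flag_cpg_overlap",
]


class GeneTableError(ValueError):
    """Structural parse failure in a gene table (names the line)."""


@dataclass
class GeneModel:
    """One transcript: bounds, CDS, exon structure and identifiers."""

    transcriptId: str
    geneSymbol: str
    chrom: str
    strand: str
    txStart: int
    txEnd: int
    cdsStart: int
    cdsEnd: int
    exonStarts: tuple[int, ...]
    exonEnds: tuple[int, ...]

    @property
    def category(self) -> str:
        return "noncoding" if self.cdsStart == self.cdsEnd else "coding"

    @property
    def tss(self) -> int:
        return self.txStart if self.strand == "+" else self.txEnd

    @property
    def exons(self) -> list[tuple[int, int]]:
        return list(zip(self.exonStarts, self.exonEnds))

    def violations(self) -> list[str]:
        out = []
        if self.strand not in "+-":
            out.append(f"strand {self.strand!r} not in {{+,-}}")
        if not self.txStart < self.txEnd:
            out.append(f"txStart {self.txStart} >= txEnd {self.txEnd}")
        if not self.txStart <= self.cdsStart <= self.cdsEnd <= self.txEnd:
            out.append("CDS bounds not nested in transcription bounds")
        if len(self.exonStarts) != len(self.exonEnds) or not self.exonStarts:
            out.append("exon start/end lists empty or of unequal length")
        else:
            prev_end = self.txStart - 1
            for s, e in self.exons:
                if s >= e:
                    out.append(f"exon [{s}, {e}) is empty or inverted")
                if s <= prev_end:
                    out.append("exons unsorted or overlapping")
                prev_end = e
            if self.exonStarts[0] < self.txStart or self.exonEnds[-1] > self.txEnd:
                out.append("exons extend beyond transcription bounds")
        return out


@dataclass
class RegulatoryRegion:
    """A gene's TSS window: [windowStart, windowEnd) on the genome."""

    gene: GeneModel
    tss: int
    windowStart: int
    windowEnd: int
    cpgOverlap: bool = False

    @property
    def interval(self) -> tuple[int, int]:
        return (self.windowStart, self.windowEnd)


def _parse_coord_list(text: str, line_no: int, path: str) -> tuple[int, ...]:
    try:
        return tuple(int(x) for x in text.strip().rstrip(",").split(",") if x != "")
    except ValueError as exc:
        raise GeneTableError(
            f"{path}:{line_no}: malformed coordinate list {text!r}"
        ) from exc


def read_gene_table(path: str) -> list[GeneModel]:
    """Parse a genePred-like TSV into validated GeneModels.

    Expected columns: name, chrom, strand, txStart, txEnd, cdsStart,
    cdsEnd, exonCount, exonStarts, exonEnds and optionally geneSymbol.
    Rows violating model invariants are rejected with a logged reason;
    structurally malformed rows raise GeneTableError naming the line.
    """
    genes: list[GeneModel] = []
    first_data = True
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise GeneTableError(
                    f"{path}:{line_no}: expected >= 10 tab-separated columns, "
                    f"got {len(fields)}"
                )
            if first_data and not fields[3].lstrip("-").isdigit():
                first_data = False
                continue  # header row
            first_data = False
            try:
                gene = GeneModel(
                    transcriptId=fields[0],
                    geneSymbol=fields[10] if len(fields) > 10 and fields[10] else fields[0],
                    chrom=fields[1],
                    strand=fields[2],
                    txStart=int(fields[3]),
                    txEnd=int(fields[4]),
                    cdsStart=int(fields[5]),
                    cdsEnd=int(fields[6]),
                    exonStarts=_parse_coord_list(fields[8], line_no, path),
                    exonEnds=_parse_coord_list(fields[9], line_no, path),
                )
            except GeneTableError:
                raise
            except ValueError as exc:
                raise GeneTableError(f"{path}:{line_no}: {exc}") from exc
            problems = gene.violations()
            if problems:
                logger.warning(
                    "rejecting %s at %s:%d: %s",
                    gene.transcriptId,
                    path,
                    line_no,
                    "; ".join(problems),
                )
                continue
            genes.append(gene)
    return genes


def exclude_nonprimary(genes: list[GeneModel]) -> list[GeneModel]:
    """Drop models on haplotype/random/unplaced contigs (chrom contains '_')."""
    return [g for g in genes if "_" not in g.chrom]


def select_canonical(
    genes: list[GeneModel], canonical_ids: list[str] | None = None
) -> list[GeneModel]:
    """One transcript per gene locus (geneSymbol as locus proxy).

    An explicit canonical-id list wins when it names a present transcript;
    otherwise the longest genomic span is chosen, ties broken by the
    lexicographically smallest transcriptId.  Deterministic and invariant
    to input order.
    """
    wanted = set(canonical_ids or ())
    missing = wanted - {g.transcriptId for g in genes}
    if missing:
        logger.warning(
            "canonical ids absent from the gene table (fallback rule applies): %s",
            ", ".join(sorted(missing)),
        )
    by_locus: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_locus.setdefault(g.geneSymbol, []).append(g)
    chosen = []
    for symbol in sorted(by_locus):
        group = by_locus[symbol]
        listed = [g for g in group if g.transcriptId in wanted]
        pool = listed or group
        chosen.append(
            min(pool, key=lambda g: (-(g.txEnd - g.txStart), g.transcriptId))
        )
    chosen.sort(key=lambda g: (g.chrom, g.txStart, g.transcriptId))
    return chosen


def regulatory_window(
    gene: GeneModel,
    up: int = 2000,
    down: int = 1000,
    chrom_length: int | None = None,
) -> RegulatoryRegion:
    """The (-up, +down) TSS window in genomic coordinates, edge-clamped."""
    if up < 0 or down < 0:
        raise ValueError("up and down must be >= 0")
    if gene.strand == "+":
        start, end = gene.txStart - up, gene.txStart + down
    else:
        start, end = gene.txEnd - down, gene.txEnd + up
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return RegulatoryRegion(gene=gene, tss=gene.tss, windowStart=start, windowEnd=end)


def gene_compartments(gene: GeneModel) -> dict[str, list[tuple[int, int]]]:
    """Exon, intron and 5'-UTR interval sets of one gene.

    The 5'-UTR is exon-aware: exonic bases strictly between the TSS and
    the CDS start in transcript orientation (empty for noncoding models).
    """
    exons = gene.exons
    introns = [
        (e0, s1) for (_, e0), (s1, _) in zip(exons, exons[1:]) if e0 < s1
    ]
    five_utr: list[tuple[int, int]] = []
    if gene.category == "coding":
        if gene.strand == "+":
            lo, hi = gene.txStart, gene.cdsStart
        else:
            lo, hi = gene.cdsEnd, gene.txEnd
        for s, e in exons:
            a, b = max(s, lo), min(e, hi)
            if a < b:
                five_utr.append((a, b))
    return {"exons": exons, "introns": introns, "five_utr": five_utr}


def flag_cpg_overlap(
    regions: list[RegulatoryRegion],
    islands: list[tuple[str, int, int]] | None,
) -> list[RegulatoryRegion]:
    """Set cpgOverlap on each region (>= 1 bp half-open intersection)."""
    if not islands:
        logger.info("no CpG islands supplied; all regions flagged False")
        for r in regions:
            r.cpgOverlap = False
        return regions
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in islands:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    for r in regions:
        tree = trees.get(r.gene.chrom)
        r.cpgOverlap = bool(tree and tree.overlap(r.windowStart, r.windowEnd))
    return regions
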