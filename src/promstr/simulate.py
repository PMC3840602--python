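"""Synthetic genomes with planted STR truth.

The generator emulates the statistical structure of TSS-proximal repeat
content in a mammalian genome: i.i.d. background sequence at a chosen GC
fraction, non-overlapping genes on both strands with exon/CDS structure,
CpG islands over a configurable fraction of TSS windows, AT-rich
short-period repeats planted upstream, GC-rich trinucleotides planted
near the TSS of CpG-island genes, and genome-wide repeats for spectrum
comparisons.  Every planted repeat is recorded in a truth table whose
fields are recomputed from the realised tract, so every pipeline stage
can be validated without downloads.

Planting is substitution-only (matching the indel-free detector); planted
tracts keep a configurable distance from each other and from splice
sites, and their immediate flanks are forced to mismatch the repeat
continuation so the planted span is unambiguous.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from .detect import primitive_motif
from .enrichment import GeneSet
from .genes import GeneModel, RegulatoryRegion, regulatory_window
from .records import (
    BASES,
    STRRecord,
    ScoringParams,
    base_composition,
    best_phase_matches,
    compute_entropy,
    compute_purity,
    infer_consensus,
    round_half_up,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PlantSpec",
    "TermSpec",
    "SimConfig",
    "SimResult",
    "TruthRecord",
    "GenerationError",
    "simulate_genome",
    "plant_repeat",
    "truth_to_simple_repeats",
    "simulate_enriched_study",
]


class GenerationError(RuntimeError):
    """Raised when a placement or purity constraint cannot be satisfied."""


@dataclass(frozen=True)
class PlantSpec:
    """One class of planted repeats.

    periods: probability over periods 1..9.  purity: inclusive target
    range (realised purity lands within +-2 of the drawn target).
    placement "window" plants at a TxPos drawn uniformly from txpos_range
    in a gene's TSS window; "genome" plants outside all windows.
    composition biases motif bases (AT-rich, GC-rich or uniform).
    """

    count: int
    periods: dict[int, float]
    purity: tuple[float, float] = (100.0, 100.0)
    placement: str = "window"
    txpos_range: tuple[int, int] = (-2000, 999)
    composition: str = "uniform"
    cpg_only: bool = False
    length_range: tuple[int, int] = (25, 60)

    def __post_init__(self) -> None:
        total = sum(self.periods.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"period distribution sums to {total}, not 1")
        if any(not 1 <= p <= 9 for p in self.periods):
            raise ValueError("periods must lie in 1..9")
        if not 70 <= self.purity[0] <= self.purity[1] <= 100:
            raise ValueError("purity targets must lie in [70, 100]")
        if self.placement not in ("window", "genome"):
            raise ValueError("placement must be 'window' or 'genome'")


@dataclass(frozen=True)
class TermSpec:
    """Planted term->gene structure with one enriched term."""

    n_terms: int = 20
    term_size: tuple[int, int] = (10, 40)
    enriched_term: str = "T000"
    fold: float = 3.0


def default_plant_specs(n_genes: int = 100) -> list[PlantSpec]:
    """The default plant classes, with counts scaled to the gene count.

    Counts below are calibrated for a 100-gene genome; smaller or larger
    genomes keep the same plants-per-gene density.
    """
    import dataclasses

    scale = n_genes / 100
    return [
        dataclasses.replace(s, count=max(3, int(round(s.count * scale))))
        for s in _default_plant_specs()
    ]


def _default_plant_specs() -> list[PlantSpec]:
    # Upstream AT-rich short periods, GC-rich trinucleotides near the TSS
    # of CpG-island genes, a sub-90-purity class so the purity filter is
    # observable, and genome-wide repeats with a broad period mix.
    return [
        PlantSpec(
            count=120,
            periods={1: 0.30, 2: 0.45, 4: 0.10, 5: 0.10, 8: 0.05},
            purity=(100.0, 100.0),
            placement="window",
            txpos_range=(-2000, -301),
            composition="at_rich",
        ),
        PlantSpec(
            count=80,
            periods={3: 0.75, 6: 0.15, 9: 0.10},
            purity=(100.0, 100.0),
            placement="window",
            txpos_range=(-300, 300),
            composition="gc_rich",
            cpg_only=True,
        ),
        PlantSpec(
            count=30,
            periods={1: 0.3, 2: 0.4, 3: 0.3},
            purity=(85.0, 87.0),
            placement="window",
            composition="at_rich",
            length_range=(80, 120),
        ),
        PlantSpec(
            count=150,
            periods={
                1: 0.24,
                2: 0.29,
                3: 0.10,
                4: 0.12,
                5: 0.08,
                6: 0.06,
                7: 0.05,
                8: 0.04,
                9: 0.02,
            },
            purity=(92.0, 100.0),
            placement="genome",
            composition="uniform",
        ),
    ]


@dataclass
class SimConfig:
    seed: int = 1
    n_chroms: int = 2
    chrom_length: int = 600_000
    n_genes: int = 100
    strand_prob: float = 0.5
    background_gc: float = 0.40
    cpg_fraction: float = 0.66
    noncoding_fraction: float = 0.10
    plant_specs: list[PlantSpec] = field(default_factory=_default_plant_specs)
    term_spec: TermSpec | None = None
    up: int = 2000
    down: int = 1000
    min_plant_gap: int = 50
    exon_buffer: int = 50
    scoring: ScoringParams = field(default_factory=ScoringParams)


@dataclass
class TruthRecord:
    """One planted repeat: realised record plus planting intent."""

    record: STRRecord
    gene_id: str | None
    tx_pos: int | None
    target_purity: float
    spec_index: int


@dataclass
class SimResult:
    config: SimConfig
    sequences: dict[str, str]
    genes: list[GeneModel]
    regions: list[RegulatoryRegion]
    islands: list[tuple[str, int, int]]
    truth: list[TruthRecord]
    term_map: dict[str, set[str]] | None = None

    def truth_records(self) -> list[STRRecord]:
        return [t.record for t in self.truth]

    def write(self, outdir) -> dict[str, str]:
        """Write FASTA, gene table, CpG BED, truth TSV and a manifest."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "fasta": os.path.join(outdir, "genome.fa"),
            "genes": os.path.join(outdir, "genes.tsv"),
            "cpg": os.path.join(outdir, "cpg_islands.bed"),
            "repeats": os.path.join(outdir, "truth_repeats.tsv"),
            "manifest": os.path.join(outdir, "manifest.json"),
        }
        with open(paths["fasta"], "w") as fh:
            for chrom in sorted(self.sequences):
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        with open(paths["genes"], "w") as fh:
            for g in self.genes:
                fh.write(
                    "\t".join(
                        [
                            g.transcriptId,
                            g.chrom,
                            g.strand,
                            str(g.txStart),
                            str(g.txEnd),
                            str(g.cdsStart),
                            str(g.cdsEnd),
                            str(len(g.exonStarts)),
                            ",".join(map(str, g.exonStarts)) + ",",
                            ",".join(map(str, g.exonEnds)) + ",",
                            g.geneSymbol,
                        ]
                    )
                    + "\n"
                )
        with open(paths["cpg"], "w") as fh:
            for chrom, start, end in self.islands:
                fh.write(f"{chrom}\t{start}\t{end}\n")
        truth_to_simple_repeats(self.truth_records(), paths["repeats"])
        manifest = {
            "seed": self.config.seed,
            "config": _config_dict(self.config),
            "n_genes": len(self.genes),
            "n_planted": len(self.truth),
        }
        if self.term_map is not None:
            paths["terms"] = os.path.join(outdir, "term_map.tsv")
            with open(paths["terms"], "w") as fh:
                for term in sorted(self.term_map):
                    for gene in sorted(self.term_map[term]):
                        fh.write(f"{term}\t{gene}\n")
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return paths


def _config_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["plant_specs"] = [asdict(s) for s in cfg.plant_specs]
    return d


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs)


def _random_motif(rng: np.random.Generator, period: int, composition: str) -> str:
    probs = {
        "at_rich": [0.4, 0.1, 0.1, 0.4],
        "gc_rich": [0.1, 0.4, 0.4, 0.1],
        "uniform": [0.25, 0.25, 0.25, 0.25],
    }[composition]
    for _ in range(200):
        motif = "".join(rng.choice(list(BASES), size=period, p=probs))
        if primitive_motif(motif) == motif:
            return motif
    raise GenerationError(f"could not draw a primitive period-{period} motif")


def plant_repeat(
    seq: np.ndarray,
    pos: int,
    motif: str,
    copies: float,
    target_purity: float,
    rng: np.random.Generator,
    params: ScoringParams | None = None,
) -> STRRecord:
    """Write motif x copies at pos, substitute down to the target purity.

    Substitutions land at distinct tract positions; the mutated tract must
    keep the motif's primitive period and land within +-2 percentage
    points of the target purity, otherwise positions are resampled.  The
    returned truth record carries the realised (recomputed) purity, score,
    composition and entropy.
    """
    params = params or ScoringParams()
    p = len(motif)
    length = int(round_half_up(copies * p))
    if pos < 0 or pos + length > seq.size:
        raise GenerationError("tract does not fit in the sequence")
    if target_purity > 100:
        raise GenerationError("target purity above 100 is unreachable")
    if target_purity < 70:
        raise GenerationError(
            f"target purity {target_purity} below the supported floor of 70"
        )
    tile = (motif * (length // p + 1))[:length]
    base_arr = np.frombuffer(tile.encode("ascii"), dtype=np.uint8)
    n_subs = int(round_half_up(length * (100 - target_purity) / 100))
    tract = ""
    ok = False
    for extra in (0, 1):
        for _ in range(200):
            arr = base_arr.copy()
            m = n_subs + extra
            if m > 0:
                sites = rng.choice(length, size=min(m, length), replace=False)
                for s in sites:
                    choices = [b for b in BASES if ord(b) != arr[s]]
                    arr[s] = ord(rng.choice(choices))
            tract = arr.tobytes().decode("ascii")
            realized = compute_purity(tract, motif)
            if abs(realized - target_purity) > 2:
                continue
            if len(primitive_motif(infer_consensus(tract, p))) != p:
                continue
            ok = True
            break
        if ok:
            break
    if not ok:
        raise GenerationError(
            f"could not realise purity {target_purity} +-2 on a {length} bp "
            f"period-{p} tract"
        )
    seq[pos : pos + length] = np.frombuffer(tract.encode("ascii"), dtype=np.uint8)
    matches, _ = best_phase_matches(tract, motif)
    score = params.match_weight * matches - params.mismatch_penalty * (
        length - matches
    )
    comp = base_composition(tract)
    fracs = tuple(tract.count(b) / length for b in BASES)
    return STRRecord(
        chrom="",
        srStart=pos,
        srEnd=pos + length,
        period=p,
        numRepeats=round_half_up(length / p, 1),
        consensusSize=p,
        perMatch=compute_purity(tract, motif),
        perIndel=0,
        score=score,
        baseA=comp[0],
        baseC=comp[1],
        baseG=comp[2],
        baseT=comp[3],
        entropy=compute_entropy(*fracs),
        sequence=motif,
    )


def _force_flanks(seq: np.ndarray, start: int, end: int, period: int,
                  motif: str, rng: np.random.Generator) -> None:
    """Isolate a planted tract so its score-optimal span is exactly [start, end).

    The period+1 bases on each side are forced to mismatch both the
    autocorrelation (splitting the candidate block) and the motif
    continuation; then the detector's own span refinement is run locally
    and any residual net-positive extension (a chance near-tandem run in
    the background just beyond the flank) is broken base by base.
    """
    p = period

    def force(j: int, avoid: set[int]) -> None:
        if 0 <= j < seq.size and seq[j] in avoid:
            choices = [b for b in BASES if ord(b) not in avoid]
            seq[j] = ord(rng.choice(choices))

    for i in range(p + 1):
        j = start - 1 - i
        if j >= 0:
            force(j, {int(seq[j + p]), ord(motif[(j - start) % p])})
        j = end + i
        if j < seq.size:
            force(j, {int(seq[j - p]), ord(motif[(j - start) % p])})
    # verification: refine the span as the detector would and break any
    # chance continuation matches that re-extend it.
    from .detect import _refine_span

    params = ScoringParams()
    pad = 2 * p + 20
    for _ in range(8):
        lo = max(0, start - pad)
        hi = min(seq.size, end + pad)
        local = seq[lo:hi].tobytes().decode("ascii")
        a, b = _refine_span(local, start - lo, end - lo, p, params)
        a, b = a + lo, b + lo
        if (a, b) == (start, end):
            return
        changed = False
        for j in list(range(a, start)) + list(range(end, b)):
            if seq[j] == ord(motif[(j - start) % p]):
                force(j, {ord(motif[(j - start) % p]), int(seq[j - p]) if j >= p else -1})
                changed = True
        if not changed:
            return
    raise GenerationError(
        f"could not isolate a period-{p} plant at {start}-{end}"
    )


def _place_genes(
    cfg: SimConfig, rng: np.random.Generator
) -> list[GeneModel]:
    genes: list[GeneModel] = []
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chroms))
    idx = 0
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        cursor = cfg.up + 500
        placed = 0
        while placed < per_chrom and idx < cfg.n_genes:
            n_exons = int(rng.integers(2, 6))
            exon_lens = [int(rng.integers(400, 700))] + [
                int(rng.integers(150, 500)) for _ in range(n_exons - 1)
            ]
            intron_lens = [int(rng.integers(300, 1200)) for _ in range(n_exons - 1)]
            tx_start = cursor
            starts, ends = [], []
            at = tx_start
            for k in range(n_exons):
                starts.append(at)
                at += exon_lens[k]
                ends.append(at)
                if k < n_exons - 1:
                    at += intron_lens[k]
            tx_end = ends[-1]
            if tx_end + cfg.down + 500 > cfg.chrom_length:
                break
            strand = "+" if rng.random() < cfg.strand_prob else "-"
            if rng.random() < cfg.noncoding_fraction:
                cds_start = cds_end = tx_end
            else:
                # CDS starts inside the first exon (leaving a 5'-UTR) and
                # ends inside the last exon, in genomic coordinates.
                cds_start = starts[0] + int(rng.integers(100, exon_lens[0] - 50))
                cds_end = ends[-1] - int(rng.integers(20, min(120, exon_lens[-1] - 10)))
            transcript = f"{'NR' if cds_start == cds_end else 'NM'}_{idx:06d}"
            genes.append(
                GeneModel(
                    transcriptId=transcript,
                    geneSymbol=f"GENE{idx:04d}",
                    chrom=chrom,
                    strand=strand,
                    txStart=tx_start,
                    txEnd=tx_end,
                    cdsStart=min(cds_start, cds_end),
                    cdsEnd=max(cds_start, cds_end),
                    exonStarts=tuple(starts),
                    exonEnds=tuple(ends),
                )
            )
            placed += 1
            idx += 1
            cursor = tx_end + cfg.down + cfg.up + int(rng.integers(800, 2500))
    if idx < cfg.n_genes:
        raise GenerationError(
            f"placed only {idx} of {cfg.n_genes} genes; increase chrom_length"
        )
    return genes


def simulate_genome(cfg: SimConfig | None = None) -> SimResult:
    """Generate a genome, gene models, CpG islands and planted STR truth.

    Fully reproducible from cfg.seed: the same configuration always
    produces byte-identical outputs.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    seqs = {
        f"chr{c + 1}": _random_sequence(rng, cfg.chrom_length, cfg.background_gc)
        for c in range(cfg.n_chroms)
    }
    genes = _place_genes(cfg, rng)
    regions = [
        regulatory_window(g, cfg.up, cfg.down, chrom_length=cfg.chrom_length)
        for g in genes
    ]
    n_cpg = int(round(cfg.cpg_fraction * len(genes)))
    cpg_idx = set(rng.choice(len(genes), size=n_cpg, replace=False).tolist())
    islands = []
    for i in sorted(cpg_idx):
        tss = regions[i].tss
        islands.append(
            (genes[i].chrom, max(0, tss - 150), min(cfg.chrom_length, tss + 150))
        )
    for i, region in enumerate(regions):
        region.cpgOverlap = i in cpg_idx

    term_map: dict[str, set[str]] | None = None
    gene_weights = np.ones(len(genes))
    if cfg.term_spec is not None:
        ts = cfg.term_spec
        term_map = {}
        symbols = [g.geneSymbol for g in genes]
        for t in range(ts.n_terms):
            name = f"T{t:03d}"
            size = int(rng.integers(ts.term_size[0], ts.term_size[1] + 1))
            size = min(size, len(symbols))
            members = rng.choice(len(symbols), size=size, replace=False)
            term_map[name] = {symbols[j] for j in members}
        enriched = term_map.get(cfg.term_spec.enriched_term, set())
        for j, g in enumerate(genes):
            if g.geneSymbol in enriched:
                gene_weights[j] = ts.fold

    planted: dict[str, list[tuple[int, int]]] = {c: [] for c in seqs}
    splice_sites: dict[str, list[int]] = {c: [] for c in seqs}
    for g in genes:
        splice_sites[g.chrom].extend(g.exonEnds[:-1])
        splice_sites[g.chrom].extend(g.exonStarts[1:])
    window_ivs: dict[str, list[tuple[int, int]]] = {c: [] for c in seqs}
    for region in regions:
        window_ivs[region.gene.chrom].append(region.interval)

    def clear(chrom: str, start: int, end: int, check_splice: bool) -> bool:
        pad = cfg.min_plant_gap
        for s, e in planted[chrom]:
            if min(end + pad, e) > max(start - pad, s):
                return False
        if check_splice:
            buf = cfg.exon_buffer
            for site in splice_sites[chrom]:
                if start - buf < site < end + buf:
                    return False
        return True

    truth: list[TruthRecord] = []
    for spec_index, spec in enumerate(cfg.plant_specs):
        periods = sorted(spec.periods)
        probs = [spec.periods[p] for p in periods]
        eligible = [
            j
            for j, region in enumerate(regions)
            if not spec.cpg_only or region.cpgOverlap
        ]
        if spec.placement == "window" and not eligible:
            raise GenerationError("no eligible genes for a window plant spec")
        for _ in range(spec.count):
            period = int(rng.choice(periods, p=probs))
            lo = max(spec.length_range[0], 25, period + 12, 3 * period)
            hi = max(lo + 1, spec.length_range[1] + 1)
            length = int(rng.integers(lo, hi))
            target = float(
                rng.integers(int(spec.purity[0]), int(spec.purity[1]) + 1)
            )
            motif = _random_motif(rng, period, spec.composition)
            placed = False
            for _ in range(300):
                if spec.placement == "window":
                    w = gene_weights[eligible]
                    j = int(rng.choice(eligible, p=w / w.sum()))
                    region, gene = regions[j], genes[j]
                    t_lo = max(spec.txpos_range[0], -cfg.up)
                    t_hi = min(spec.txpos_range[1], cfg.down - length)
                    if t_lo > t_hi:
                        continue
                    txpos = int(rng.integers(t_lo, t_hi + 1))
                    if gene.strand == "+":
                        start = gene.txStart + txpos
                    else:
                        start = gene.txEnd - txpos - length
                    chrom = gene.chrom
                else:
                    chrom = f"chr{int(rng.integers(1, cfg.n_chroms + 1))}"
                    start = int(
                        rng.integers(100, cfg.chrom_length - length - 100)
                    )
                    if any(
                        min(start + length, e) > max(start, s)
                        for s, e in window_ivs[chrom]
                    ):
                        continue
                    txpos, gene = None, None
                end = start + length
                if start < period + 2 or end > cfg.chrom_length - period - 2:
                    continue
                if not clear(chrom, start, end, spec.placement == "window"):
                    continue
                rec = plant_repeat(
                    seqs[chrom],
                    start,
                    motif,
                    length / period,
                    target,
                    rng,
                    cfg.scoring,
                )
                _force_flanks(seqs[chrom], start, end, period, motif, rng)
                rec.chrom = chrom
                planted[chrom].append((start, end))
                truth.append(
                    TruthRecord(
                        record=rec,
                        gene_id=gene.transcriptId if gene is not None else None,
                        tx_pos=txpos,
                        target_purity=target,
                        spec_index=spec_index,
                    )
                )
                placed = True
                break
            if not placed:
                raise GenerationError(
                    f"could not place a period-{period} plant from spec "
                    f"{spec_index} after bounded retries (gap/splice/window "
                    "constraints)"
                )
    truth.sort(key=lambda t: (t.record.chrom, t.record.srStart))
    sequences = {c: s.tobytes().decode("ascii") for c, s in seqs.items()}
    logger.info(
        "simulated %d chroms, %d genes, %d planted repeats (seed %d)",
        cfg.n_chroms,
        len(genes),
        len(truth),
        cfg.seed,
    )
    return SimResult(
        config=cfg,
        sequences=sequences,
        genes=genes,
        regions=regions,
        islands=islands,
        truth=truth,
        term_map=term_map,
    )


def truth_to_simple_repeats(records: list[STRRecord], path: str) -> None:
    """Serialise truth records in the ingestible simpleRepeats dialect."""
    from .io import write_simple_repeats

    write_simple_repeats(records, path)


def simulate_enriched_study(
    n_background: int = 1000,
    n_terms: int = 40,
    term_size: int = 100,
    set_size: int = 200,
    fold: float = 3.0,
    enriched_term: str = "T000",
    seed: int = 0,
) -> tuple[GeneSet, GeneSet, dict[str, set[str]]]:
    """A gene-set-level study with one term planted at a target fold.

    Returns (study set, background, term map).  The study set is drawn
    without replacement with weights `fold` for genes of the enriched
    term, so the realised enrichment approaches the target fold; all
    other terms are null.  Used for power/calibration checks of the
    enrichment statistics without a full genome simulation.
    """
    rng = np.random.default_rng(seed)
    symbols = [f"G{i:05d}" for i in range(n_background)]
    background = GeneSet("background", frozenset(symbols))
    term_map: dict[str, set[str]] = {}
    for t in range(n_terms):
        members = rng.choice(n_background, size=term_size, replace=False)
        term_map[f"T{t:03d}"] = {symbols[j] for j in members}
    enriched = term_map[enriched_term]
    weights = np.array([fold if s in enriched else 1.0 for s in symbols])
    pick = rng.choice(
        n_background, size=set_size, replace=False, p=weights / weights.sum()
    )
    study = GeneSet(
        "study",
        frozenset(symbols[j] for j in pick),
        provenance={"fold": fold, "enriched_term": enriched_term, "seed": seed},
    )
    return study, background, term_map
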