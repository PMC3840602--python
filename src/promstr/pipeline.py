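"""End-to-end orchestration: ingest/detect -> annotate -> table -> profiles
-> gene sets -> enrichment, with per-stage filter counts and a
machine-readable summary."""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass

import pandas as pd

from . import io as pio
from .detect import DetectorConfig, detect_strs
from .enrichment import (
    GeneSet,
    exonic_gene_set,
    high_density_quartile,
    hypergeometric_enrichment,
    intron_density_table,
    majority_consensus,
    random_gene_samples,
    table_gene_set,
)
from .genes import (
    exclude_nonprimary,
    flag_cpg_overlap,
    read_gene_table,
    regulatory_window,
    select_canonical,
)
from .mapping import build_repeat_table
from .profiling import compute_profile, split_by_cpg
from .records import ScoringParams

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run.

    Either simple_repeats (precomputed repeats) or genome_fasta (for
    detection) must be provided; both may be given, in which case the
    precomputed table wins and the FASTA only supplies chromosome lengths.
    """

    gene_table: str = ""
    genome_fasta: str | None = None
    simple_repeats: str | None = None
    cpg_bed: str | None = None
    id_map: str | None = None
    term_map: str | None = None
    outdir: str = "promstr_out"
    up: int = 2000
    down: int = 1000
    min_purity: float = 90.0
    max_period: int = 9
    min_score: int = 50
    lowess_frac: float = 0.1
    lowess_iters: int = 3
    quartile: float = 0.25
    n_samples: int = 10
    alpha: float = 0.05
    min_agree: int = 6
    canonical_ids: str | None = None
    seed: int = 1

    def params_dict(self) -> dict:
        # outdir is excluded: where artifacts land must not change their
        # content or the reproducibility hash.
        return {
            k: v
            for k, v in dataclasses.asdict(self).items()
            if k != "outdir" and not isinstance(v, (dict, list))
        }

    def scoring(self) -> ScoringParams:
        return ScoringParams(
            min_score=self.min_score,
            max_period=self.max_period,
            min_purity=self.min_purity,
        )

    def __post_init__(self) -> None:
        if self.up < 0 or self.down < 0:
            raise ValueError("up and down must be >= 0")
        if not 0 < self.quartile < 1:
            raise ValueError("quartile must lie in (0, 1)")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage-named abort
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


@_stage("ingest")
def _load_strs(cfg: PipelineConfig):
    if cfg.simple_repeats:
        strs = pio.read_simple_repeats(cfg.simple_repeats)
        logger.info("ingested %d repeat records", len(strs))
        return strs
    if not cfg.genome_fasta:
        raise ValueError("need simple_repeats or genome_fasta")
    from pyfaidx import Fasta

    det = DetectorConfig(scoring=cfg.scoring())
    strs = []
    with Fasta(cfg.genome_fasta) as fa:
        for name in fa.keys():
            strs.extend(detect_strs(str(fa[name][:]), det, chrom=name))
    logger.info("detected %d repeat records", len(strs))
    return strs


@_stage("annotate")
def _load_genes(cfg: PipelineConfig):
    genes = read_gene_table(cfg.gene_table)
    n_all = len(genes)
    genes = exclude_nonprimary(genes)
    n_primary = len(genes)
    canonical_ids = None
    if cfg.canonical_ids:
        with open(cfg.canonical_ids) as fh:
            canonical_ids = [line.strip() for line in fh if line.strip()]
    canonical = select_canonical(genes, canonical_ids)
    chrom_lengths = (
        pio.read_fasta_lengths(cfg.genome_fasta) if cfg.genome_fasta else {}
    )
    regions = [
        regulatory_window(
            g, cfg.up, cfg.down, chrom_length=chrom_lengths.get(g.chrom)
        )
        for g in canonical
    ]
    islands = pio.read_bed(cfg.cpg_bed) if cfg.cpg_bed else None
    flag_cpg_overlap(regions, islands)
    counts = {
        "transcripts": n_all,
        "after_contig_exclusion": n_primary,
        "canonical": len(canonical),
        "cpg_regions": sum(r.cpgOverlap for r in regions),
    }
    return canonical, regions, counts


def _read_id_map(path: str | None) -> dict[str, dict[str, str]]:
    if not path:
        return {}
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "refSeqId" not in df.columns:
        raise PipelineError("stage 'annotate' failed: id map lacks refSeqId column")
    return {
        row["refSeqId"]: {k: v for k, v in row.items() if k != "refSeqId"}
        for _, row in df.iterrows()
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write artifacts under cfg.outdir.

    Returns the summary dict (also written as summary.json).  Counts in
    the summary are monotone non-increasing along each filter chain.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    params = cfg.params_dict()
    strs = _load_strs(cfg)
    canonical, regions, gene_counts = _load_genes(cfg)
    id_map = _read_id_map(cfg.id_map)

    table, str_counts = build_repeat_table(
        strs, regions, cfg.scoring(), id_map, up=cfg.up, down=cfg.down
    )
    table_path = os.path.join(cfg.outdir, "repeat_table.tsv")
    pio.write_repeat_table(table, table_path, params, cfg.seed)

    profiles = {}
    subsets = {"all": table}
    cpg_table, noncpg_table = split_by_cpg(table, regions)
    subsets["cpg"] = cpg_table
    subsets["noncpg"] = noncpg_table
    region_counts = {
        "all": len(regions),
        "cpg": sum(r.cpgOverlap for r in regions),
        "noncpg": sum(not r.cpgOverlap for r in regions),
    }
    for name, sub in subsets.items():
        n_regions = max(region_counts[name], 1)
        prof = compute_profile(
            sub,
            n_regions,
            up=cfg.up,
            down=cfg.down,
            lowess_frac=cfg.lowess_frac,
            lowess_iters=cfg.lowess_iters,
        )
        path = os.path.join(cfg.outdir, f"profile_{name}.tsv")
        with open(path, "w") as fh:
            for line in pio.metadata_lines({**params, "subset": name}, cfg.seed):
                fh.write(line + "\n")
            prof.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6g")
        profiles[name] = path

    # gene sets
    reg_set = table_gene_set(table)
    exon_set = exonic_gene_set(strs, canonical)
    density = intron_density_table(canonical, strs, cfg.min_purity)
    dense_set = high_density_quartile(density, cfg.quartile)
    intron_pool = GeneSet("intron_pool", frozenset(density.index))
    sample_size = min(len(reg_set), len(intron_pool))
    samples = (
        random_gene_samples(intron_pool, sample_size, cfg.n_samples, cfg.seed)
        if sample_size > 0
        else []
    )
    sets_path = os.path.join(cfg.outdir, "gene_sets.json")
    with open(sets_path, "w") as fh:
        json.dump(
            {
                s.name: sorted(s.genes)
                for s in [reg_set, exon_set, dense_set, *samples]
            },
            fh,
            indent=1,
            sort_keys=True,
        )

    enrichment_summary = {}
    if cfg.term_map:
        term_map = pio.read_term_map(cfg.term_map)
        background = GeneSet(
            "background", frozenset(g.geneSymbol for g in canonical)
        )
        named = {"regulatory": reg_set, "exonic": exon_set, "intron_dense": dense_set}
        for name, gs in named.items():
            res = hypergeometric_enrichment(
                GeneSet(name, gs.genes & background.genes), background, term_map
            )
            path = os.path.join(cfg.outdir, f"enrichment_{name}.tsv")
            with open(path, "w") as fh:
                for line in pio.metadata_lines({**params, "set": name}, cfg.seed):
                    fh.write(line + "\n")
                res.to_csv(fh, sep="\t", index=False, float_format="%.6g")
            enrichment_summary[name] = {
                "significant": int((res["fdr"] < cfg.alpha).sum()),
                "tested": int(len(res)),
                "path": path,
            }
        sample_results = [
            hypergeometric_enrichment(s, background, term_map) for s in samples
        ]
        consensus = majority_consensus(sample_results, cfg.alpha, cfg.min_agree)
        consensus_path = os.path.join(cfg.outdir, "consensus_terms.txt")
        with open(consensus_path, "w") as fh:
            fh.write("\n".join(consensus) + ("\n" if consensus else ""))
        enrichment_summary["sample_consensus"] = {
            "terms": consensus,
            "n_samples": len(sample_results),
            "min_agree": cfg.min_agree,
        }

    summary = {
        "parameters": params,
        "seed": cfg.seed,
        "str_counts": str_counts,
        "gene_counts": gene_counts,
        "table": {
            "rows": str_counts["rows"],
            "unique_strs": int(
                table[["Chrom", "srStart", "srEnd"]].drop_duplicates().shape[0]
            )
            if len(table)
            else 0,
            "genes": str_counts["genes"],
            "path": table_path,
        },
        "profiles": profiles,
        "gene_sets": {
            "regulatory": len(reg_set),
            "exonic": len(exon_set),
            "intron_dense": len(dense_set),
            "intron_pool": len(intron_pool),
            "samples": len(samples),
            "path": sets_path,
        },
        "enrichment": enrichment_summary,
    }
    with open(os.path.join(cfg.outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
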