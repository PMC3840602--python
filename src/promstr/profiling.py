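"""Per-position (metagene) profiles of STRs across the TSS window.

Every repeat-table row covers the TxPos positions
[txPos, txPos + srLength - 1]; profiles accumulate coverage counts,
per-period decompositions and unweighted means of base composition and
copy number over that grid, optionally smoothed by LOWESS local
regression (tricube weights with robustness iterations).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .mapping import overlaps_entity
from .records import STRRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PositionProfile",
    "position_counts",
    "to_density",
    "lowess_smooth",
    "decompose_by_period",
    "composition_profile",
    "period_spectrum",
    "split_by_cpg",
    "compute_profile",
]

MAX_PERIOD = 9


def _spans(table: pd.DataFrame, up: int, down: int) -> tuple[np.ndarray, np.ndarray]:
    txpos = table["txPos"].to_numpy(dtype=np.int64)
    length = table["srLength"].to_numpy(dtype=np.int64)
    if len(txpos) and ((txpos < -up).any() or (txpos + length > down).any()):
        raise ValueError(
            "row violates full containment: txPos span outside the grid"
        )
    return txpos, length


def position_counts(table: pd.DataFrame, up: int = 2000, down: int = 1000) -> np.ndarray:
    """STR coverage count at each TxPos in [-up, down-1].

    Each row adds 1 to every position it covers, so the profile sums to
    the total covered length (sum of srLength over rows).
    """
    txpos, length = _spans(table, up, down)
    counts = np.zeros(up + down, dtype=np.int64)
    for t, n in zip(txpos, length):
        counts[t + up : t + up + n] += 1
    return counts


def to_density(counts: np.ndarray, n_regions: int) -> np.ndarray:
    """Per-base density: coverage counts divided by the number of regions."""
    if n_regions <= 0:
        raise ValueError("n_regions must be > 0")
    return np.asarray(counts, dtype=float) / n_regions


def lowess_smooth(
    series: np.ndarray, frac: float = 0.1, iters: int = 3
) -> np.ndarray:
    """LOWESS smoothing on the positional grid (NaN-aware).

    Locally weighted linear regression with tricube weights and `iters`
    robustness iterations; missing (NaN) input positions stay missing.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    y = np.asarray(series, dtype=float)
    mask = np.isfinite(y)
    if mask.sum() < 3:
        warnings.warn("series shorter than 3 finite points; returned unchanged")
        return y.copy()
    x = np.arange(y.size, dtype=float)
    out = np.full(y.size, np.nan)
    out[mask] = _sm_lowess(
        y[mask], x[mask], frac=frac, it=iters, return_sorted=False
    )
    return out


def decompose_by_period(
    table: pd.DataFrame, up: int = 2000, down: int = 1000
) -> np.ndarray:
    """Coverage counts split by period 1..9; rows sum to the total profile."""
    out = np.zeros((MAX_PERIOD, up + down), dtype=np.int64)
    for p in range(1, MAX_PERIOD + 1):
        sub = table[table["Period"] == p]
        out[p - 1] = position_counts(sub, up, down)
    return out


def composition_profile(
    table: pd.DataFrame, up: int = 2000, down: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position unweighted means of (A, C, G, T) percents and copy number.

    Positions covered by no STR are NaN (missing, not zero), which keeps
    the composition curves unbiased by empty stretches of the grid.
    """
    txpos, length = _spans(table, up, down)
    n = up + down
    counts = np.zeros(n)
    base_sum = np.zeros((4, n))
    copy_sum = np.zeros(n)
    bases = table[["A", "C", "G", "T"]].to_numpy(dtype=float) if len(table) else None
    copies = table["numRepeats"].to_numpy(dtype=float) if len(table) else None
    for i, (t, m) in enumerate(zip(txpos, length)):
        sl = slice(t + up, t + up + m)
        counts[sl] += 1
        base_sum[:, sl] += bases[i][:, None]
        copy_sum[sl] += copies[i]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_base = np.where(counts > 0, base_sum / counts, np.nan)
        mean_copies = np.where(counts > 0, copy_sum / counts, np.nan)
    return mean_base, mean_copies


def period_spectrum(
    compartment_sets: dict[str, list[STRRecord]],
) -> pd.DataFrame:
    """Per-compartment proportions of member STRs at each period 1..9.

    Columns are compartments, indexed by period; each non-empty column
    sums to 1.  Empty compartments yield an all-NaN column and a log line.
    """
    data = {}
    for name, members in compartment_sets.items():
        if not members:
            logger.info("compartment %s is empty; spectrum undefined", name)
            data[name] = [np.nan] * MAX_PERIOD
            continue
        total = len(members)
        data[name] = [
            sum(1 for s in members if s.period == p) / total
            for p in range(1, MAX_PERIOD + 1)
        ]
    return pd.DataFrame(data, index=pd.RangeIndex(1, MAX_PERIOD + 1, name="period"))


def compartment_subsets(
    strs: list[STRRecord],
    regions,
    genes,
    up: int = 2000,
    down: int = 1000,
    table_purity: float = 90.0,
    max_period: int = MAX_PERIOD,
) -> dict[str, list[STRRecord]]:
    """Standard compartment membership by the any-overlap rule.

    No purity filter is applied to the positional compartments (the
    unfiltered "regulatory region" category included); the purity filter
    applies only to the table-equivalent category.
    """
    from .genes import gene_compartments  # local to avoid cycle at import

    strs = [s for s in strs if s.period <= max_period]
    out: dict[str, list[STRRecord]] = {
        "all": list(strs),
        "upstream": [],
        "proximal_promoter": [],
        "regulatory_region": [],
        "table": [],
        "exon": [],
        "intron": [],
        "five_prime_utr": [],
    }
    window_sets = {"upstream": [], "proximal_promoter": [], "regulatory_region": []}
    for region in regions:
        gene = region.gene
        tss, sign = region.tss, (1 if gene.strand == "+" else -1)

        def genomic(lo: int, hi: int) -> tuple[int, int]:
            # inclusive TxPos window -> half-open genomic interval
            a = tss + sign * lo
            b = tss + sign * (hi + 1)
            return (min(a, b), max(a, b))

        window_sets["upstream"].append((gene.chrom, genomic(-up, -1)))
        window_sets["proximal_promoter"].append((gene.chrom, genomic(-250, 250)))
        window_sets["regulatory_region"].append((gene.chrom, genomic(-up, down - 1)))
    genic = {"exon": [], "intron": [], "five_prime_utr": []}
    for gene in genes:
        comp = gene_compartments(gene)
        genic["exon"].extend((gene.chrom, iv) for iv in comp["exons"])
        genic["intron"].extend((gene.chrom, iv) for iv in comp["introns"])
        genic["five_prime_utr"].extend((gene.chrom, iv) for iv in comp["five_utr"])
    for rec in strs:
        for name, items in list(window_sets.items()) + list(genic.items()):
            ivs = [iv for chrom, iv in items if chrom == rec.chrom]
            if overlaps_entity(rec, ivs):
                out[name].append(rec)
    for rec in strs:
        if rec.perMatch >= table_purity and any(
            rec.chrom == region.gene.chrom
            and rec.srStart >= region.windowStart
            and rec.srEnd <= region.windowEnd
            for region in regions
        ):
            out["table"].append(rec)
    return out


def split_by_cpg(
    table: pd.DataFrame, regions
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition table rows by their region's CpG-island overlap flag."""
    flags = {r.gene.transcriptId: r.cpgOverlap for r in regions}
    mask = table["refSeqId"].map(flags).fillna(False).astype(bool)
    return table[mask].reset_index(drop=True), table[~mask].reset_index(drop=True)


@dataclass
class PositionProfile:
    """Bundle of positional tracks over [-up, down-1]."""

    up: int
    down: int
    n_regions: int
    counts: np.ndarray
    density: np.ndarray
    per_period: np.ndarray
    mean_base_pct: np.ndarray
    mean_num_repeats: np.ndarray
    smoothed_density: np.ndarray
    lowess_frac: float = 0.1
    lowess_iters: int = 3

    @property
    def positions(self) -> np.ndarray:
        return np.arange(-self.up, self.down)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"position": self.positions})
        df["count"] = self.counts
        df["density"] = self.density
        df["density_smooth"] = self.smoothed_density
        for p in range(1, MAX_PERIOD + 1):
            df[f"count_p{p}"] = self.per_period[p - 1]
        for i, b in enumerate("ACGT"):
            df[f"mean_pct_{b}"] = self.mean_base_pct[i]
        df["mean_num_repeats"] = self.mean_num_repeats
        return df


def compute_profile(
    table: pd.DataFrame,
    n_regions: int,
    up: int = 2000,
    down: int = 1000,
    lowess_frac: float = 0.1,
    lowess_iters: int = 3,
) -> PositionProfile:
    """All positional tracks for one table (or table subset)."""
    counts = position_counts(table, up, down)
    density = to_density(counts, n_regions)
    per_period = decompose_by_period(table, up, down)
    mean_base, mean_copies = composition_profile(table, up, down)
    smoothed = lowess_smooth(density, frac=lowess_frac, iters=lowess_iters)
    return PositionProfile(
        up=up,
        down=down,
        n_regions=n_regions,
        counts=counts,
        density=density,
        per_period=per_period,
        mean_base_pct=mean_base,
        mean_num_repeats=mean_copies,
        smoothed_density=smoothed,
        lowess_frac=lowess_frac,
        lowess_iters=lowess_iters,
    )


def plot_profiles(profile: PositionProfile, path: str) -> None:
    """Convenience four-panel figure (density, periods, copies, bases)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(11, 7), sharex=True)
    x = profile.positions
    axes[0, 0].plot(x, profile.density, lw=0.4, alpha=0.5)
    axes[0, 0].plot(x, profile.smoothed_density, lw=1.5)
    axes[0, 0].set_title("STR density")
    for p in range(1, MAX_PERIOD + 1):
        axes[0, 1].plot(
            x,
            lowess_smooth(
                to_density(profile.per_period[p - 1], profile.n_regions),
                frac=profile.lowess_frac,
                iters=profile.lowess_iters,
            ),
            lw=1,
            label=str(p),
        )
    axes[0, 1].legend(title="period", fontsize=6, ncol=3)
    axes[0, 1].set_title("density by period")
    axes[1, 0].plot(x, profile.mean_num_repeats, lw=0.4)
    axes[1, 0].set_title("mean repeat units")
    for i, b in enumerate("ACGT"):
        axes[1, 1].plot(x, profile.mean_base_pct[i], lw=0.5, label=b)
    axes[1, 1].legend(fontsize=7)
    axes[1, 1].set_title("mean base %")
    for ax in axes.flat:
        ax.axvline(0, color="k", lw=0.5, ls="--")
    fig.supxlabel("position relative to TSS (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
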