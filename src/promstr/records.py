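"""Repeat-level data types and sequence metrics.

A short tandem repeat (STR, microsatellite) is a tandem repeat whose unit
("period") is 1-9 bp.  Records here mirror the fields of the UCSC
simpleRepeats table: genomic span, period, copy number, consensus motif,
purity (percent match to the consensus tiling), indel percentage, alignment
score, base composition and entropy.

The reporting arithmetic is fixed by two constants inferred from that table:
a per-base match weight of 2 and a minimum reported alignment score of 50,
which together imply a minimum reportable tract length of 25 bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

BASES = "ACGT"

__all__ = [
    "BASES",
    "ScoringParams",
    "STRRecord",
    "pure_repeat_score",
    "min_reportable_length",
    "infer_consensus",
    "compute_purity",
    "best_phase_matches",
    "base_composition",
    "compute_entropy",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero toward +inf (0.05 -> 0.1 at 1 digit)."""
    factor = 10.0**ndigits
    return math.floor(x * factor + 0.5) / factor


@dataclass(frozen=True)
class ScoringParams:
    """Reporting thresholds and alignment weights for STR records.

    match_weight and min_score are pinned by the source repeats table
    (weight 2, minimum score 50); mismatch/indel penalties follow Tandem
    Repeat Finder's published defaults and are configurable.
    """

    match_weight: int = 2
    mismatch_penalty: int = 7
    indel_penalty: int = 7
    min_score: int = 50
    max_period: int = 9
    min_purity: float = 90.0

    def __post_init__(self) -> None:
        for name in (
            "match_weight",
            "mismatch_penalty",
            "indel_penalty",
            "min_score",
            "min_purity",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.max_period < 1:
            raise ValueError("max_period must be >= 1")


@dataclass
class STRRecord:
    """One tandem repeat call over [srStart, srEnd) (0-based half-open)."""

    chrom: str
    srStart: int
    srEnd: int
    period: int
    numRepeats: float
    consensusSize: int
    perMatch: float
    perIndel: float
    score: float
    baseA: int
    baseC: int
    baseG: int
    baseT: int
    entropy: float
    sequence: str

    @property
    def srLength(self) -> int:
        return self.srEnd - self.srStart

    @property
    def interval(self) -> tuple[int, int]:
        return (self.srStart, self.srEnd)

    def violations(self) -> list[str]:
        """Invariant violations, empty when the record is well-formed."""
        out: list[str] = []
        if self.srEnd <= self.srStart:
            out.append(f"srEnd {self.srEnd} <= srStart {self.srStart}")
        if not 0 <= self.perMatch <= 100:
            out.append(f"perMatch {self.perMatch} outside [0, 100]")
        if not 0 <= self.perIndel <= 100:
            out.append(f"perIndel {self.perIndel} outside [0, 100]")
        if not 0 <= self.entropy <= 2 + 1e-9:
            out.append(f"entropy {self.entropy} outside [0, 2]")
        comp = self.baseA + self.baseC + self.baseG + self.baseT
        if not 97 <= comp <= 100:
            out.append(f"base composition sums to {comp}, expected 97..100")
        if self.period < 1:
            out.append(f"period {self.period} < 1")
        if self.perIndel == 0 and self.consensusSize > 0:
            expect = round_half_up(self.srLength / self.consensusSize, 1)
            if abs(self.numRepeats - expect) > 0.05 + 1e-9:
                out.append(
                    f"numRepeats {self.numRepeats} != srLength/consensusSize = {expect}"
                )
        return out


def pure_repeat_score(length_bp: int, params: ScoringParams | None = None) -> int:
    """Alignment score of a perfect tract: match_weight per base.

    A 39 bp pure dinucleotide (19.5 copies) scores 78 at weight 2; the
    25 bp minimum tract scores exactly the minimum score of 50.
    """
    params = params or ScoringParams()
    if length_bp < 0:
        raise ValueError(f"tract length must be >= 0, got {length_bp}")
    return params.match_weight * length_bp


def min_reportable_length(params: ScoringParams | None = None) -> int:
    """Shortest tract whose pure score reaches min_score: ceil(min_score/weight)."""
    params = params or ScoringParams()
    if params.match_weight == 0:
        raise ValueError("match_weight must be > 0 to bound tract length")
    return math.ceil(params.min_score / params.match_weight)


def infer_consensus(tract: str, period: int) -> str:
    """Column-majority consensus of a tract phased at the given period.

    Column j collects tract[j], tract[j+period], ...; ties break
    alphabetically (A < C < G < T).
    """
    if not 1 <= period <= len(tract):
        raise ValueError(f"period {period} outside [1, len(tract)={len(tract)}]")
    bad = set(tract) - set(BASES)
    if bad:
        raise ValueError(f"non-ACGT characters in tract: {sorted(bad)}")
    out = []
    for j in range(period):
        column = tract[j::period]
        best = max(BASES, key=lambda b: (column.count(b), -BASES.index(b)))
        out.append(best)
    return "".join(out)


def best_phase_matches(tract: str, motif: str) -> tuple[int, int]:
    """(match count, phase) of the best indel-free tiling of motif over tract.

    Phase r compares tract[i] with motif[(i + r) % len(motif)]. 'N' never
    matches.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if not tract:
        raise ValueError("tract must be non-empty")
    p = len(motif)
    best, best_phase = -1, 0
    for r in range(p):
        m = sum(1 for i, c in enumerate(tract) if c == motif[(i + r) % p])
        if m > best:
            best, best_phase = m, r
    return best, best_phase


def compute_purity(tract: str, motif: str) -> int:
    """Percent of tract positions matching the best-phase motif tiling.

    Indel-free: the motif is tiled across the tract at each of the
    len(motif) phases and the best phase is reported, rounded to the
    nearest integer percent.
    """
    matches, _ = best_phase_matches(tract, motif)
    return int(round_half_up(100.0 * matches / len(tract)))


def base_composition(tract: str) -> tuple[int, int, int, int]:
    """Integer-truncated (A, C, G, T) percentages over the tract.

    'N' bases are excluded from both numerator and denominator, so the
    four components always sum to 97..100 by truncation.
    """
    if not tract:
        raise ValueError("tract must be non-empty")
    denom = sum(tract.count(b) for b in BASES)
    if denom == 0:
        raise ValueError("tract contains no A/C/G/T bases")
    return tuple(int(100 * tract.count(b) // denom) for b in BASES)  # type: ignore[return-value]


def compute_entropy(pA: float, pC: float, pG: float, pT: float) -> float:
    """Shannon entropy in bits of the base-composition distribution.

    0 for a homopolymer, 2 at uniform composition.
    """
    ps = (pA, pC, pG, pT)
    if any(p < 0 for p in ps):
        raise ValueError("composition fractions must be non-negative")
    return -sum(p * math.log2(p) for p in ps if p > 0) + 0.0
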