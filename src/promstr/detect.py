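"""Substitution-only tandem repeat detection for periods 1-9.

The detector exists so the pipeline runs on synthetic genomes without a
precomputed repeats table.  It is deliberately indel-free: candidates are
seeded from exact runs in the period-p autocorrelation indicator
m[i] = (s[i] == s[i-p]), extended across short mismatch runs, trimmed to
the span maximising match_weight*matches - mismatch_penalty*mismatches,
and finally scored against the column-majority consensus.  Records below
the minimum score or the reporting purity floor are dropped; overlapping
calls sharing at least half of the shorter span are resolved by score,
then smaller period, then leftmost start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import (
    STRRecord,
    ScoringParams,
    base_composition,
    best_phase_matches,
    compute_entropy,
    infer_consensus,
    round_half_up,
)

__all__ = ["DetectorConfig", "primitive_motif", "scan_period", "detect_strs"]


@dataclass(frozen=True)
class DetectorConfig:
    """Detector tuning.

    seed_len: exact autocorrelation run required to open a candidate; the
    effective seed for period p is max(seed_len, 2*p).  max_gap: longest
    run of autocorrelation mismatches tolerated inside a candidate
    (defaults to the period).  report_min_purity sits below the table's
    90% purity filter so downstream filtering is observable.
    """

    scoring: ScoringParams = field(default_factory=ScoringParams)
    seed_len: int = 12
    max_gap: int | None = None
    report_min_purity: float = 80.0

    def gap_for(self, period: int) -> int:
        return self.max_gap if self.max_gap is not None else period

    def seed_for(self, period: int) -> int:
        return max(self.seed_len, 2 * period)


def primitive_motif(motif: str) -> str:
    """Smallest unit u such that the motif is u repeated (possibly once)."""
    if not motif:
        raise ValueError("motif must be non-empty")
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return motif[:d]
    return motif


def scan_period(
    sequence: str, period: int, cfg: DetectorConfig | None = None
) -> list[tuple[int, int]]:
    """Candidate half-open spans for one period, pre-filtering.

    Candidates contain an exact autocorrelation match run >= the effective
    seed length, never contain a mismatch run longer than max_gap, and are
    trimmed at both ends to the score-optimal span.
    """
    cfg = cfg or DetectorConfig()
    if not 1 <= period <= cfg.scoring.max_period:
        raise ValueError(f"period {period} outside [1, {cfg.scoring.max_period}]")
    seed = cfg.seed_for(period)
    gap = cfg.gap_for(period)
    if len(sequence) < period + seed:
        return []
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    ok = arr != ord("N")
    m = (arr[period:] == arr[:-period]) & ok[period:] & ok[:-period]
    if not m.any():
        return []
    # run-length encode the indicator
    edges = np.flatnonzero(np.diff(m)) + 1
    starts = np.concatenate(([0], edges))
    ends = np.concatenate((edges, [m.size]))
    vals = m[starts]
    lens = ends - starts
    seed_runs = np.flatnonzero(vals & (lens >= seed))
    if seed_runs.size == 0:
        return []
    w = cfg.scoring.match_weight
    pen = cfg.scoring.mismatch_penalty
    spans: list[tuple[int, int]] = []
    for ri in seed_runs:
        # Each seed run is trimmed independently: a block may contain two
        # distinct repeats separated by a tolerated-but-costly gap, and
        # each must be reported with its own optimal span.
        lo = hi = int(ri)
        while lo - 2 >= 0 and lens[lo - 1] <= gap:
            lo -= 2
        while hi + 2 < len(vals) and lens[hi + 1] <= gap:
            hi += 2
        b0, b1 = int(starts[lo]), int(ends[hi])
        v = np.where(m[b0:b1], w, -pen)
        prefix = np.concatenate(([0], np.cumsum(v)))
        s0 = int(starts[ri]) - b0
        s1 = int(ends[ri]) - b0
        # best right cut at/after the seed end, best left cut at/before the seed start
        right = s1 + int(np.argmax(prefix[s1 : b1 - b0 + 1]))
        left = int(np.argmin(prefix[: s0 + 1]))
        # tract = template unit + matched positions [b0+left, b0+right) of m
        span = (b0 + left, b0 + right + period)
        if span not in spans:
            spans.append(span)
    return spans


def _refine_span(
    sequence: str, start: int, end: int, period: int, params: ScoringParams
) -> tuple[int, int]:
    """Re-optimise a span against the consensus-tiling score.

    Used after the autocorrelation trim (which double-counts substitutions)
    and after a non-primitive consensus is collapsed to a smaller period.
    The consensus and phase are anchored on the current span; the span is
    then moved to the score-optimal cut on each side within a bounded
    neighbourhood.
    """
    motif = infer_consensus(sequence[start:end], period)
    _, phase = best_phase_matches(sequence[start:end], motif)
    ext = 2 * period + 16
    ra = max(0, start - ext)
    rb = min(len(sequence), end + ext)
    v = np.empty(rb - ra, dtype=np.int64)
    for k, j in enumerate(range(ra, rb)):
        hit = sequence[j] == motif[(j - start + phase) % period]
        v[k] = params.match_weight if hit else -params.mismatch_penalty
    prefix = np.concatenate(([0], np.cumsum(v)))
    mid = (start + end) // 2 - ra
    left = int(np.argmin(prefix[: mid + 1]))
    right = mid + int(np.argmax(prefix[mid : rb - ra + 1]))
    if right - left < period:
        return start, end
    return ra + left, ra + right


def detect_strs(
    sequence: str, cfg: DetectorConfig | None = None, chrom: str = "seq"
) -> list[STRRecord]:
    """Detect STRs over periods 1..max_period in one sequence.

    Candidates with a non-primitive consensus are collapsed to the
    primitive period and re-trimmed before overlap resolution.  Returned
    records are sorted by (chrom, srStart); perIndel is always 0.
    """
    cfg = cfg or DetectorConfig()
    params = cfg.scoring
    if not sequence:
        return []
    candidates: dict[tuple[int, int, int], dict] = {}
    for period in range(1, params.max_period + 1):
        for a, b in scan_period(sequence, period, cfg):
            tract = sequence[a:b]
            if "N" in tract:
                continue
            p = period
            for _ in range(3):  # primitive collapse may cascade at most twice
                motif = infer_consensus(tract, p)
                prim = primitive_motif(motif)
                if len(prim) == p:
                    break
                p = len(prim)
                a, b = _refine_span(sequence, a, b, p, params)
                tract = sequence[a:b]
            a, b = _refine_span(sequence, a, b, p, params)
            tract = sequence[a:b]
            motif = infer_consensus(tract, p)
            matches, _ = best_phase_matches(tract, motif)
            mismatches = len(tract) - matches
            score = params.match_weight * matches - params.mismatch_penalty * mismatches
            purity = int(round_half_up(100.0 * matches / len(tract)))
            if score < params.min_score or purity < cfg.report_min_purity:
                continue
            key = (a, b, p)
            prev = candidates.get(key)
            if prev is None or score > prev["score"]:
                candidates[key] = {
                    "start": a,
                    "end": b,
                    "period": p,
                    "motif": motif,
                    "score": score,
                    "purity": purity,
                    "tract": tract,
                }
    kept: list[dict] = []
    for cand in sorted(
        candidates.values(), key=lambda c: (-c["score"], c["period"], c["start"])
    ):
        conflict = False
        for other in kept:
            ov = min(cand["end"], other["end"]) - max(cand["start"], other["start"])
            shorter = min(
                cand["end"] - cand["start"], other["end"] - other["start"]
            )
            if ov >= 0.5 * shorter:
                conflict = True
                break
        if not conflict:
            kept.append(cand)
    records = []
    for c in sorted(kept, key=lambda c: c["start"]):
        comp = base_composition(c["tract"])
        denom = sum(c["tract"].count(b) for b in "ACGT")
        fracs = tuple(c["tract"].count(b) / denom for b in "ACGT")
        length = c["end"] - c["start"]
        records.append(
            STRRecord(
                chrom=chrom,
                srStart=c["start"],
                srEnd=c["end"],
                period=c["period"],
                numRepeats=round_half_up(length / c["period"], 1),
                consensusSize=c["period"],
                perMatch=c["purity"],
                perIndel=0,
                score=c["score"],
                baseA=comp[0],
                baseC=comp[1],
                baseG=comp[2],
                baseT=comp[3],
                entropy=compute_entropy(*fracs),
                sequence=c["motif"],
            )
        )
    return records


def detect_genome(
    sequences: dict[str, str], cfg: DetectorConfig | None = None
) -> list[STRRecord]:
    """detect_strs over a chromosome dict, sorted by (chrom, srStart)."""
    out: list[STRRecord] = []
    for chrom in sorted(sequences):
        out.extend(detect_strs(sequences[chrom], cfg, chrom=chrom))
    return out
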