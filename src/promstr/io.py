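"""Readers and writers for the pipeline's tab-separated dialects.

Formats: the simpleRepeats dialect (chrom, chromStart, chromEnd, period,
copyNum, consensusSize, perMatch, perIndel, score, A, C, G, T, entropy,
sequence), genePred-like gene tables (see genes.read_gene_table), BED3
CpG islands, the 30-column repeat table and term-map TSVs.  Every output
carries a metadata comment header (tool version, config hash, seed) so it
can be reproduced.
"""

from __future__ import annotations

import hashlib
import json
import logging

import pandas as pd

from .mapping import TABLE_COLUMNS
from .records import STRRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SIMPLE_REPEATS_COLUMNS",
    "ParseError",
    "read_simple_repeats",
    "write_simple_repeats",
    "read_bed",
    "read_fasta_lengths",
    "write_repeat_table",
    "read_repeat_table",
    "read_term_map",
    "metadata_lines",
]

SIMPLE_REPEATS_COLUMNS = [
    "chrom",
    "chromStart",
    "chromEnd",
    "period",
    "copyNum",
    "consensusSize",
    "perMatch",
    "perIndel",
    "score",
    "A",
    "C",
    "G",
    "T",
    "entropy",
    "sequence",
]


class ParseError(ValueError):
    pass


def metadata_lines(params: dict, seed: int | None = None) -> list[str]:
    """Reproducibility header: version, parameter hash and parameters."""
    from . import __version__

    payload = json.dumps(params, sort_keys=True, default=str)
    digest = hashlib.sha256(payload.encode()).hexdigest()[:12]
    lines = [f"# promstr_version={__version__}", f"# config_hash={digest}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    for key in sorted(params):
        lines.append(f"# param {key}={params[key]}")
    return lines


def read_simple_repeats(path: str) -> list[STRRecord]:
    """Parse a simpleRepeats-dialect TSV into validated STRRecords.

    A header line is optional.  Records violating type invariants are
    rejected with logged line numbers; missing columns or non-numeric
    coordinates raise ParseError.
    """
    records: list[STRRecord] = []
    first_data = True
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < len(SIMPLE_REPEATS_COLUMNS):
                raise ParseError(
                    f"{path}:{line_no}: expected {len(SIMPLE_REPEATS_COLUMNS)} "
                    f"columns, got {len(fields)}"
                )
            if first_data and not fields[1].lstrip("-").isdigit():
                first_data = False
                continue  # header
            first_data = False
            try:
                rec = STRRecord(
                    chrom=fields[0],
                    srStart=int(fields[1]),
                    srEnd=int(fields[2]),
                    period=int(fields[3]),
                    numRepeats=float(fields[4]),
                    consensusSize=int(fields[5]),
                    perMatch=float(fields[6]),
                    perIndel=float(fields[7]),
                    score=float(fields[8]),
                    baseA=int(fields[9]),
                    baseC=int(fields[10]),
                    baseG=int(fields[11]),
                    baseT=int(fields[12]),
                    entropy=float(fields[13]),
                    sequence=fields[14],
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{line_no}: {exc}") from exc
            problems = rec.violations()
            if problems:
                logger.warning(
                    "rejecting repeat at %s:%d: %s", path, line_no, "; ".join(problems)
                )
                continue
            records.append(rec)
    return records


def write_simple_repeats(records: list[STRRecord], path: str) -> None:
    """Serialise records in the documented simpleRepeats column order."""
    with open(path, "w") as fh:
        fh.write("\t".join(SIMPLE_REPEATS_COLUMNS) + "\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.srStart)):
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(r.srStart),
                        str(r.srEnd),
                        str(r.period),
                        f"{r.numRepeats:.1f}",
                        str(r.consensusSize),
                        f"{r.perMatch:g}",
                        f"{r.perIndel:g}",
                        f"{r.score:g}",
                        str(r.baseA),
                        str(r.baseC),
                        str(r.baseG),
                        str(r.baseT),
                        f"{r.entropy:.4f}",
                        r.sequence,
                    ]
                )
                + "\n"
            )


def read_bed(path: str) -> list[tuple[str, int, int]]:
    """BED3+ intervals (chrom, start, end), extra columns ignored."""
    out = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{line_no}: BED needs >= 3 columns")
            try:
                out.append((fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise ParseError(f"{path}:{line_no}: {exc}") from exc
    return out


def read_fasta_lengths(path: str) -> dict[str, int]:
    """Chromosome lengths via the FASTA index."""
    from pyfaidx import Fasta

    with Fasta(path) as fa:
        return {name: len(fa[name]) for name in fa.keys()}


def _format_value(col: str, value) -> str:
    if col == "numRepeats":
        return f"{float(value):.1f}"
    if col == "Entropy":
        return f"{float(value):.2f}"
    if col in ("perMatch", "perIndel", "Score"):
        return f"{float(value):g}"
    return str(value)


def write_repeat_table(
    table: pd.DataFrame, path: str, params: dict | None = None, seed: int | None = None
) -> None:
    """Write the repeat table in the exact 30-column order, bit-stable."""
    with open(path, "w") as fh:
        for line in metadata_lines(params or {}, seed):
            fh.write(line + "\n")
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for _, row in table.iterrows():
            fh.write(
                "\t".join(_format_value(c, row[c]) for c in TABLE_COLUMNS) + "\n"
            )


def read_repeat_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing repeat-table columns {missing}")
    return df[TABLE_COLUMNS]


def read_term_map(path: str) -> dict[str, set[str]]:
    """Two-column TSV (term_id, gene_id) -> term -> gene set."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{line_no}: term map needs 2 columns")
            out.setdefault(fields[0], set()).add(fields[1])
    return out
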