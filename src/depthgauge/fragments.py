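"""Resolve paired-end alignments into strand-specific fragments.

A proper pair (mates on the same contig, opposite strands, inward-facing,
outer span <= 450 bp) becomes one fragment spanning from the leftmost mate
start to the rightmost mate end — the gap between mates, if any, is filled.
For an improper pair one mate is discarded (the mate with the lower genomic
start is kept, deterministically) and the survivor, like any unpaired read,
becomes an orphan fragment of its own extent.

The transcript strand of a fragment depends on the library chemistry; under
the default dUTP protocol the second cDNA strand is destroyed before
amplification, so R2 maps to the transcript strand ("dUTP_R2_sense").
The alternative "R1_sense" convention is the exact mirror.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
import pysam

from .model import fragments_frame, empty_fragments

logger = logging.getLogger(__name__)

PROTOCOLS = ("dUTP_R2_sense", "R1_sense")

DEFAULT_MAX_SPAN = 450


@dataclass(frozen=True)
class ReadAlignment:
    """One aligned read (0-based half-open interval)."""

    read_id: str
    contig: str
    start: int
    end: int
    strand: str
    read_number: int = 0  # 1, 2, or 0 for an unpaired read
    is_paired: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"read {self.read_id!r}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"read {self.read_id!r}: strand must be + or -")


def fragment_strand(read: ReadAlignment, protocol: str = "dUTP_R2_sense") -> str:
    """Transcript strand implied by one read's orientation and role.

    Under dUTP_R2_sense, R2 (and an unpaired read, treated as R2-like) maps
    on the transcript strand while R1 maps opposite; R1_sense mirrors this.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"protocol must be one of {PROTOCOLS}")
    flip = {"+": "-", "-": "+"}
    r2_like = read.read_number != 1
    if protocol == "dUTP_R2_sense":
        return read.strand if r2_like else flip[read.strand]
    return flip[read.strand] if r2_like else read.strand


@dataclass
class ResolveResult:
    """Fragments plus the pairing bookkeeping."""

    fragments: pd.DataFrame
    n_proper: int = 0
    n_improper: int = 0
    n_unpaired: int = 0
    n_malformed: int = 0

    @property
    def n_templates(self) -> int:
        return self.n_proper + self.n_improper + self.n_unpaired


def _is_proper(r1: ReadAlignment, r2: ReadAlignment, max_span: int) -> bool:
    if r1.contig != r2.contig or r1.strand == r2.strand:
        return False
    fwd, rev = (r1, r2) if r1.strand == "+" else (r2, r1)
    if fwd.start > rev.start:  # outward-facing
        return False
    span = max(r1.end, r2.end) - min(r1.start, r2.start)
    return span <= max_span


def resolve_fragments(
    alignments,
    max_span: int = DEFAULT_MAX_SPAN,
    protocol: str = "dUTP_R2_sense",
) -> ResolveResult:
    """Turn a stream of :class:`ReadAlignment` into a fragment table.

    Mates are matched by read_id. Each input template yields exactly one
    fragment: a gap-filled pair fragment when proper, otherwise an orphan.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"protocol must be one of {PROTOCOLS}")
    pending: dict[str, ReadAlignment] = {}
    rows = []
    res = ResolveResult(fragments=empty_fragments())

    def emit_orphan(read: ReadAlignment) -> None:
        rows.append(
            (read.contig, read.start, read.end, fragment_strand(read, protocol),
             read.read_id, "orphan")
        )

    for read in alignments:
        if not read.is_paired:
            res.n_unpaired += 1
            emit_orphan(read)
            continue
        mate = pending.pop(read.read_id, None)
        if mate is None:
            pending[read.read_id] = read
            continue
        if _is_proper(mate, read, max_span):
            res.n_proper += 1
            start = min(mate.start, read.start)
            end = max(mate.end, read.end)
            r2 = read if read.read_number == 2 else mate
            rows.append(
                (read.contig, start, end, fragment_strand(r2, protocol),
                 read.read_id, "pair")
            )
        else:
            res.n_improper += 1
            keep = mate if mate.start <= read.start else read
            emit_orphan(keep)

    # Mates that never showed up: their partner reads count as unpaired.
    for read in pending.values():
        res.n_unpaired += 1
        emit_orphan(read)

    if rows:
        res.fragments = fragments_frame(rows)
    return res


def read_sam(path):
    """Yield :class:`ReadAlignment` from a SAM/BAM file.

    Secondary, supplementary and unmapped records are skipped (each
    fragment is counted once); malformed records are counted and skipped.
    """
    n_malformed = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            try:
                yield ReadAlignment(
                    read_id=rec.query_name,
                    contig=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    read_number=2 if rec.is_read2 else (1 if rec.is_read1 else 0),
                    is_paired=rec.is_paired,
                )
            except (ValueError, TypeError):
                n_malformed += 1
    if n_malformed:
        logger.warning("read_sam: skipped %d malformed records", n_malformed)


def resolve_sam(path, max_span: int = DEFAULT_MAX_SPAN, protocol: str = "dUTP_R2_sense") -> ResolveResult:
    """Convenience: read a SAM/BAM file and resolve it into fragments."""
    return resolve_fragments(read_sam(path), max_span=max_span, protocol=protocol)
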