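"""Readers and writers for the standard formats at the package boundary.

Internal coordinates are 0-based half-open everywhere; GFF3 (1-based
inclusive) and SAM (1-based) conversions happen only here.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pysam

from .model import FRAGMENT_COLUMNS, AnnotationSet, Feature, GenomeModel, empty_fragments

logger = logging.getLogger(__name__)

_TSV_HEADER = ["contig", "start", "end", "strand", "fragment_id"]


def write_fragment_tsv(fragments: pd.DataFrame, path) -> None:
    """Write the simplified fragment format: contig, start (0-based), end
    (exclusive), strand, fragment_id."""
    fragments.loc[:, _TSV_HEADER].to_csv(path, sep="\t", index=False)


def read_fragment_tsv(path) -> pd.DataFrame:
    """Read a fragment TSV; rows with end <= start are dropped and counted.

    The number of rejected rows is available as ``df.attrs["n_rejected"]``.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"contig": object, "start": np.int64, "end": np.int64,
               "strand": object, "fragment_id": object},
    )
    if df.empty:
        out = empty_fragments()
        out.attrs["n_rejected"] = 0
        return out
    bad = (df["end"] <= df["start"]) | ~df["strand"].isin(["+", "-"])
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("read_fragment_tsv: rejected %d malformed lines", n_bad)
    df = df.loc[~bad].reset_index(drop=True)
    df["origin"] = "pair"
    df = df.loc[:, list(FRAGMENT_COLUMNS)]
    df.attrs["n_rejected"] = n_bad
    return df


def write_fasta(genome: GenomeModel, path, seed: int = 0, line_width: int = 70) -> None:
    """Write a random-ACGT FASTA of the genome (only lengths matter downstream)."""
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACGT"), size=genome.length)
    with open(path, "w") as fh:
        fh.write(f">{genome.contig}\n")
        for i in range(0, genome.length, line_width):
            fh.write("".join(seq[i : i + line_width]) + "\n")


_GFF_TYPE = {"ORF": "CDS", "ncRNA": "ncRNA", "rRNA": "rRNA"}
_GFF_TYPE_INV = {"CDS": "ORF", "gene": "ORF", "ncRNA": "ncRNA", "rRNA": "rRNA"}


def write_gff3(annotation: AnnotationSet, path) -> None:
    """GFF3 writer (1-based inclusive); feature class goes in the type column."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {annotation.contig} 1 {annotation.length}\n")
        for f in annotation.features:
            fh.write(
                "\t".join(
                    [
                        annotation.contig,
                        "depthgauge",
                        _GFF_TYPE[f.feature_class],
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        f"ID={f.feature_id}",
                    ]
                )
                + "\n"
            )


def read_gff3(path, length: int | None = None) -> AnnotationSet:
    """Read a GFF3 produced by :func:`write_gff3` (or a compatible subset).

    Unrecognised feature types are skipped. Genome length is taken from the
    ``##sequence-region`` pragma unless given explicitly.
    """
    contig = None
    seq_len = length
    features: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if seq_len is None and len(parts) >= 4:
                    seq_len = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                continue
            ftype = _GFF_TYPE_INV.get(cols[2])
            if ftype is None:
                continue
            contig = contig or cols[0]
            fid = ""
            for kv in cols[8].split(";"):
                if kv.startswith("ID="):
                    fid = kv[3:]
            features.append(Feature(fid, ftype, int(cols[3]) - 1, int(cols[4]), cols[6]))
    if contig is None:
        contig = "chr"
    if seq_len is None:
        raise ValueError("genome length not found in GFF3; pass length= explicitly")
    return AnnotationSet(contig=contig, length=seq_len, features=features)


def write_bed6(annotation: AnnotationSet, path) -> None:
    """BED6 writer (0-based half-open); class prefixes the name column."""
    with open(path, "w") as fh:
        for f in annotation.features:
            fh.write(
                f"{annotation.contig}\t{f.start}\t{f.end}\t"
                f"{f.feature_class}:{f.feature_id}\t0\t{f.strand}\n"
            )


def read_bed6(path, length: int) -> AnnotationSet:
    contig = "chr"
    features: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            cols = line.rstrip("\n").split("\t")
            contig = cols[0]
            fclass, _, fid = cols[3].partition(":")
            features.append(Feature(fid or cols[3], fclass, int(cols[1]), int(cols[2]), cols[5]))
    return AnnotationSet(contig=contig, length=length, features=features)


def write_fragments_sam(
    fragments: pd.DataFrame, genome: GenomeModel, read_len: int, path
) -> None:
    """Emit each fragment as a properly paired read pair in SAM.

    Under the dUTP protocol convention R2 carries the transcript strand:
    a plus-strand fragment yields a forward R2 at its 5' end and a reverse
    R1 at its 3' end; minus-strand fragments mirror this. Sequences are
    written as N runs (only coordinates matter downstream).
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": genome.contig, "LN": genome.length}],
        }
    )
    FLAG_PAIRED, FLAG_PROPER = 0x1, 0x2
    FLAG_REV, FLAG_MREV = 0x10, 0x20
    FLAG_R1, FLAG_R2 = 0x40, 0x80

    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in fragments.itertuples(index=False):
            s, e = int(row.start), int(row.end)
            span = e - s
            rl = min(read_len, span)
            left_pos, right_pos = s, e - rl
            if row.strand == "+":
                left_flag = FLAG_PAIRED | FLAG_PROPER | FLAG_R2 | FLAG_MREV
                right_flag = FLAG_PAIRED | FLAG_PROPER | FLAG_R1 | FLAG_REV
            else:
                left_flag = FLAG_PAIRED | FLAG_PROPER | FLAG_R1 | FLAG_MREV
                right_flag = FLAG_PAIRED | FLAG_PROPER | FLAG_R2 | FLAG_REV
            for pos, flag, mate_pos, tlen in (
                (left_pos, left_flag, right_pos, span),
                (right_pos, right_flag, left_pos, -span),
            ):
                a = pysam.AlignedSegment(header)
                a.query_name = row.fragment_id
                a.flag = flag
                a.reference_id = 0
                a.reference_start = pos
                a.mapping_quality = 60
                a.cigarstring = f"{rl}M"
                a.next_reference_id = 0
                a.next_reference_start = mate_pos
                a.template_length = tlen
                a.query_sequence = "N" * rl
                a.query_qualities = pysam.qualitystring_to_array("I" * rl)
                out.write(a)


def write_bedgraph(values: np.ndarray, contig: str, path) -> None:
    """Write a per-position vector as a run-length-collapsed bedGraph."""
    vals = np.asarray(values)
    change = np.flatnonzero(np.diff(vals)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(vals)]))
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            v = vals[s]
            if v != 0:
                fh.write(f"{contig}\t{s}\t{e}\t{v:g}\n")
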