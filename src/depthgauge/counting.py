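"""Fragment-to-feature assignment with strand-aware fractional counting.

A fragment overlapping k >= 1 annotated features (by at least 1 bp,
regardless of strand) contributes 1/k to each: to the feature's sense
column when the strands agree, otherwise to its antisense column. A
fragment overlapping no feature goes to the unassigned tally, so fragment
mass is conserved exactly.

RPKM uses non-rRNA fragments as its depth denominator, the unit in which
sequencing-depth recommendations are expressed: fragments assigned to rRNA
genes are informative about depletion efficiency, not about the mRNA pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AnnotationSet

logger = logging.getLogger(__name__)


@dataclass
class CountTable:
    """Per-feature sense/antisense fragment counts (fractional allowed).

    ``table`` is indexed by feature_id with columns feature_class, length,
    strand, sense_count, antisense_count.
    """

    table: pd.DataFrame
    total_fragments: float
    unassigned: float

    @property
    def rrna_assigned(self) -> float:
        m = self.table["feature_class"] == "rRNA"
        return float(
            self.table.loc[m, ["sense_count", "antisense_count"]].to_numpy().sum()
        )

    @property
    def non_rrna_fragments(self) -> float:
        return self.total_fragments - self.rrna_assigned

    def assigned_mass(self) -> float:
        return float(self.table[["sense_count", "antisense_count"]].to_numpy().sum())


def _overlaps_sorted(annotation: AnnotationSet):
    """Features sorted by start, with a flag for the fast non-overlap path."""
    feats = annotation.to_frame().sort_values("start")
    starts = feats["start"].to_numpy()
    ends = feats["end"].to_numpy()
    non_overlapping = bool((starts[1:] >= ends[:-1]).all()) if len(feats) > 1 else True
    return feats, starts, ends, non_overlapping


def assign_fragments(fragments: pd.DataFrame, annotation: AnnotationSet) -> CountTable:
    """Count fragments per feature with 1/k splitting across overlaps.

    Uses a vectorised interval join when the annotation is non-overlapping
    (the common bacterial case); falls back to an interval tree otherwise.
    """
    feats, f_starts, f_ends, disjoint = _overlaps_sorted(annotation)
    n_feat = len(feats)
    sense = np.zeros(n_feat)
    anti = np.zeros(n_feat)
    unassigned = 0.0
    n_frag = len(fragments)

    if n_frag and n_feat:
        q_start = fragments["start"].to_numpy()
        q_end = fragments["end"].to_numpy()
        q_strand = (fragments["strand"] == "+").to_numpy()
        feat_plus = (feats["strand"] == "+").to_numpy()

        if disjoint:
            # Features with f_start < q_end and f_end > q_start form a
            # contiguous index run when intervals are disjoint and sorted.
            lo = np.searchsorted(f_ends, q_start, side="right")
            hi = np.searchsorted(f_starts, q_end, side="left")
            k = hi - lo
            unassigned = float((k <= 0).sum())
            one = k == 1
            if one.any():
                idx = lo[one]
                same = feat_plus[idx] == q_strand[one]
                np.add.at(sense, idx[same], 1.0)
                np.add.at(anti, idx[~same], 1.0)
            multi = np.flatnonzero(k > 1)
            for i in multi:
                w = 1.0 / k[i]
                for j in range(lo[i], hi[i]):
                    if feat_plus[j] == q_strand[i]:
                        sense[j] += w
                    else:
                        anti[j] += w
        else:
            from intervaltree import IntervalTree

            tree = IntervalTree()
            for j in range(n_feat):
                tree.addi(int(f_starts[j]), int(f_ends[j]), j)
            for i in range(n_frag):
                hits = tree.overlap(int(q_start[i]), int(q_end[i]))
                if not hits:
                    unassigned += 1.0
                    continue
                w = 1.0 / len(hits)
                for iv in hits:
                    j = iv.data
                    if feat_plus[j] == q_strand[i]:
                        sense[j] += w
                    else:
                        anti[j] += w

    table = pd.DataFrame(
        {
            "feature_class": feats["feature_class"],
            "length": feats["length"],
            "strand": feats["strand"],
            "sense_count": sense,
            "antisense_count": anti,
        },
        index=feats.index,
    )
    return CountTable(table=table, total_fragments=float(n_frag), unassigned=unassigned)


def detection_summary(counts: CountTable, min_fragments=(1, 5, 10, 20)) -> pd.DataFrame:
    """Features detected (sense_count >= threshold) at each threshold.

    Fractional counts are compared as-is. rRNA features are excluded from
    the detection denominator only if you pre-filter; by default all
    annotated features count.
    """
    thresholds = [t for t in min_fragments]
    if any(t < 1 for t in thresholds):
        raise ValueError("min_fragments thresholds must be >= 1")
    sc = counts.table["sense_count"].to_numpy()
    n = len(sc)
    rows = [
        (t, int((sc >= t).sum()), (sc >= t).sum() / n if n else np.nan)
        for t in thresholds
    ]
    return pd.DataFrame(rows, columns=["threshold", "n_detected", "fraction"])


def rrna_fraction(counts: CountTable) -> float:
    """Fraction of all fragments assigned to rRNA features.

    Returns NaN for an empty dataset; 0 (with a logged note) when the
    annotation has no rRNA features at all.
    """
    if counts.total_fragments == 0:
        return float("nan")
    if not (counts.table["feature_class"] == "rRNA").any():
        logger.info("rrna_fraction: annotation has no rRNA features; returning 0")
        return 0.0
    return counts.rrna_assigned / counts.total_fragments


def rpkm(counts: CountTable) -> pd.Series:
    """RPKM per feature: sense_count * 1e9 / (length * non-rRNA fragments)."""
    denom = counts.non_rrna_fragments
    if denom <= 0:
        return pd.Series(np.nan, index=counts.table.index, name="rpkm")
    vals = counts.table["sense_count"] * 1e9 / (counts.table["length"] * denom)
    vals.name = "rpkm"
    return vals


def sense_antisense_correlation(counts: CountTable, feature_class: str = "ORF") -> float:
    """R^2 of per-feature mean sense vs antisense coverage, a strand-
    specificity QC.

    Mean per-base coverage on each strand of a feature is proportional to
    count / length (the constant mean fragment length cancels), so the R^2
    is computed on those ratios. Near-zero R^2 indicates clean strand
    separation; a high R^2 mimics a library whose second strand was not
    removed. Returns NaN when fewer than 3 usable features or a degenerate
    variance makes the correlation undefined.
    """
    t = counts.table[counts.table["feature_class"] == feature_class]
    if len(t) < 3:
        return float("nan")
    x = (t["sense_count"] / t["length"]).to_numpy()
    y = (t["antisense_count"] / t["length"]).to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def counts_to_tsv(counts: CountTable, path) -> None:
    out = counts.table.copy()
    out["rpkm"] = rpkm(counts)
    out.to_csv(path, sep="\t", index_label="feature_id")
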