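"""Sequencing-depth experiments: subsampling, count scaling, saturation.

Saturation curves are built by nested (telescoping) subsampling: one random
permutation of the fragment table is drawn and each requested depth takes a
prefix of it, so every smaller dataset is a subset of every larger one and
detection/coverage metrics are monotone in depth pathwise, not just in
expectation. Independent per-depth samples are available via
``nested=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import (
    PositionCategories,
    categorize_positions,
    compute_coverage,
    coverage_summary,
    subtract_background,
)
from .counting import CountTable, assign_fragments, detection_summary
from .model import AnnotationSet


def subsample_fragments(fragments: pd.DataFrame, n_target: int, seed: int = 0) -> pd.DataFrame:
    """Simple random sample of exactly n_target fragments, without replacement."""
    n = len(fragments)
    if n_target > n:
        raise ValueError(f"cannot sample {n_target} fragments from {n}")
    if n_target < 0:
        raise ValueError("n_target must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(71,)))
    idx = rng.choice(n, size=n_target, replace=False)
    return fragments.iloc[np.sort(idx)].reset_index(drop=True)


@dataclass
class ScaledCounts:
    """A CountTable scaled to a fraction f of its original depth."""

    counts: CountTable
    f: float
    mode: str


def scale_counts(
    counts: CountTable, f: float, mode: str = "proportional", seed: int = 0
) -> ScaledCounts:
    """Scale per-feature counts to a depth fraction f in (0, 1].

    proportional (default)
        count -> round(count * f), round-half-even; relative expression
        between genes is preserved exactly before rounding.
    binomial
        count -> Binomial(round(count), f) per feature: the stochastic
        thinning a real subsampling of fragments would produce, preserving
        expectation.
    """
    if not 0.0 < f <= 1.0:
        raise ValueError(f"scale fraction must be in (0, 1], got {f}")
    if mode not in ("proportional", "binomial"):
        raise ValueError("mode must be 'proportional' or 'binomial'")
    t = counts.table.copy()
    if mode == "proportional":
        t["sense_count"] = np.round(t["sense_count"] * f)
        t["antisense_count"] = np.round(t["antisense_count"] * f)
    else:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(73,)))
        for col in ("sense_count", "antisense_count"):
            t[col] = rng.binomial(np.round(t[col]).astype(np.int64), f).astype(float)
    scaled_total = counts.total_fragments * f
    assigned = float(t[["sense_count", "antisense_count"]].to_numpy().sum())
    unassigned = max(scaled_total - assigned, 0.0)
    out = CountTable(table=t, total_fragments=scaled_total, unassigned=unassigned)
    return ScaledCounts(counts=out, f=f, mode=mode)


@dataclass
class SaturationCurve:
    """Detection and coverage summaries at a ladder of depths."""

    depths: list[int]
    detection: pd.DataFrame  # depth, threshold, n_detected, fraction
    coverage: pd.DataFrame | None = None  # depth, pct_bkg, category, threshold, ...
    counts_by_depth: dict[int, CountTable] = field(default_factory=dict)


def saturation_analysis(
    fragments: pd.DataFrame,
    annotation: AnnotationSet,
    depths,
    thresholds=(1, 5, 10),
    pct_bkg=(),
    seed: int = 0,
    nested: bool = True,
    include_coverage: bool = False,
    keep_counts: bool = False,
) -> SaturationCurve:
    """Detection (and optionally genome-coverage) summaries vs depth.

    For each depth: subsample, assign fragments to features, summarise
    detection at the fragment thresholds; with ``include_coverage``, also
    compute the per-category coverage fractions, once per requested
    background-subtraction percentage (0 means no subtraction).
    """
    depths = sorted(int(d) for d in depths)
    n = len(fragments)
    if depths and depths[-1] > n:
        raise ValueError(f"requested depth {depths[-1]} exceeds {n} available fragments")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(79,)))
    perm = rng.permutation(n)

    categories: PositionCategories | None = None
    pct_list = list(pct_bkg) if pct_bkg else [0.0]
    if include_coverage:
        categories = categorize_positions(annotation)

    det_rows, cov_frames = [], []
    counts_by_depth: dict[int, CountTable] = {}
    for d in depths:
        if nested:
            sub = fragments.iloc[np.sort(perm[:d])]
        else:
            idx = rng.choice(n, size=d, replace=False)
            sub = fragments.iloc[np.sort(idx)]
        counts = assign_fragments(sub, annotation)
        if keep_counts:
            counts_by_depth[d] = counts
        det = detection_summary(counts, thresholds)
        det.insert(0, "depth", d)
        det_rows.append(det)
        if include_coverage:
            track = compute_coverage(sub, annotation.length)
            for pct in pct_list:
                if pct > 0:
                    model = subtract_background(track, pct, seed=seed)
                    summ = coverage_summary(model, categories, thresholds)
                else:
                    summ = coverage_summary(track, categories, thresholds)
                summ.insert(0, "pct_bkg", pct)
                summ.insert(0, "depth", d)
                cov_frames.append(summ)

    detection = pd.concat(det_rows, ignore_index=True) if det_rows else pd.DataFrame(
        columns=["depth", "threshold", "n_detected", "fraction"]
    )
    cov = pd.concat(cov_frames, ignore_index=True) if cov_frames else None
    return SaturationCurve(
        depths=depths, detection=detection, coverage=cov, counts_by_depth=counts_by_depth
    )


def replicate_detection(
    rpkm_rep1: pd.Series, rpkm_rep2: pd.Series, rpkm_thresholds
) -> pd.DataFrame:
    """Percent of all features with RPKM >= threshold in BOTH replicates."""
    if not rpkm_rep1.index.equals(rpkm_rep2.index):
        if set(rpkm_rep1.index) != set(rpkm_rep2.index):
            raise ValueError("replicates must share an identical feature set")
        rpkm_rep2 = rpkm_rep2.reindex(rpkm_rep1.index)
    n = len(rpkm_rep1)
    rows = []
    for t in rpkm_thresholds:
        both = int(((rpkm_rep1 >= t) & (rpkm_rep2 >= t)).sum())
        rows.append((float(t), both, 100.0 * both / n if n else np.nan))
    return pd.DataFrame(rows, columns=["rpkm_threshold", "n_detected_both", "percent"])
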