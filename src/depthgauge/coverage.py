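"""Strand-specific per-base fragment coverage and gDNA background subtraction.

Coverage C is incremented at every strand-specific position spanned by a
fragment. Assuming genomic-DNA contamination lands uniformly over both
strands of the genome, its expected per-position coverage is

    Cbkg = Csum * (pctBkg / 100) / (2 * genome_length)

where Csum is the total strand-specific coverage. Subtracting this constant
from C leaves a fractional remainder at lightly covered positions, which is
resolved by stochastic rounding: with d = C - Cbkg,

    Ceff = 0            if d <= 0
         = floor(d)     if d >= 1
         = Bernoulli(d) if 0 < d < 1

A ``literal_formula`` switch computes Cbkg = Csum * pctBkg / 1000 instead,
for auditing against the compact published form of the expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AnnotationSet

#: Position-category codes, per strand-specific position.
CAT_IGR, CAT_ORF, CAT_NCRNA, CAT_RRNA, CAT_AS = 0, 1, 2, 3, 4
CATEGORY_NAMES = {CAT_IGR: "IGR", CAT_ORF: "ORF", CAT_NCRNA: "ncRNA",
                  CAT_RRNA: "rRNA", CAT_AS: "AS"}
#: Row order used in summary tables.
CATEGORY_ORDER = ("ORF", "ncRNA", "rRNA", "AS", "IGR", "Total")

_CLASS_CODE = {"ORF": CAT_ORF, "ncRNA": CAT_NCRNA, "rRNA": CAT_RRNA}
# Painting order: lowest precedence first, so later classes overwrite.
_PAINT_ORDER = ("ORF", "ncRNA", "rRNA")


@dataclass
class CoverageTrack:
    """Per-position integer fragment coverage, one vector per strand."""

    plus: np.ndarray
    minus: np.ndarray

    @property
    def csum(self) -> int:
        """Total strand-specific coverage (= sum of fragment lengths)."""
        return int(self.plus.sum()) + int(self.minus.sum())

    @property
    def genome_length(self) -> int:
        return len(self.plus)

    def strand(self, s: str) -> np.ndarray:
        return self.plus if s == "+" else self.minus


def compute_coverage(fragments: pd.DataFrame, genome_length: int) -> CoverageTrack:
    """Accumulate per-base coverage from a fragment table.

    Each fragment adds 1 at every position of [start, end) on its strand.
    Fragments outside [0, genome_length) raise, naming the offender.
    """
    starts = fragments["start"].to_numpy()
    ends = fragments["end"].to_numpy()
    bad = (starts < 0) | (ends > genome_length)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        fid = fragments["fragment_id"].iloc[i]
        raise ValueError(
            f"fragment {fid!r} [{starts[i]}, {ends[i]}) outside genome "
            f"[0, {genome_length})"
        )
    track = CoverageTrack(
        plus=np.zeros(genome_length, dtype=np.int64),
        minus=np.zeros(genome_length, dtype=np.int64),
    )
    for sym, vec in (("+", track.plus), ("-", track.minus)):
        m = (fragments["strand"] == sym).to_numpy()
        if not m.any():
            continue
        diff = np.zeros(genome_length + 1, dtype=np.int64)
        np.add.at(diff, starts[m], 1)
        np.add.at(diff, ends[m], -1)
        vec += np.cumsum(diff[:-1])
    return track


@dataclass
class PositionCategories:
    """Per-(position, strand) category codes (see CAT_* constants)."""

    plus: np.ndarray
    minus: np.ndarray

    def strand(self, s: str) -> np.ndarray:
        return self.plus if s == "+" else self.minus

    def sizes(self) -> dict[str, int]:
        counts = np.bincount(self.plus, minlength=5) + np.bincount(self.minus, minlength=5)
        out = {CATEGORY_NAMES[c]: int(counts[c]) for c in CATEGORY_NAMES}
        out["Total"] = 2 * len(self.plus)
        return out


def categorize_positions(annotation: AnnotationSet, genome_length: int | None = None) -> PositionCategories:
    """Label every strand-specific position as ORF / ncRNA / rRNA / AS / IGR.

    Sense positions take their feature's class (precedence rRNA > ncRNA >
    ORF where sense features overlap). A position is antisense (AS) only if
    a gene sits on the opposite strand and no gene occupies it on its own
    strand; everything else is intergenic (IGR).
    """
    L = genome_length if genome_length is not None else annotation.length
    plus = np.zeros(L, dtype=np.int8)
    minus = np.zeros(L, dtype=np.int8)
    vec = {"+": plus, "-": minus}
    for cls in _PAINT_ORDER:
        for f in annotation.by_class(cls):
            vec[f.strand][f.start : f.end] = _CLASS_CODE[cls]
    # AS: opposite strand carries a gene, own strand does not.
    as_plus = (plus == CAT_IGR) & (minus != CAT_IGR)
    as_minus = (minus == CAT_IGR) & (plus != CAT_IGR)
    plus[as_plus] = CAT_AS
    minus[as_minus] = CAT_AS
    return PositionCategories(plus=plus, minus=minus)


@dataclass
class BackgroundModel:
    """Result of gDNA background subtraction on a coverage track."""

    pct_bkg: float
    cbkg: float
    ceff: CoverageTrack


def subtract_background(
    track: CoverageTrack,
    pct_bkg: float,
    seed: int = 0,
    literal_formula: bool = False,
) -> BackgroundModel:
    """Subtract the uniform gDNA coverage expectation with stochastic rounding.

    Bernoulli draws for the fractional branch consume one random stream in
    genome order (plus strand first), so results are bit-reproducible for a
    fixed seed.
    """
    if not 0.0 <= pct_bkg <= 100.0:
        raise ValueError(f"pct_bkg must be in [0, 100], got {pct_bkg}")
    csum = track.csum
    if literal_formula:
        cbkg = csum * pct_bkg / 1000.0
    else:
        cbkg = csum * (pct_bkg / 100.0) / (2.0 * track.genome_length)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(53,)))
    out = []
    for vec in (track.plus, track.minus):
        d = vec.astype(np.float64) - cbkg
        eff = np.where(d >= 1.0, np.floor(d), 0.0)
        frac = (d > 0.0) & (d < 1.0)
        if frac.any():
            eff[frac] = (rng.random(int(frac.sum())) < d[frac]).astype(np.float64)
        out.append(eff.astype(np.int64))
    return BackgroundModel(pct_bkg=pct_bkg, cbkg=cbkg, ceff=CoverageTrack(*out))


def coverage_summary(
    track: CoverageTrack | BackgroundModel,
    categories: PositionCategories,
    thresholds=(1, 5, 10),
) -> pd.DataFrame:
    """Fraction of strand-specific positions covered >= each threshold,
    per position category plus a Total row over all positions.

    Empty categories report NaN rather than 0.
    """
    if isinstance(track, BackgroundModel):
        track = track.ceff
    thresholds = [int(t) for t in thresholds]
    if any(t < 1 for t in thresholds):
        raise ValueError("thresholds must be >= 1")
    cov = np.concatenate([track.plus, track.minus])
    cat = np.concatenate([categories.plus, categories.minus])
    sizes = categories.sizes()
    rows = []
    for t in thresholds:
        hit = cov >= t
        hit_by_cat = np.bincount(cat[hit], minlength=5)
        for code, name in CATEGORY_NAMES.items():
            n = sizes[name]
            frac = hit_by_cat[code] / n if n else np.nan
            rows.append((name, t, int(hit_by_cat[code]), n, frac))
        rows.append(("Total", t, int(hit.sum()), sizes["Total"], hit.sum() / sizes["Total"]))
    df = pd.DataFrame(rows, columns=["category", "threshold", "covered", "size", "fraction"])
    df["category"] = pd.Categorical(df["category"], categories=CATEGORY_ORDER, ordered=True)
    return df.sort_values(["threshold", "category"]).reset_index(drop=True)
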