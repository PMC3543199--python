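"""Core domain types shared across the package.

All genomic coordinates are 0-based half-open on the internal surface;
conversions to 1-based inclusive (GFF3, SAM) happen only in the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Recognised feature classes, in ascending sense-precedence order
#: (rRNA wins over ncRNA wins over ORF where sense features overlap).
FEATURE_CLASSES = ("ORF", "ncRNA", "rRNA")

STRANDS = ("+", "-")

#: Canonical column order for fragment tables.
FRAGMENT_COLUMNS = ("contig", "start", "end", "strand", "fragment_id", "origin")


@dataclass(frozen=True)
class Feature:
    """A strand-aware annotated feature (gene) on the genome."""

    feature_id: str
    feature_class: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"feature {self.feature_id!r}: class {self.feature_class!r} "
                f"not one of {FEATURE_CLASSES}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"feature {self.feature_id!r}: strand must be + or -")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"feature {self.feature_id!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotationSet:
    """A genome (single linear contig) plus its strand-aware features.

    Serves both as the annotation container consumed by coverage/counting
    and, via the :class:`GenomeModel` alias, as the simulator's genome model.
    """

    contig: str
    length: int
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"genome length must be positive, got {self.length}")
        seen: set[str] = set()
        for f in self.features:
            if f.feature_id in seen:
                raise ValueError(f"duplicate feature id {f.feature_id!r}")
            seen.add(f.feature_id)
            if f.end > self.length:
                raise ValueError(
                    f"feature {f.feature_id!r} [{f.start}, {f.end}) exceeds "
                    f"genome length {self.length}"
                )

    def __len__(self) -> int:
        return len(self.features)

    def by_class(self, feature_class: str) -> list[Feature]:
        return [f for f in self.features if f.feature_class == feature_class]

    @property
    def rrna_ids(self) -> list[str]:
        return [f.feature_id for f in self.by_class("rRNA")]

    def to_frame(self) -> pd.DataFrame:
        """Features as a DataFrame indexed by feature_id."""
        df = pd.DataFrame(
            {
                "feature_id": [f.feature_id for f in self.features],
                "feature_class": [f.feature_class for f in self.features],
                "start": np.array([f.start for f in self.features], dtype=np.int64),
                "end": np.array([f.end for f in self.features], dtype=np.int64),
                "strand": [f.strand for f in self.features],
            }
        )
        df["length"] = df["end"] - df["start"]
        return df.set_index("feature_id")


class GenomeModel(AnnotationSet):
    """A simulated genome: an AnnotationSet produced by the generator."""


@dataclass
class ExpressionProfile:
    """Expected library composition for the fragment simulator.

    abundance
        Relative molar abundance per feature (index = feature ids). Only
        ratios matter; the simulator samples fragments with probability
        proportional to abundance x feature length.
    antisense_rate
        Fraction of non-rRNA transcript fragments emitted antisense to a
        feature (spurious transcription / residual second-strand signal).
    gdna_fraction
        Fraction of all fragments drawn uniformly from both strands of the
        genome (residual genomic-DNA contamination).
    rrna_fraction
        Fraction of transcript-derived fragments originating from rRNA
        features (0.0015 emulates a well-depleted library; 0.82 an
        undepleted one).
    """

    abundance: pd.Series
    antisense_rate: float = 0.02
    gdna_fraction: float = 0.01
    rrna_fraction: float = 0.0015

    def __post_init__(self) -> None:
        ab = pd.Series(self.abundance, dtype=float)
        if (ab < 0).any() or not np.isfinite(ab).all():
            raise ValueError("abundances must be finite and nonnegative")
        if ab.sum() <= 0:
            raise ValueError("abundances must have a positive total")
        object.__setattr__(self, "abundance", ab)
        for name in ("antisense_rate", "gdna_fraction", "rrna_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class Fragment:
    """One cDNA molecule's genomic interval (the atomic unit of counting).

    Fragment tables throughout the package are pandas DataFrames with the
    columns in :data:`FRAGMENT_COLUMNS`; this dataclass documents and
    validates the row schema.
    """

    contig: str
    start: int
    end: int
    strand: str
    fragment_id: str = ""
    origin: str = "pair"  # pair | orphan

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"fragment needs 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError("fragment strand must be + or -")
        if self.origin not in ("pair", "orphan"):
            raise ValueError("origin must be 'pair' or 'orphan'")


def fragments_frame(records) -> pd.DataFrame:
    """Build a canonical fragment table from Fragment objects or tuples."""
    rows = []
    for r in records:
        if isinstance(r, Fragment):
            rows.append((r.contig, r.start, r.end, r.strand, r.fragment_id, r.origin))
        else:
            rows.append(tuple(r))
    df = pd.DataFrame(rows, columns=list(FRAGMENT_COLUMNS))
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def empty_fragments() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": pd.Series(dtype=object),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=object),
            "fragment_id": pd.Series(dtype=object),
            "origin": pd.Series(dtype=object),
        }
    )
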