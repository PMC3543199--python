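"""Synthetic bacterial RNA-seq data with known ground truth.

Generates a toy genome (ORFs, ncRNAs, rRNA operons, intergenic gaps), a
log-normal expression profile, and aligned paired-end fragments labelled by
origin (sense transcript, antisense transcript, rRNA, genomic-DNA
contamination), so every downstream stage of the depth analysis can be
tested against a known truth without external sequencing data.

All randomness flows from a single integer seed through named per-operation
streams, so re-running any one operation with the same arguments is
bit-reproducible regardless of what else ran.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    ExpressionProfile,
    Feature,
    GenomeModel,
    empty_fragments,
)

# Named sub-stream ids: one per randomised operation.
_STREAM_GENOME = 11
_STREAM_EXPRESSION = 23
_STREAM_FRAGMENTS = 37

#: Fragment origin labels carried in the ground-truth table.
LABELS = ("sense-transcript", "antisense-transcript", "rRNA", "gDNA")

#: Outer-span ceiling for a properly paired fragment (library size selection).
MAX_FRAGMENT_LENGTH = 450

_ORF_LEN_RANGE = (300, 1500)
_NCRNA_LEN_RANGE = (80, 300)
_RRNA_OPERON_LEN = 4500  # ~16S + 23S + 5S
_MIN_GAP = 20


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def generate_genome(
    length: int,
    n_orfs: int = 50,
    n_ncrnas: int = 5,
    rrna_operons: int = 1,
    seed: int = 0,
    contig: str = "chr",
) -> GenomeModel:
    """Place non-overlapping ORF / ncRNA / rRNA features on a linear contig.

    Features are shuffled, assigned random strands, and laid out left to
    right separated by random intergenic gaps (minimum 20 bp). Raises
    ``ValueError`` when the requested features cannot fit.
    """
    if length <= 0:
        raise ValueError(f"genome length must be positive, got {length}")
    rng = _rng(seed, _STREAM_GENOME)

    specs: list[tuple[str, str, int]] = []
    for i in range(n_orfs):
        specs.append((f"orf_{i + 1:04d}", "ORF", int(rng.integers(*_ORF_LEN_RANGE))))
    for i in range(n_ncrnas):
        specs.append((f"ncrna_{i + 1:03d}", "ncRNA", int(rng.integers(*_NCRNA_LEN_RANGE))))
    for i in range(rrna_operons):
        specs.append((f"rrna_{i + 1:02d}", "rRNA", _RRNA_OPERON_LEN))

    order = rng.permutation(len(specs))
    specs = [specs[i] for i in order]

    total_feat = sum(s[2] for s in specs)
    n_gaps = len(specs) + 1
    slack = length - total_feat - n_gaps * _MIN_GAP
    if slack < 0:
        raise ValueError(
            f"cannot place {len(specs)} features totalling {total_feat} bp plus "
            f"{n_gaps} gaps of >= {_MIN_GAP} bp on a {length} bp genome"
        )

    # Split the slack over the gaps with a symmetric multinomial.
    extra = rng.multinomial(slack, np.full(n_gaps, 1.0 / n_gaps)) if slack > 0 else np.zeros(
        n_gaps, dtype=int
    )
    strands = rng.choice(["+", "-"], size=len(specs))

    features: list[Feature] = []
    pos = 0
    for i, (fid, fclass, flen) in enumerate(specs):
        pos += _MIN_GAP + int(extra[i])
        features.append(Feature(fid, fclass, pos, pos + flen, str(strands[i])))
        pos += flen

    features.sort(key=lambda f: f.start)
    return GenomeModel(contig=contig, length=length, features=features)


def sample_expression(
    genome: GenomeModel,
    lognormal_mu: float = 1.0,
    lognormal_sigma: float = 2.0,
    seed: int = 0,
    antisense_rate: float = 0.02,
    gdna_fraction: float = 0.01,
    rrna_fraction: float = 0.0015,
) -> ExpressionProfile:
    """Draw i.i.d. log-normal relative abundances for every feature.

    sigma around 2 gives the several-orders-of-magnitude dynamic range
    characteristic of bacterial transcriptomes; sigma = 0 collapses to a
    flat profile at exp(mu). Library composition fractions are stored on
    the profile (see :class:`ExpressionProfile`).
    """
    if lognormal_sigma < 0:
        raise ValueError(f"lognormal_sigma must be >= 0, got {lognormal_sigma}")
    rng = _rng(seed, _STREAM_EXPRESSION)
    ids = [f.feature_id for f in genome.features]
    ab = rng.lognormal(mean=lognormal_mu, sigma=lognormal_sigma, size=len(ids))
    return ExpressionProfile(
        abundance=pd.Series(ab, index=ids),
        antisense_rate=antisense_rate,
        gdna_fraction=gdna_fraction,
        rrna_fraction=rrna_fraction,
    )


@dataclass
class SimulatedFragments:
    """Simulator output: a fragment table plus per-fragment ground truth.

    fragments
        Canonical fragment table (contig, start, end, strand, fragment_id,
        origin); every simulated fragment has origin "pair".
    truth
        fragment_id, label (one of :data:`LABELS`), source_feature ("" for
        gDNA fragments).
    """

    fragments: pd.DataFrame
    truth: pd.DataFrame
    genome: GenomeModel
    read_len: int

    def write_fragment_tsv(self, path) -> None:
        from .io import write_fragment_tsv

        write_fragment_tsv(self.fragments, path)

    def write_truth_tsv(self, path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)

    def write_sam(self, path) -> None:
        from .io import write_fragments_sam

        write_fragments_sam(self.fragments, self.genome, self.read_len, path)


def simulate_fragments(
    genome: GenomeModel,
    profile: ExpressionProfile,
    n_fragments: int,
    fraglen_mean: float = 159.0,
    fraglen_sd: float = 40.0,
    read_len: int = 76,
    seed: int = 0,
    antisense_mode: str = "uniform",
) -> SimulatedFragments:
    """Simulate aligned paired-end fragments with known origins.

    Each fragment is, independently: gDNA with probability
    ``profile.gdna_fraction`` (uniform over both strands of the genome);
    otherwise transcript-derived — rRNA with probability
    ``profile.rrna_fraction``, else a non-rRNA feature chosen with
    probability proportional to abundance x length, antisense with
    probability ``profile.antisense_rate``. Fragment lengths are normal
    (mean/sd as given) clipped to [read_len, 450] and to the source
    feature; starts are uniform within the source.

    antisense_mode
        "uniform": antisense fragments land on features weighted by length
        only (spurious transcription, uncorrelated with expression).
        "mirrored": weighted like sense fragments (emulates residual
        second-strand signal, which tracks each gene's own expression).
    """
    if antisense_mode not in ("uniform", "mirrored"):
        raise ValueError("antisense_mode must be 'uniform' or 'mirrored'")
    if fraglen_mean + 3 * fraglen_sd > MAX_FRAGMENT_LENGTH:
        raise ValueError(
            f"fraglen_mean + 3*fraglen_sd must be <= {MAX_FRAGMENT_LENGTH} "
            f"so proper pairs satisfy the span rule"
        )
    if read_len > fraglen_mean:
        raise ValueError("read_len must be <= fraglen_mean")
    if n_fragments < 0:
        raise ValueError("n_fragments must be >= 0")

    rng = _rng(seed, _STREAM_FRAGMENTS)
    L = genome.length
    feats = genome.to_frame()

    if n_fragments == 0:
        truth = pd.DataFrame(
            {"fragment_id": pd.Series(dtype=object), "label": pd.Series(dtype=object),
             "source_feature": pd.Series(dtype=object)}
        )
        return SimulatedFragments(empty_fragments(), truth, genome, read_len)

    is_rrna = feats["feature_class"].to_numpy() == "rRNA"
    weights = profile.abundance.reindex(feats.index).to_numpy() * feats["length"].to_numpy()

    rrna_idx = np.flatnonzero(is_rrna)
    non_idx = np.flatnonzero(~is_rrna)
    if non_idx.size == 0 and profile.rrna_fraction < 1.0 and profile.gdna_fraction < 1.0:
        raise ValueError("no non-rRNA features to draw transcript fragments from")

    # Origin of each fragment.
    u = rng.random(n_fragments)
    is_gdna = u < profile.gdna_fraction
    n_tx = int((~is_gdna).sum())
    tx_u = rng.random(n_tx)
    eff_rrna = profile.rrna_fraction if rrna_idx.size else 0.0
    tx_is_rrna = tx_u < eff_rrna
    n_non = int((~tx_is_rrna).sum())
    as_u = rng.random(n_non)
    non_is_as = as_u < profile.antisense_rate

    # Source feature per transcript fragment.
    src = np.full(n_fragments, -1, dtype=np.int64)
    tx_pos = np.flatnonzero(~is_gdna)
    if tx_is_rrna.any():
        w = weights[rrna_idx]
        p = w / w.sum() if w.sum() > 0 else np.full(rrna_idx.size, 1.0 / rrna_idx.size)
        src[tx_pos[tx_is_rrna]] = rng.choice(rrna_idx, size=int(tx_is_rrna.sum()), p=p)
    non_pos = tx_pos[~tx_is_rrna]
    if n_non:
        w_sense = weights[non_idx]
        p_sense = w_sense / w_sense.sum()
        if antisense_mode == "uniform":
            w_as = feats["length"].to_numpy()[non_idx].astype(float)
            p_as = w_as / w_as.sum()
        else:
            p_as = p_sense
        sense_pos = non_pos[~non_is_as]
        as_pos = non_pos[non_is_as]
        if sense_pos.size:
            src[sense_pos] = rng.choice(non_idx, size=sense_pos.size, p=p_sense)
        if as_pos.size:
            src[as_pos] = rng.choice(non_idx, size=as_pos.size, p=p_as)

    # Fragment lengths: normal clipped to [read_len, 450].
    lens = rng.normal(fraglen_mean, fraglen_sd, size=n_fragments)
    lens = np.clip(np.rint(lens), read_len, MAX_FRAGMENT_LENGTH).astype(np.int64)
    lens = np.minimum(lens, L)

    starts = np.empty(n_fragments, dtype=np.int64)
    strands = np.empty(n_fragments, dtype=object)
    labels = np.empty(n_fragments, dtype=object)
    source = np.empty(n_fragments, dtype=object)

    f_start = feats["start"].to_numpy()
    f_end = feats["end"].to_numpy()
    f_strand = feats["strand"].to_numpy()
    f_ids = feats.index.to_numpy()

    # gDNA: uniform over the genome on a random strand.
    g = np.flatnonzero(is_gdna)
    if g.size:
        starts[g] = rng.integers(0, L - lens[g] + 1)
        strands[g] = rng.choice(["+", "-"], size=g.size)
        labels[g] = "gDNA"
        source[g] = ""

    # Transcript fragments: clip to the feature, uniform start within it.
    t = np.flatnonzero(src >= 0)
    if t.size:
        s_i = src[t]
        flen = f_end[s_i] - f_start[s_i]
        lens[t] = np.minimum(lens[t], flen)
        span = flen - lens[t] + 1
        starts[t] = f_start[s_i] + (rng.random(t.size) * span).astype(np.int64)
        source[t] = f_ids[s_i]

    as_mask = np.zeros(n_fragments, dtype=bool)
    if n_non:
        as_mask[non_pos[non_is_as]] = True
    rr_mask = np.zeros(n_fragments, dtype=bool)
    if tx_is_rrna.any():
        rr_mask[tx_pos[tx_is_rrna]] = True
    sense_mask = (src >= 0) & ~as_mask

    if sense_mask.any():
        strands[sense_mask] = f_strand[src[sense_mask]]
        labels[sense_mask] = "sense-transcript"
    if rr_mask.any():
        labels[rr_mask] = "rRNA"
    if as_mask.any():
        flip = {"+": "-", "-": "+"}
        strands[as_mask] = [flip[s] for s in f_strand[src[as_mask]]]
        labels[as_mask] = "antisense-transcript"

    ids = np.array([f"f{i + 1:08d}" for i in range(n_fragments)], dtype=object)
    frags = pd.DataFrame(
        {
            "contig": genome.contig,
            "start": starts,
            "end": starts + lens,
            "strand": strands,
            "fragment_id": ids,
            "origin": "pair",
        }
    )
    truth = pd.DataFrame({"fragment_id": ids, "label": labels, "source_feature": source})
    return SimulatedFragments(frags, truth, genome, read_len)
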