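import numpy as np
import pandas as pd
import pytest

import depthgauge as dg


@pytest.fixture(scope="session")
def genome():
    return dg.generate_genome(100_000, n_orfs=50, n_ncrnas=5, rrna_operons=1, seed=11)


@pytest.fixture(scope="session")
def profile(genome):
    return dg.sample_expression(genome, seed=11)


@pytest.fixture(scope="session")
def sim(genome, profile):
    return dg.simulate_fragments(genome, profile, 20_000, seed=11)


@pytest.fixture(scope="session")
def counts(sim, genome):
    return dg.assign_fragments(sim.fragments, genome)


def random_fragments(rng, genome_length, n, max_len=450, contig="chr"):
    """Uniform random fragment table for oracle tests (not via the simulator)."""
    lens = rng.integers(1, max_len + 1, size=n)
    lens = np.minimum(lens, genome_length)
    starts = rng.integers(0, genome_length - lens + 1)
    return pd.DataFrame(
        {
            "contig": contig,
            "start": starts.astype(np.int64),
            "end": (starts + lens).astype(np.int64),
            "strand": rng.choice(["+", "-"], size=n),
            "fragment_id": [f"r{i}" for i in range(n)],
            "origin": "pair",
        }
    )


def brute_force_coverage(frags, genome_length):
    """Quadratic per-position recount, independent of the diff-array path."""
    plus = np.zeros(genome_length, dtype=np.int64)
    minus = np.zeros(genome_length, dtype=np.int64)
    for row in frags.itertuples(index=False):
        vec = plus if row.strand == "+" else minus
        for p in range(row.start, row.end):
            vec[p] += 1
    return plus, minus


def brute_force_counts(frags, annotation):
    """Quadratic fragment-x-feature overlap scan with 1/k splitting."""
    feats = [(f.feature_id, f.start, f.end, f.strand) for f in annotation.features]
    sense = {f[0]: 0.0 for f in feats}
    anti = {f[0]: 0.0 for f in feats}
    unassigned = 0.0
    for row in frags.itertuples(index=False):
        hits = [f for f in feats if f[1] < row.end and f[2] > row.start]
        if not hits:
            unassigned += 1.0
            continue
        w = 1.0 / len(hits)
        for fid, _, _, fstrand in hits:
            if fstrand == row.strand:
                sense[fid] += w
            else:
                anti[fid] += w
    return sense, anti, unassigned
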