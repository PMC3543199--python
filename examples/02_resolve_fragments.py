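"""Resolve paired-end SAM alignments into strand-specific fragments.

Writes the simulated reads as a proper-pair SAM file, reads it back, and
checks that pair resolution (gap-filling, 450 bp span rule, dUTP strand
convention) reproduces every original fragment exactly.
"""

import tempfile, os

import depthgauge as dg

genome = dg.generate_genome(100_000, n_orfs=50, n_ncrnas=5, rrna_operons=1, seed=1)
profile = dg.sample_expression(genome, seed=1)
sim = dg.simulate_fragments(genome, profile, 20_000, seed=1)

with tempfile.TemporaryDirectory() as d:
    sam = os.path.join(d, "reads.sam")
    sim.write_sam(sam)
    res = dg.resolve_sam(sam, max_span=450, protocol="dUTP_R2_sense")

print(f"templates resolved: {res.n_templates} "
      f"(proper {res.n_proper}, improper {res.n_improper}, unpaired {res.n_unpaired})")
cols = ["fragment_id", "start", "end", "strand"]
got = res.fragments[cols].sort_values("fragment_id").reset_index(drop=True)
want = sim.fragments[cols].sort_values("fragment_id").reset_index(drop=True)
print(f"round-trip exact: {got.equals(want)}")
# Every proper pair becomes one fragment spanning both mates; exact
# recovery confirms the SAM writer and the resolver agree on coordinates
# and on which read carries the transcript strand.
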