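"""End-to-end workflow: simulate reads, train the filter, call variants.

Seeds signature-skewed SNVs into a 20 kb random reference, simulates
paired-end reads at x3 depth with the default error model, builds a balanced
labeled dataset, trains the classifier, and writes a VCF of calls.
"""

import tempfile
from pathlib import Path

import numpy as np

import detext as dx
from detext.signatures import cosmic_max_synthetic_table

workdir = Path(tempfile.mkdtemp(prefix="detext_example_"))
table = cosmic_max_synthetic_table()

ref = dx.random_reference(20_000, seed=7)
hap, truth = dx.seed_snvs(ref, 200, 7, table)
sam = workdir / "reads.sam"
dx.simulate_reads(ref, hap, dx.SimConfig(depth=3, vaf=1.0, seed=7), sam)
print(f"simulated reads -> {sam}")

truth_set = {(v.chrom, v.pos, v.ref, v.alt) for v in truth}
ds = dx.build_dataset(sam, ref, truth_set, table,
                      n_per_class=300, balance="over", seed=7)
print(f"dataset: {len(ds)} examples, "
      f"{int(ds.labels.sum())} true / {int((1 - ds.labels).sum())} false")

config = dx.ModelConfig(max_iters=300, patience=0, seed=5)
params, history = dx.train(ds, config)
print(f"trained for {history.converged_at} iterations; "
      f"holdout accuracy {history.val_acc[-1]:.3f}")

calls = dx.call_variants(sam, ref, params, config, table)
vcf = workdir / "calls.vcf"
dx.write_vcf(calls, vcf, ref)

called = {(c.chrom, c.pos, c.ref, c.alt) for c in calls}
tp = len(called & truth_set)
print(f"{len(calls)} calls written to {vcf}")
print(f"precision {tp / max(len(called), 1):.3f} — fraction of calls that "
      f"are seeded SNVs rather than sequencing errors")
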