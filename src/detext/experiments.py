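"""Self-contained study harnesses on fully synthetic data.

These reproduce, at desk scale, the structure of the headline experiments:
a skewed-spectrum cohort at x1 extracted depth for the signature-prior
ablation, the train-fraction AUC trend, and the simulator contract checks.
All randomness derives from a single integer seed.

Problem sizes (50 kb reference, 2,500 seeded SNVs, 2,000 examples per class,
250 training iterations) are the package's desk-scale defaults: large enough
for the comparative effects to be stable across seeds, small enough to run
on one CPU core in minutes.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from .evaluation import coefficient_sweep, stratified_split, train_fraction_sweep
from .model import ModelConfig
from .signatures import SignatureTable, cosmic_max_synthetic_table
from .simulate import (
    LabeledDataset,
    SimConfig,
    build_dataset,
    downsample_depth,
    random_reference,
    seed_snvs,
    simulate_reads,
)

__all__ = [
    "make_study_dataset",
    "ablation_study",
    "fraction_trend_study",
    "simulator_checks",
]

REFERENCE_LENGTH = 50_000
N_SNVS = 2_500
N_PER_CLASS = 2_000
RAW_DEPTH = 8
TRAIN_ITERS = 250


def make_study_dataset(
    seed: int,
    workdir: str | Path | None = None,
    table: SignatureTable | None = None,
) -> LabeledDataset:
    """Build the standard study cohort at x1 extracted depth.

    A 50 kb random reference receives 2,500 SNVs whose trinucleotide classes
    follow the skewed signature spectrum (the hot T[C>T]A class dominates);
    paired-end reads are simulated at x8 raw depth with the default error
    model, reduced to x1 by per-position pair extraction, and all candidates
    are labeled by exact truth matching and balanced to 2,000 per class
    (sequencing errors are the minority and are over-sampled).
    """
    table = table or cosmic_max_synthetic_table()
    seed = int(seed) % (2**31)
    with tempfile.TemporaryDirectory() as tmp:
        root = Path(workdir) if workdir is not None else Path(tmp)
        root.mkdir(parents=True, exist_ok=True)
        ref = random_reference(REFERENCE_LENGTH, seed=seed)
        hap, truth = seed_snvs(ref, N_SNVS, seed, table)
        raw_sam = root / "raw.sam"
        simulate_reads(
            ref, hap, SimConfig(depth=RAW_DEPTH, vaf=1.0, seed=seed), raw_sam
        )
        x1_sam = root / "x1.sam"
        downsample_depth(raw_sam, x1_sam, 1, seed=seed)
        truth_set = {(v.chrom, v.pos, v.ref, v.alt) for v in truth}
        return build_dataset(
            x1_sam, ref, truth_set, table,
            n_per_class=N_PER_CLASS, balance="over", seed=seed,
        )


def ablation_study(
    seed: int,
    n_seeds: int = 5,
    coefficients: tuple[float, float] = (0.0, 7.0),
    dataset: LabeledDataset | None = None,
) -> dict:
    """Signature-prior ablation: test accuracy with and without the prior.

    Trains fresh models over ``n_seeds`` training seeds on 70/30 stratified
    splits of the study cohort, once per coefficient, and reports mean test
    accuracy for each.  With the skewed true-SNV spectrum and uniform
    errors, the prior feature should raise mean accuracy over the
    coefficient-zero ablation.
    """
    ds = dataset if dataset is not None else make_study_dataset(seed)
    accs: dict[float, list[float]] = {c: [] for c in coefficients}
    for k in range(n_seeds):
        run_seed = (int(seed) + k) % (2**31)
        rng = np.random.default_rng(run_seed)
        tr, te = stratified_split(ds.labels, 0.7, rng)
        config = ModelConfig(max_iters=TRAIN_ITERS, patience=0, seed=run_seed)
        table = coefficient_sweep(
            ds.subset(tr), ds.subset(te), config, coefficients=coefficients
        )
        for coef, acc in zip(table.coefficient, table.acc):
            accs[float(coef)].append(float(acc))
    lo, hi = coefficients
    return {
        "mean_acc_without_prior": float(np.mean(accs[lo])),
        "mean_acc_with_prior": float(np.mean(accs[hi])),
        "per_seed": accs,
        "n_examples": len(ds),
        "n_seeds": n_seeds,
    }


def fraction_trend_study(
    seed: int,
    n_seeds: int = 3,
    fractions: tuple[float, float] = (0.1, 0.7),
    dataset: LabeledDataset | None = None,
) -> dict:
    """Mean test AUC at small vs large train fractions over several seeds."""
    ds = dataset if dataset is not None else make_study_dataset(seed)
    aucs: dict[float, list[float]] = {f: [] for f in fractions}
    for k in range(n_seeds):
        run_seed = (int(seed) + 1000 + k) % (2**31)
        config = ModelConfig(max_iters=TRAIN_ITERS, patience=0, seed=run_seed)
        table, _ = train_fraction_sweep(
            ds, config, fractions=fractions, seed=run_seed
        )
        for frac, auc in zip(table.fraction, table.auc):
            aucs[float(frac)].append(float(auc))
    return {
        "mean_auc": {f: float(np.mean(v)) for f, v in aucs.items()},
        "per_seed": aucs,
        "n_examples": len(ds),
        "n_seeds": n_seeds,
    }


def simulator_checks(seed: int) -> dict:
    """Empirical simulator contracts: base-error rate and depth capping."""
    seed = int(seed) % (2**31)
    ref = random_reference(10_000, seed=seed)
    out = {}
    with tempfile.TemporaryDirectory() as tmp:
        root = Path(tmp)
        sam = root / "err.sam"
        simulate_reads(
            ref, None, SimConfig(depth=12, error_rate=0.001, seed=seed), sam
        )
        import pysam

        n_bases = n_mismatch = 0
        with pysam.AlignmentFile(str(sam)) as f:
            for rec in f:
                seq = ref[rec.reference_name]
                start = rec.reference_start
                n_bases += len(rec.query_sequence)
                n_mismatch += sum(
                    b != seq[start + i] for i, b in enumerate(rec.query_sequence)
                )
        p = 0.001
        se = float(np.sqrt(p * (1 - p) / n_bases))
        out["error_rate"] = n_mismatch / n_bases
        out["error_rate_z"] = abs(out["error_rate"] - p) / se
        out["n_bases"] = n_bases

        # stack duplicate pairs, then cap at n=2 per start position
        dup = root / "dup.sam"
        hap, _ = seed_snvs(ref, 0, seed)
        simulate_reads(ref, hap, SimConfig(depth=1, seed=seed), root / "one.sam")
        lines = (root / "one.sam").read_text().splitlines(keepends=True)
        header = [l for l in lines if l.startswith("@")]
        body = [l for l in lines if not l.startswith("@")]
        dup_body = []
        for mult in range(5):
            for l in body:
                parts = l.split("\t")
                parts[0] = f"{parts[0]}.dup{mult}"
                dup_body.append("\t".join(parts))
        # duplicated pairs share positions; re-sort to keep coordinate order
        dup_body.sort(key=lambda l: (l.split("\t")[2], int(l.split("\t")[3])))
        dup.write_text("".join(header) + "".join(dup_body))
        capped = root / "x2.sam"
        downsample_depth(dup, capped, 2, seed=seed)
        counts: dict[tuple, set] = {}
        frag_start: dict[str, tuple] = {}
        with pysam.AlignmentFile(str(capped)) as f:
            for rec in f:
                key = (rec.reference_id, rec.reference_start)
                prev = frag_start.get(rec.query_name)
                if prev is None or key < prev:
                    frag_start[rec.query_name] = key
        for name, key in frag_start.items():
            counts.setdefault(key, set()).add(name)
        out["max_pairs_per_position"] = max(len(v) for v in counts.values())
    return out
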