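"""Synthetic low-depth sequencing data: references, reads, depth, labels.

The generator produces everything the experiments need without external
downloads: SNVs seeded into a reference (optionally with a signature-skewed
trinucleotide class distribution, the structure a signature prior can
exploit), paired-end 100 bp reads with substitution sequencing errors at rate
0.001 and split base-quality ranges (33-36 for normal bases, 7-19 for
erroneous ones), insert sizes uniform in (0, 600) clipped to the read length,
exact n-fold depth downsampling by per-position read-pair extraction, and
balanced labeled training sets built by exact truth matching.

What it deliberately does not model: amplification bias, UMIs, adapter
artifacts, GC bias, indels and alignment ambiguity — reads are emitted
pre-aligned at their true positions with all-match CIGARs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .encoding import BASE_CODES
from .pipeline import (
    VariantCall,
    candidate_prior,
    candidate_tokens,
    iter_candidates,
)
from .signatures import ALL_CLASSES, SignatureTable, canonical_class

__all__ = [
    "SimConfig",
    "LabeledDataset",
    "random_reference",
    "seed_snvs",
    "simulate_reads",
    "downsample_depth",
    "build_dataset",
]

log = logging.getLogger(__name__)

_BASES = np.array(["A", "C", "G", "T"])
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the read simulator.

    Defaults are the study conditions: 100 bp paired-end reads, substitution
    error rate 0.001 per base, insert sizes uniform on the inclusive range
    (0, 600) clipped to at least one read length, base qualities uniform on
    (33, 36) for correct bases and (7, 19) for sequencing errors.
    """

    read_length: int = 100
    error_rate: float = 0.001
    insert_size_range: tuple[int, int] = (0, 600)
    base_quality_normal: tuple[int, int] = (33, 36)
    base_quality_error: tuple[int, int] = (7, 19)
    depth: float = 1.0
    n_snvs: int = 0
    vaf: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError(f"error_rate must be in [0, 1), got {self.error_rate}")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        for name in ("insert_size_range", "base_quality_normal", "base_quality_error"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} is empty: ({lo}, {hi})")
        if not 0.0 < self.vaf <= 1.0:
            raise ValueError("vaf must be in (0, 1]")


def random_reference(
    length: int, seed: int = 0, name: str = "chrS", gc: float = 0.5
) -> dict[str, str]:
    """A single-contig random reference with controllable GC content."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {name: "".join(rng.choice(_BASES, size=length, p=p))}


# ---------------------------------------------------------------------------
# SNV seeding


def _class_positions(reference: Mapping[str, str]) -> dict[str, list[tuple[str, int, str]]]:
    """Map each canonical SBS96 key to reference (chrom, 0-based pos, alt) slots."""
    slots: dict[str, list[tuple[str, int, str]]] = {c.key: [] for c in ALL_CLASSES}
    for chrom, seq in reference.items():
        for i in range(1, len(seq) - 1):
            ref = seq[i]
            if ref not in BASE_CODES or seq[i - 1] not in BASE_CODES or seq[i + 1] not in BASE_CODES:
                continue
            for alt in "ACGT":
                if alt == ref:
                    continue
                cls = canonical_class(seq[i - 1], ref, alt, seq[i + 1])
                slots[cls.key].append((chrom, i, alt))
    return slots


def seed_snvs(
    reference: Mapping[str, str],
    n_snvs: int,
    rng: np.random.Generator | int = 0,
    signature_table: SignatureTable | None = None,
) -> tuple[dict[str, str], list[VariantCall]]:
    """Implant SNVs into a reference, returning (haplotype, truth records).

    With no signature table, positions and alternate alleles are uniform.
    With one, each variant's SBS96 class is drawn proportionally to the
    table's per-class maximum probability before a matching context is
    picked — a skewed trinucleotide spectrum like real somatic catalogs,
    and the structure the classifier's prior feature keys on.

    Positions are distinct; truth records are 1-based and sorted.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    usable = sum(max(0, len(s) - 2) for s in reference.values())
    if n_snvs > usable:
        raise ValueError(f"cannot place {n_snvs} SNVs in {usable} usable positions")

    chosen: dict[tuple[str, int], str] = {}
    if signature_table is None:
        flat = [
            (chrom, i)
            for chrom, seq in reference.items()
            for i in range(1, len(seq) - 1)
            if seq[i] in BASE_CODES
        ]
        picks = rng.choice(len(flat), size=n_snvs, replace=False)
        for k in picks:
            chrom, i = flat[k]
            ref = reference[chrom][i]
            alts = [b for b in "ACGT" if b != ref]
            chosen[(chrom, i)] = alts[rng.integers(len(alts))]
    else:
        slots = _class_positions(reference)
        keys = [c.key for c in ALL_CLASSES]
        weights = signature_table.probabilities.max(axis=1).to_numpy()
        weights = weights / weights.sum()
        guard = 0
        while len(chosen) < n_snvs:
            guard += 1
            if guard > 50 * n_snvs + 1000:
                raise ValueError(
                    "could not place the requested SNVs; reference too small "
                    "for the requested class spectrum"
                )
            key = keys[rng.choice(96, p=weights)]
            if not slots[key]:
                continue
            chrom, i, alt = slots[key][rng.integers(len(slots[key]))]
            if (chrom, i) not in chosen:
                chosen[(chrom, i)] = alt

    haplotype = {c: list(s) for c, s in reference.items()}
    truth = []
    for (chrom, i), alt in sorted(chosen.items()):
        truth.append(
            VariantCall(
                chrom=chrom, pos=i + 1, id=".", ref=reference[chrom][i],
                alt=alt, qual=99.0, filter="PASS", info={},
            )
        )
        haplotype[chrom][i] = alt
    return {c: "".join(s) for c, s in haplotype.items()}, truth


# ---------------------------------------------------------------------------
# Read simulation


def _sam_header(reference: Mapping[str, str]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": n, "LN": len(s)} for n, s in reference.items()],
        }
    )


def _sequence_read(
    source: str, start: int, sim: SimConfig, rng: np.random.Generator
) -> tuple[str, np.ndarray]:
    """Extract a read with substitution errors and matching base qualities."""
    L = sim.read_length
    bases = list(source[start : start + L])
    err = rng.random(L) < sim.error_rate
    qlo, qhi = sim.base_quality_normal
    quals = rng.integers(qlo, qhi + 1, size=L)
    elo, ehi = sim.base_quality_error
    for j in np.flatnonzero(err):
        orig = bases[j]
        alts = [b for b in "ACGT" if b != orig]
        bases[j] = alts[rng.integers(len(alts))]
        quals[j] = rng.integers(elo, ehi + 1)
    return "".join(bases), quals


def simulate_reads(
    reference: Mapping[str, str],
    haplotype: Mapping[str, str] | None,
    sim: SimConfig,
    out_sam: str | Path,
) -> int:
    """Simulate paired-end reads to the target depth; write a sorted SAM.

    Fragments are placed uniformly; each fragment is drawn from the variant
    haplotype with probability ``sim.vaf`` (else from the reference), so
    seeded SNVs appear at the configured allele fraction.  Reads are emitted
    pre-aligned with all-match CIGARs — the simulator knows the true
    placement, so no aligner is involved.  Returns the number of pairs.
    """
    if haplotype is None:
        haplotype = reference
    rng = np.random.default_rng(sim.seed)
    L = sim.read_length
    header = _sam_header(reference)
    records = []
    n_pairs_total = 0
    for tid, (chrom, ref_seq) in enumerate(reference.items()):
        glen = len(ref_seq)
        if glen < L:
            continue
        hap_seq = haplotype[chrom]
        n_pairs = int(np.ceil(sim.depth * glen / (2 * L)))
        n_pairs_total += n_pairs
        ins_lo, ins_hi = sim.insert_size_range
        for k in range(n_pairs):
            frag = int(rng.integers(ins_lo, ins_hi + 1))
            frag = max(L, min(frag, glen))
            start = int(rng.integers(0, glen - frag + 1))
            source = hap_seq if rng.random() < sim.vaf else ref_seq
            r1_seq, r1_q = _sequence_read(source, start, sim, rng)
            r2_start = start + frag - L
            r2_seq, r2_q = _sequence_read(source, r2_start, sim, rng)
            name = f"sim.{chrom}.{k}"
            for is_r2, (seq, quals, pos, mpos, tlen, flag) in enumerate(
                (
                    (r1_seq, r1_q, start, r2_start, frag, 0x1 | 0x2 | 0x20 | 0x40),
                    (r2_seq, r2_q, r2_start, start, -frag, 0x1 | 0x2 | 0x10 | 0x80),
                )
            ):
                a = pysam.AlignedSegment(header)
                a.query_name = name
                a.query_sequence = seq
                a.flag = flag
                a.reference_id = tid
                a.reference_start = pos
                a.mapping_quality = 60
                a.cigarstring = f"{L}M"
                a.next_reference_id = tid
                a.next_reference_start = mpos
                a.template_length = tlen
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in quals)
                )
                records.append(a)
    records.sort(key=lambda a: (a.reference_id, a.reference_start, a.query_name))
    with pysam.AlignmentFile(str(out_sam), "w", header=header) as out:
        for a in records:
            out.write(a)
    return n_pairs_total


# ---------------------------------------------------------------------------
# Depth downsampling


def downsample_depth(
    in_sam: str | Path,
    out_sam: str | Path,
    n: int,
    seed: int = 0,
) -> int:
    """Retain at most ``n`` read pairs per distinct fragment start position.

    This is the exact n-fold depth construction: one pair kept per position
    simulates x1 depth, two pairs x2, and so on.  Selection is a seeded
    random choice; mates are kept or dropped together.  The input must be
    coordinate-sorted.  Returns the number of pairs retained.
    """
    if n < 1:
        raise ValueError("target fold depth must be >= 1")
    rng = np.random.default_rng(seed)
    with pysam.AlignmentFile(str(in_sam), check_sq=False) as sam:
        header = sam.header
        if header.get("HD", {}).get("SO") != "coordinate":
            raise ValueError("downsampling requires a coordinate-sorted SAM")
        records = list(sam)

    last = (-1, -1)
    frag_start: dict[str, tuple[int, int]] = {}
    for rec in records:
        key = (rec.reference_id, rec.reference_start)
        if key < last:
            raise ValueError("SAM records are not coordinate-sorted")
        last = key
        prev = frag_start.get(rec.query_name)
        if prev is None or key < prev:
            frag_start[rec.query_name] = key

    by_pos: dict[tuple[int, int], list[str]] = {}
    for qname, key in frag_start.items():
        by_pos.setdefault(key, []).append(qname)

    keep: set[str] = set()
    for key in sorted(by_pos):
        names = sorted(by_pos[key])
        if len(names) <= n:
            keep.update(names)
        else:
            keep.update(rng.choice(names, size=n, replace=False))

    with pysam.AlignmentFile(str(out_sam), "w", header=header) as out:
        for rec in records:
            if rec.query_name in keep:
                out.write(rec)
    return len(keep)


# ---------------------------------------------------------------------------
# Labeled datasets


@dataclass
class LabeledDataset:
    """Encoded, labeled candidate reads ready for training.

    ``tokens`` is (N, L) int token indices, ``priors`` the raw per-candidate
    maximum signature probability (unscaled; the model applies the
    coefficient), ``labels`` 1 for true variants and 0 for false positives.
    ``provenance`` records where each example came from.
    """

    tokens: np.ndarray
    priors: np.ndarray
    labels: np.ndarray
    provenance: pd.DataFrame

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            self.tokens[idx],
            self.priors[idx],
            self.labels[idx],
            self.provenance.iloc[idx].reset_index(drop=True),
        )

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as f:
            np.savez(
                f,
                tokens=self.tokens,
                priors=self.priors,
                labels=self.labels,
                provenance=self.provenance.to_json().encode(),
            )

    @classmethod
    def load(cls, path: str | Path) -> "LabeledDataset":
        import io

        with np.load(path) as d:
            prov = pd.read_json(io.BytesIO(bytes(d["provenance"])))
            return cls(d["tokens"], d["priors"], d["labels"], prov)


def build_dataset(
    sam_path: str | Path,
    reference: Mapping[str, str],
    truth: set[tuple[str, int, str, str]] | Sequence[VariantCall],
    signature_table: SignatureTable,
    n_per_class: int | None = None,
    balance: str = "under",
    seed: int = 0,
    seq_len: int = 100,
) -> LabeledDataset:
    """Label, encode and class-balance all candidates of an alignment file.

    A candidate is a true variant iff its (chrom, pos, ref, alt) exactly
    matches a truth record (position-only matching would mislabel sequencing
    errors that land on a variant site with the wrong allele).  Balancing is
    plain seeded random sampling: ``under`` draws ``n_per_class`` without
    replacement from each class, ``over`` draws with replacement from the
    minority; ``n_per_class=None`` keeps everything.
    """
    if balance not in ("under", "over"):
        raise ValueError(f"balance must be 'under' or 'over', got {balance!r}")
    truth_set = (
        set(truth)
        if not (truth and isinstance(next(iter(truth)), VariantCall))
        else {(v.chrom, v.pos, v.ref, v.alt) for v in truth}
    )
    rng = np.random.default_rng(seed)

    rows, toks, priors, labels = [], [], [], []
    for cand in iter_candidates(sam_path, reference, seq_len):
        key = (cand.chrom, cand.pos, cand.ref_base, cand.alt_base)
        label = int(key in truth_set)
        toks.append(candidate_tokens(cand, seq_len))
        priors.append(candidate_prior(cand, signature_table))
        labels.append(label)
        rows.append(
            {
                "chrom": cand.chrom,
                "pos": cand.pos,
                "ref": cand.ref_base,
                "alt": cand.alt_base,
                "read_id": cand.read_id,
                "label": label,
            }
        )

    tokens = np.array(toks, dtype=np.int64).reshape(len(toks), seq_len)
    priors_a = np.asarray(priors, dtype=float)
    labels_a = np.asarray(labels, dtype=np.int64)
    prov = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "read_id", "label"]
    )
    ds = LabeledDataset(tokens, priors_a, labels_a, prov)

    for cls, name in ((1, "true variant"), (0, "false positive")):
        if not np.any(labels_a == cls):
            raise ValueError(f"no {name} candidates found; cannot build a dataset")
    if n_per_class is None:
        return ds

    picks = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels_a == cls)
        if balance == "under":
            if len(idx) < n_per_class:
                raise ValueError(
                    f"class {cls} has only {len(idx)} candidates; cannot "
                    f"under-sample {n_per_class} (use balance='over')"
                )
            picks.append(rng.choice(idx, size=n_per_class, replace=False))
        else:
            picks.append(rng.choice(idx, size=n_per_class, replace=True))
    order = np.concatenate(picks)
    rng.shuffle(order)
    return ds.subset(order)
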