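"""End-to-end variant calling: SAM in, filtered VCF out.

Each aligned read is scanned for single-base mismatches against the
reference; every mismatch becomes a per-read candidate carrying its aligned
read/reference window and trinucleotide context.  Candidates are difference-
encoded, scored by the classifier together with their signature prior, and
aggregated per site into VCF records.  The filter needs no duplicate
read-pair support — a single supporting read is enough, which is the whole
point at extra-low depth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO

from . import model as _model
from .encoding import BASE_CODES, encode_read, tokenize
from .signatures import (
    SignatureTable,
    canonical_class,
    max_probability,
)

__all__ = [
    "CandidateVariant",
    "VariantCall",
    "load_reference",
    "extract_candidates",
    "iter_candidates",
    "candidate_tokens",
    "candidate_prior",
    "call_variants",
    "write_vcf",
    "read_truth_vcf",
]

log = logging.getLogger(__name__)


@dataclass
class CandidateVariant:
    """A single mismatch on a single read, with its reference context."""

    chrom: str
    pos: int  # 1-based reference coordinate of the mismatch
    ref_base: str
    alt_base: str
    context: tuple[str, str]  # reference 5' and 3' flanking bases
    read_id: str
    read_window: tuple[str, str]  # aligned (read, reference) strings
    window_offset: int  # index of the mismatch within the window
    score: float | None = None


@dataclass
class VariantCall:
    chrom: str
    pos: int  # 1-based
    id: str
    ref: str
    alt: str
    qual: float
    filter: str
    info: dict = field(default_factory=dict)


def load_reference(path: str | Path) -> dict[str, str]:
    """Read a FASTA into an uppercase name -> sequence mapping.

    Suitable for the toy-to-megabase references this package targets; any
    mapping supporting ``ref[name][i:j]`` (e.g. ``pyfaidx.Fasta(as_raw=True)``)
    can be passed wherever a reference is expected.
    """
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def _is_usable(rec: pysam.AlignedSegment) -> bool:
    return not (
        rec.is_unmapped
        or rec.is_secondary
        or rec.is_supplementary
        or rec.query_sequence is None
    )


def extract_candidates(
    rec: pysam.AlignedSegment,
    reference: Mapping[str, str],
    seq_len: int = 100,
) -> list[CandidateVariant]:
    """Per-read mismatch candidates from one alignment record.

    Walks the aligned (CIGAR M/=/X) columns; insertions, deletions and clips
    contribute no candidates and are excluded from the aligned window.
    Mismatches touching a non-ACGT reference base or sitting flush against a
    contig edge (no trinucleotide context) are dropped with a log message.
    Unmapped, secondary and supplementary records yield an empty list.
    """
    if not _is_usable(rec):
        return []
    chrom = rec.reference_name
    if chrom not in reference:
        raise KeyError(f"reference sequence {chrom!r} not present in FASTA")
    ref_seq = reference[chrom]
    query = rec.query_sequence.upper()

    pairs = rec.get_aligned_pairs(matches_only=True)
    if not pairs:
        return []
    read_aln = "".join(query[q] for q, _ in pairs)
    ref_aln = "".join(ref_seq[r] for _, r in pairs)

    out = []
    for j, (q, r) in enumerate(pairs):
        rb, ab = ref_aln[j], read_aln[j]
        if rb == ab:
            continue
        if rb not in BASE_CODES or ab not in BASE_CODES:
            log.info(
                "dropping candidate at %s:%d on %s: non-ACGT base (%s>%s)",
                chrom, r + 1, rec.query_name, rb, ab,
            )
            continue
        if r == 0 or r + 1 >= len(ref_seq):
            log.info(
                "dropping candidate at %s:%d on %s: no flanking context",
                chrom, r + 1, rec.query_name,
            )
            continue
        five, three = ref_seq[r - 1], ref_seq[r + 1]
        if five not in BASE_CODES or three not in BASE_CODES:
            log.info(
                "dropping candidate at %s:%d on %s: non-ACGT context",
                chrom, r + 1, rec.query_name,
            )
            continue
        out.append(
            CandidateVariant(
                chrom=chrom,
                pos=r + 1,
                ref_base=rb,
                alt_base=ab,
                context=(five, three),
                read_id=rec.query_name,
                read_window=(read_aln, ref_aln),
                window_offset=j,
            )
        )
    return out


def iter_candidates(
    sam_path: str | Path,
    reference: Mapping[str, str],
    seq_len: int = 100,
    min_baseq: int = 0,
    min_mapq: int = 0,
) -> Iterable[CandidateVariant]:
    """Candidates from every usable record of a SAM/BAM file."""
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as sam:
        for rec in sam:
            if not _is_usable(rec) or (min_mapq and rec.mapping_quality < min_mapq):
                continue
            for cand in extract_candidates(rec, reference, seq_len):
                if min_baseq and rec.query_qualities is not None:
                    # candidate offset within aligned window == offset into
                    # matched pairs; map back to the query coordinate
                    q = rec.get_aligned_pairs(matches_only=True)[
                        cand.window_offset
                    ][0]
                    if rec.query_qualities[q] < min_baseq:
                        continue
                yield cand


def candidate_tokens(cand: CandidateVariant, seq_len: int = 100) -> tuple[int, ...]:
    """Difference-encode and tokenize a candidate's aligned window."""
    read_aln, ref_aln = cand.read_window
    diff = encode_read(read_aln, ref_aln, seq_len, cand.window_offset)
    return tokenize(diff)


def candidate_prior(
    cand: CandidateVariant,
    table: SignatureTable,
    subset: Sequence[str] | None = None,
) -> float:
    """Raw maximum signature probability of the candidate's SBS96 class."""
    cls = canonical_class(
        cand.context[0], cand.ref_base, cand.alt_base, cand.context[1]
    )
    return max_probability(cls, table, subset)


def _phred(p_error: float, cap: float = 99.0) -> float:
    if p_error <= 0:
        return cap
    return min(cap, -10.0 * math.log10(p_error))


def call_variants(
    sam_path: str | Path,
    reference: Mapping[str, str] | str | Path,
    params: "_model.ModelParams",
    config: "_model.ModelConfig",
    signature_table: SignatureTable,
    threshold: float | None = None,
    signature_subset: Sequence[str] | None = None,
    min_baseq: int = 0,
    min_mapq: int = 0,
) -> list[VariantCall]:
    """Score every candidate read and aggregate passing ones into calls.

    A candidate passes when its classifier probability of being a true
    variant reaches ``threshold`` (default ``config.threshold``).  Multiple
    reads supporting the same (chrom, pos, ref, alt) collapse into one
    record: DP counts the supporting reads, SC keeps the maximum classifier
    probability (which also sets QUAL, phred-scaled), MSP the class prior.
    Output is sorted by reference order, then position.
    """
    if isinstance(reference, (str, Path)):
        reference = load_reference(reference)
    if threshold is None:
        threshold = config.threshold

    cands = list(
        iter_candidates(sam_path, reference, config.seq_len, min_baseq, min_mapq)
    )
    if not cands:
        return []
    tokens = np.array(
        [candidate_tokens(c, config.seq_len) for c in cands], dtype=np.int64
    )
    priors = np.array(
        [candidate_prior(c, signature_table, signature_subset) for c in cands]
    )
    scores = _model.predict(params, (tokens, priors), config)
    for c, s in zip(cands, scores):
        c.score = float(s)

    chrom_order = {name: i for i, name in enumerate(reference)}
    sites: dict[tuple, dict] = {}
    for c, p in zip(cands, priors):
        key = (c.chrom, c.pos, c.ref_base, c.alt_base)
        site = sites.setdefault(
            key, {"depth": 0, "max_score": -1.0, "prior": float(p)}
        )
        site["depth"] += 1
        site["max_score"] = max(site["max_score"], c.score)

    calls = []
    for (chrom, pos, ref, alt), site in sites.items():
        if site["max_score"] < threshold:
            continue
        calls.append(
            VariantCall(
                chrom=chrom,
                pos=pos,
                id=".",
                ref=ref,
                alt=alt,
                qual=round(_phred(1.0 - site["max_score"]), 2),
                filter="PASS",
                info={
                    "DP": site["depth"],
                    "SC": round(site["max_score"], 6),
                    "MSP": round(site["prior"], 6),
                },
            )
        )
    calls.sort(key=lambda v: (chrom_order.get(v.chrom, 1 << 30), v.pos, v.alt))
    return calls


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=detext
##INFO=<ID=DP,Number=1,Type=Integer,Description="Supporting read count">
##INFO=<ID=SC,Number=1,Type=Float,Description="Maximum classifier probability of a true variant over supporting reads">
##INFO=<ID=MSP,Number=1,Type=Float,Description="Maximum mutational-signature probability of the substitution class">
"""


def write_vcf(
    calls: Sequence[VariantCall],
    path: str | Path,
    reference: Mapping[str, str] | None = None,
    extra_header: Sequence[str] = (),
) -> None:
    """Write calls as VCFv4.2 text (valid and header-only when empty).

    ``calls`` must already be sorted by (reference order, position); contig
    header lines are emitted when the reference mapping is supplied.
    """
    if reference is not None:
        order = {name: i for i, name in enumerate(reference)}
        keys = [(order.get(c.chrom, 1 << 30), c.pos) for c in calls]
    else:
        keys = [(c.chrom, c.pos) for c in calls]
    if any(a > b for a, b in zip(keys, keys[1:])):
        raise ValueError("calls must be sorted by (chrom, pos) before writing")

    with open(path, "w") as f:
        f.write(_VCF_HEADER)
        if reference is not None:
            for name, seq in reference.items():
                f.write(f"##contig=<ID={name},length={len(seq)}>\n")
        for line in extra_header:
            f.write(line.rstrip("\n") + "\n")
        f.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            info = ";".join(f"{k}={v}" for k, v in c.info.items()) or "."
            f.write(
                f"{c.chrom}\t{c.pos}\t{c.id}\t{c.ref}\t{c.alt}\t"
                f"{c.qual:g}\t{c.filter}\t{info}\n"
            )


def read_truth_vcf(path: str | Path) -> set[tuple[str, int, str, str]]:
    """Load truth SNVs as a set of (chrom, 1-based pos, ref, alt) tuples.

    Non-SNV records (indels, MNPs, symbolic alleles) are skipped; each ALT
    allele of a multi-allelic SNV record contributes its own tuple.
    """
    truth = set()
    try:
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                if rec.ref is None or len(rec.ref) != 1 or rec.ref not in BASE_CODES:
                    continue
                for alt in rec.alts or ():
                    if len(alt) == 1 and alt in BASE_CODES:
                        truth.add((rec.chrom, rec.pos, rec.ref, alt))
    except (ValueError, OSError) as exc:
        raise ValueError(f"malformed truth VCF {path}: {exc}") from exc
    return truth
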