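"""Difference encoding of candidate-supporting reads.

A read and its position-aligned reference window are reduced to a single
integer sequence: positions where read and reference agree carry the read
base's own code (A=1, T=2, C=4, G=8), and positions where they disagree carry
the numeric difference ``code(ref) - code(read)``, which is nonzero and keeps
the identity of both the original and the substituted base (e.g. an A->T
substitution is coded as 1 - 2 = -1, so a T(A->T)T context becomes
``(2, -1, 2)``).  The sequence is then mapped to token indices for an
embedding layer; match codes and difference values occupy disjoint token ids
even where their integer values collide (a T->A difference is +1, the same
integer as a matched A).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "BASE_CODES",
    "PAD_CODE",
    "UNKNOWN_CODE",
    "VOCAB_SIZE",
    "PAD_TOKEN",
    "UNKNOWN_TOKEN",
    "DIFF_VALUES",
    "DiffCodeSequence",
    "encode_base",
    "diff_code",
    "encode_read",
    "tokenize",
    "decode_read",
]

#: Fixed base -> integer code map.  Powers of two so that every ordered pair
#: of distinct bases yields a distinct difference.
BASE_CODES = {"A": 1, "T": 2, "C": 4, "G": 8}

#: Reserved code for padding positions (beyond the read).
PAD_CODE = 0

#: Sentinel code for positions involving a non-ACGT base (e.g. N); kept out
#: of the arithmetic code space entirely.
UNKNOWN_CODE = 99

#: All difference values reachable from the 12 ordered mismatch pairs.
DIFF_VALUES = tuple(
    sorted(
        {
            BASE_CODES[r] - BASE_CODES[a]
            for r in BASE_CODES
            for a in BASE_CODES
            if r != a
        }
    )
)

PAD_TOKEN = 0
UNKNOWN_TOKEN = 1
_MATCH_TOKENS = {code: 2 + i for i, code in enumerate(sorted(BASE_CODES.values()))}
_DIFF_TOKENS = {d: 6 + i for i, d in enumerate(DIFF_VALUES)}

#: Embedding vocabulary size: pad + unknown + 4 match codes + 12 differences
#: = 18 used slots; sized 20 to leave reserved headroom.
VOCAB_SIZE = 20


class EncodingError(ValueError):
    """Raised for bases or read/reference windows the encoder cannot accept."""


def encode_base(base: str) -> int:
    """Return the integer code of a nucleotide (A=1, T=2, C=4, G=8).

    Case-insensitive.  Raises :class:`EncodingError` for anything outside the
    four-letter alphabet; the caller decides whether to mask instead.
    """
    try:
        return BASE_CODES[base.upper()]
    except (KeyError, AttributeError):
        raise EncodingError(f"not an A/T/C/G base: {base!r}") from None


def diff_code(ref_base: str, read_base: str) -> int:
    """Difference code of a mismatch: ``code(ref) - code(read)``.

    Defined only for genuine mismatches; equal bases raise, since matched
    positions keep their base code rather than a zero difference.
    """
    r, a = encode_base(ref_base), encode_base(read_base)
    if r == a:
        raise EncodingError(
            f"{ref_base!r} -> {read_base!r} is not a mismatch; matched "
            "positions are base-coded, not difference-coded"
        )
    return r - a


@dataclass(frozen=True)
class DiffCodeSequence:
    """Fixed-length integer code sequence for one candidate-supporting read.

    Attributes
    ----------
    codes:
        Length-``L`` tuple: base codes at matches, ``code(ref) - code(read)``
        at mismatches, :data:`PAD_CODE` beyond the read and
        :data:`UNKNOWN_CODE` where either base is not A/C/G/T.
    candidate_offset:
        0-based index of the candidate mismatch within ``codes``.
    pad_mask:
        True where the position is padding.
    mismatch_mask:
        True where the position is a read/reference mismatch (needed to
        disambiguate raw values shared by match and difference codes).
    """

    codes: tuple[int, ...]
    candidate_offset: int
    pad_mask: tuple[bool, ...]
    mismatch_mask: tuple[bool, ...]

    def __len__(self) -> int:
        return len(self.codes)


def _position_code(ref_base: str, read_base: str) -> tuple[int, bool]:
    """(code, is_mismatch) for one aligned column.

    The flag is needed downstream because the raw values +1/+2/+4 occur both
    as match codes and as differences (e.g. matched A and a T->A substitution
    are both 1); tokenization keys on the pair, keeping the printed
    arithmetic intact while the token space stays collision-free.
    """
    r, a = ref_base.upper(), read_base.upper()
    if r not in BASE_CODES or a not in BASE_CODES:
        return UNKNOWN_CODE, False
    if r == a:
        return BASE_CODES[a], False
    return BASE_CODES[r] - BASE_CODES[a], True


def encode_read(
    read_seq: str,
    ref_window: str,
    length: int = 100,
    candidate_offset: int | None = None,
) -> DiffCodeSequence:
    """Encode a position-aligned (read, reference) pair to a code sequence.

    ``read_seq`` and ``ref_window`` must be equal-length, already aligned
    strings (indel columns removed upstream).  Reads shorter than ``length``
    are right-padded with :data:`PAD_CODE`; longer reads are center-cropped
    around ``candidate_offset``.  When ``candidate_offset`` is omitted it
    defaults to the first mismatch, or the window midpoint if none exists.
    """
    if len(read_seq) != len(ref_window):
        raise EncodingError(
            f"read ({len(read_seq)} bp) and reference window "
            f"({len(ref_window)} bp) are not position-aligned"
        )
    if not read_seq:
        raise EncodingError("empty read")
    if length < 1:
        raise EncodingError(f"sequence length must be >= 1, got {length}")

    if candidate_offset is None:
        mismatches = [
            i
            for i, (a, r) in enumerate(zip(read_seq, ref_window))
            if a.upper() != r.upper()
        ]
        candidate_offset = mismatches[0] if mismatches else len(read_seq) // 2
    if not 0 <= candidate_offset < len(read_seq):
        raise EncodingError(
            f"candidate offset {candidate_offset} outside read of length {len(read_seq)}"
        )

    if len(read_seq) > length:
        start = min(max(candidate_offset - length // 2, 0), len(read_seq) - length)
        read_seq = read_seq[start : start + length]
        ref_window = ref_window[start : start + length]
        candidate_offset -= start

    coded = [_position_code(r, a) for r, a in zip(ref_window, read_seq)]
    codes = [c for c, _ in coded]
    mismatch = [m for _, m in coded]
    n_pad = length - len(codes)
    codes.extend([PAD_CODE] * n_pad)
    mismatch.extend([False] * n_pad)
    pad_mask = (False,) * (length - n_pad) + (True,) * n_pad
    return DiffCodeSequence(tuple(codes), candidate_offset, pad_mask, tuple(mismatch))


def tokenize(diff: DiffCodeSequence) -> tuple[int, ...]:
    """Map a code sequence to embedding token indices in ``[0, VOCAB_SIZE)``.

    Pad -> 0, unknown -> 1, the four match codes and the twelve difference
    values each get their own id; match and difference tokens are disjoint by
    construction even where the raw integers collide.  Any value outside the
    defined code space falls back to the unknown token.
    """
    out = []
    for code, is_pad, is_mm in zip(diff.codes, diff.pad_mask, diff.mismatch_mask):
        if is_pad:
            out.append(PAD_TOKEN)
        elif is_mm and code in _DIFF_TOKENS:
            out.append(_DIFF_TOKENS[code])
        elif not is_mm and code in _MATCH_TOKENS:
            out.append(_MATCH_TOKENS[code])
        else:
            out.append(UNKNOWN_TOKEN)
    return tuple(out)


_CODE_TO_BASE = {v: k for k, v in BASE_CODES.items()}


def decode_read(ref_window: str, diff: DiffCodeSequence) -> str:
    """Recover the read sequence from the reference window and the codes.

    Inverse of :func:`encode_read` at every non-pad, non-unknown position:
    match codes name the base directly and difference codes give
    ``read = code(ref) - diff``.  Unknown positions come back as ``N``.
    """
    bases = []
    for ref_base, code, is_pad, is_mm in zip(
        ref_window, diff.codes, diff.pad_mask, diff.mismatch_mask
    ):
        if is_pad:
            break
        if code == UNKNOWN_CODE:
            bases.append("N")
        elif is_mm:
            bases.append(_CODE_TO_BASE[BASE_CODES[ref_base.upper()] - code])
        else:
            bases.append(_CODE_TO_BASE[code])
    return "".join(bases)
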