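"""SBS96 substitution classes and mutational-signature priors.

A single-base substitution is classified by its pyrimidine-referenced base
change (C>A, C>G, C>T, T>A, T>C, T>G) together with the reference bases
immediately 5' and 3' of the mutated base, giving 4 x 6 x 4 = 96 classes.
Substitutions whose reference base is a purine are reported on the opposite
strand: the context is reverse-complemented so that the reference base is
always C or T.

A signature table assigns each class a probability under each mutational
process (COSMIC-style SBS signatures, columns summing to one over the 96
classes).  The maximum occurrence probability of a candidate's class, scaled
by a coefficient, is the prior feature the classifier appends to its pooled
convolutional features.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubstitutionClass",
    "SignatureTable",
    "ALL_CLASSES",
    "canonical_class",
    "load_signature_table",
    "max_probability",
    "prior_feature",
    "synthetic_signature_table",
    "cosmic_max_synthetic_table",
    "packaged_table_path",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PYRIMIDINES = ("C", "T")
_BASES = ("A", "C", "G", "T")


class SignatureError(ValueError):
    """Raised for invalid substitution contexts or malformed tables."""


@dataclass(frozen=True, order=True)
class SubstitutionClass:
    """One of the 96 pyrimidine-referenced trinucleotide substitution classes."""

    five_prime: str
    ref: str
    alt: str
    three_prime: str

    def __post_init__(self):
        if self.ref not in PYRIMIDINES:
            raise SignatureError(
                f"canonical class must have a pyrimidine reference base, got {self.ref!r}"
            )
        for b in (self.five_prime, self.alt, self.three_prime):
            if b not in _BASES:
                raise SignatureError(f"not an A/C/G/T base: {b!r}")
        if self.alt == self.ref:
            raise SignatureError("reference and alternate base are equal")

    @property
    def key(self) -> str:
        """Canonical bracket notation, e.g. ``A[C>G]G``."""
        return f"{self.five_prime}[{self.ref}>{self.alt}]{self.three_prime}"

    def __str__(self) -> str:
        return self.key


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def canonical_class(
    five_prime: str, ref: str, alt: str, three_prime: str
) -> SubstitutionClass:
    """Canonicalize a substitution-in-context to its SBS96 class.

    If the reference base is a purine (A/G) the whole context is
    reverse-complemented — flanks swapped and complemented, ref and alt
    complemented — so the class is strand-symmetric.  Idempotent on already
    canonical input.
    """
    bases = [b.upper() for b in (five_prime, ref, alt, three_prime)]
    for b in bases:
        if b not in _BASES:
            raise SignatureError(f"not an A/C/G/T base: {b!r}")
    five, r, a, three = bases
    if r == a:
        raise SignatureError("reference and alternate base are equal")
    if r not in PYRIMIDINES:
        five, three = _COMPLEMENT[three], _COMPLEMENT[five]
        r, a = _COMPLEMENT[r], _COMPLEMENT[a]
    return SubstitutionClass(five, r, a, three)


#: All 96 classes in lexicographic order of (ref, alt, 5', 3').
ALL_CLASSES: tuple[SubstitutionClass, ...] = tuple(
    SubstitutionClass(f, r, a, t)
    for r in PYRIMIDINES
    for a in _BASES
    if a != r
    for f in _BASES
    for t in _BASES
)

_CLASS_INDEX = {c.key: i for i, c in enumerate(ALL_CLASSES)}


def _parse_class_key(text: str) -> str:
    """Accept ``A[C>G]G`` or ``A(C>G)G`` (spaces tolerated); return bracket form."""
    s = text.strip().replace(" ", "").replace("(", "[").replace(")", "]")
    if len(s) != 7 or s[1] != "[" or s[3] != ">" or s[5] != "]":
        raise SignatureError(f"unparseable substitution class: {text!r}")
    cls = canonical_class(s[0], s[2], s[4], s[6])
    if cls.key != f"{s[0]}[{s[2]}>{s[4]}]{s[6]}":
        raise SignatureError(
            f"class {text!r} is not pyrimidine-referenced; tables must use canonical keys"
        )
    return cls.key


@dataclass(frozen=True)
class SignatureTable:
    """96-class x S-signature probability matrix.

    ``probabilities`` is a DataFrame indexed by canonical class key (all 96
    present exactly once, canonical order) with one column per signature;
    every column sums to one.
    """

    probabilities: pd.DataFrame

    @property
    def signatures(self) -> list[str]:
        return list(self.probabilities.columns)

    @property
    def classes(self) -> list[str]:
        return list(self.probabilities.index)

    def __post_init__(self):
        df = self.probabilities
        if list(df.index) != [c.key for c in ALL_CLASSES]:
            raise SignatureError("table rows not in validated canonical order")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignatureTable":
        """Validate and canonically order a class-indexed probability frame."""
        keys = [_parse_class_key(k) for k in df.index]
        if len(set(keys)) != len(keys):
            dup = pd.Series(keys).value_counts()
            raise SignatureError(
                f"duplicate substitution class rows: {list(dup[dup > 1].index)}"
            )
        missing = set(_CLASS_INDEX) - set(keys)
        if missing:
            raise SignatureError(
                f"table is missing {len(missing)} of the 96 classes, "
                f"e.g. {sorted(missing)[:3]}"
            )
        df = df.copy()
        df.index = keys
        df = df.loc[[c.key for c in ALL_CLASSES]]
        values = df.to_numpy(dtype=float)
        if np.any(values < 0) or np.any(values > 1):
            raise SignatureError("probabilities must lie in [0, 1]")
        sums = values.sum(axis=0)
        bad = [
            (col, s) for col, s in zip(df.columns, sums) if abs(s - 1.0) > 1e-6
        ]
        if bad:
            raise SignatureError(
                "signature columns must sum to 1 over the 96 classes; got "
                + ", ".join(f"{c}={s:.6f}" for c, s in bad)
            )
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.probabilities.rename_axis("Type").to_csv(path, sep="\t")


def load_signature_table(path: str | Path) -> SignatureTable:
    """Read a signature probability TSV.

    Expected layout: a header row naming the signatures, first column the
    substitution class in ``A[C>G]G`` (or ``A(C>G)G``) notation, remaining
    columns the per-signature probabilities.  Rows may be in any order; all
    96 classes must appear exactly once and each column must sum to one.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise SignatureError(f"{path}: no signature columns found")
    return SignatureTable.from_frame(df)


def max_probability(
    cls: SubstitutionClass,
    table: SignatureTable,
    subset: Sequence[str] | None = None,
) -> float:
    """Maximum occurrence probability of a class across signature columns.

    ``subset`` restricts the maximum to the named signatures (e.g. the four
    processes active in a particular cancer type); by default all columns of
    the table participate.
    """
    cols = table.signatures if subset is None else list(subset)
    if not cols:
        raise SignatureError("empty signature subset")
    unknown = set(cols) - set(table.signatures)
    if unknown:
        raise SignatureError(f"unknown signatures: {sorted(unknown)}")
    return float(table.probabilities.loc[cls.key, cols].max())


def prior_feature(max_prob: float, coefficient: float = 7.0) -> float:
    """Scale a class probability into the network's feature range.

    The raw probabilities (~0.005-0.42) are small next to pooled
    convolutional activations; multiplying by a coefficient (default 7) puts
    the prior on a comparable scale.  Coefficient 0 disables the prior
    entirely, giving the no-signature ablation.
    """
    if not 0.0 <= max_prob <= 1.0:
        raise SignatureError(f"probability {max_prob} outside [0, 1]")
    if coefficient < 0:
        raise SignatureError(f"coefficient must be nonnegative, got {coefficient}")
    return max_prob * coefficient


# ---------------------------------------------------------------------------
# Packaged synthetic tables


def synthetic_signature_table() -> SignatureTable:
    """A deterministic two-signature synthetic table for tests and demos.

    Signature ``SYN1`` concentrates 80% of its mass uniformly on the sixteen
    C>T classes (a clock-like, deamination-flavoured shape); ``SYN2``
    concentrates 80% on the sixteen T>G classes.  The remaining mass is
    spread uniformly.  Entirely synthetic; not fitted to any catalogue.
    """
    keys = [c.key for c in ALL_CLASSES]
    cols = {}
    for name, major in (("SYN1", ("C", "T")), ("SYN2", ("T", "G"))):
        vals = np.empty(96)
        in_major = np.array([(c.ref, c.alt) == major for c in ALL_CLASSES])
        vals[in_major] = 0.8 / in_major.sum()
        vals[~in_major] = 0.2 / (~in_major).sum()
        cols[name] = vals
    return SignatureTable.from_frame(pd.DataFrame(cols, index=keys))


def cosmic_max_synthetic_table() -> SignatureTable:
    """Synthetic single-column stand-in for the COSMIC per-class maximum.

    Embeds the two published extreme per-class maxima — A[C>G]G at 0.005275
    (lowest of the 96) and T[C>T]A at 0.41994 (highest, a 79.6-fold spread) —
    and fills the other 94 classes with a uniform share of the remaining
    mass so the column sums to one.  A stand-in for lookup-path tests and
    simulations; real COSMIC SBS tables drop in via the same TSV format.
    """
    lo_key, lo = "A[C>G]G", 0.005275
    hi_key, hi = "T[C>T]A", 0.41994
    keys = [c.key for c in ALL_CLASSES]
    fill = (1.0 - lo - hi) / 94
    vals = np.full(96, fill)
    vals[_CLASS_INDEX[lo_key]] = lo
    vals[_CLASS_INDEX[hi_key]] = hi
    return SignatureTable.from_frame(
        pd.DataFrame({"COSMIC_MAX": vals}, index=keys)
    )


def packaged_table_path(name: str) -> Path:
    """Path to a packaged signature TSV (``synthetic`` or ``cosmic_max``)."""
    fname = {
        "synthetic": "signatures_synthetic.tsv",
        "cosmic_max": "cosmic_max_synthetic.tsv",
    }[name]
    return Path(resources.files("detext").joinpath("data", fname))
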