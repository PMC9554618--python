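"""Difference-encode a candidate read and look up its signature prior.

Builds a tiny read/reference pair with one substitution, shows the integer
difference code and token sequence, and computes the scaled SBS96 prior the
classifier appends before its softmax.
"""

from detext.encoding import diff_code, encode_read, tokenize
from detext.signatures import (
    canonical_class,
    cosmic_max_synthetic_table,
    max_probability,
    prior_feature,
)

# An A->T substitution in a T_T context: reference TAT, read TTT.
diff = encode_read("TTT", "TAT", length=3)
print("difference codes:", diff.codes)          # (2, -1, 2)
print("A->T code:", diff_code("A", "T"))        # 1 - 2 = -1
print("token indices:", tokenize(diff))

# The same substitution as an SBS96 class. T(A>T)T has a purine reference,
# so it is reported on the opposite strand as A[T>A]A.
cls = canonical_class("T", "A", "T", "T")
print("canonical class:", cls.key)

table = cosmic_max_synthetic_table()
p = max_probability(cls, table)
print(f"max signature probability: {p:.6f}")
print(f"prior feature at coefficient 7: {prior_feature(p, 7):.6f}")
# The codes keep both the original and substituted base recoverable; the
# prior tells the classifier how often this substitution class occurs in
# somatic catalogs.
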