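"""Encode the classic worked-example windows and verify the kernel forms.

The positive 5p window (letters UGGgug, two 1-nt loops) becomes
L1 G G G L1 G; with k=3 ones per loop token the per-arm vector is
6(M+6)-dimensional.  The loop-token inner product and squared distance
follow the closed forms max{k-|l1-l2|,0} and 2*min{|l1-l2|,k}.
"""

import numpy as np

from lbsizecleav import (
    EncodingScheme,
    encode_token,
    encode_tokens,
    fixture_worked_example,
    loop_dot,
    loop_sqdist,
)
from lbsizecleav.dataset import Token

win5p, win3p = fixture_worked_example()
M = 5  # dataset-wide maximum loop length (here: chosen for display)
scheme = EncodingScheme("lbsize", w=6, k=3, M=M)

print("positive 5p tokens:", " ".join(t.render() for t in win5p.arm_tokens))
print("negative 3p tokens:", " ".join(t.render() for t in win3p.arm_tokens))
vec = encode_tokens(win5p.arm_tokens, scheme)
print(f"per-arm vector length: {len(vec)} = 6*(M+6) with M={M}")
print("L1 token pattern:", encode_token(Token("U", 1), scheme).astype(int).tolist())
print("   (k=3 ones in 1-based slots (4+l)..(k+3+l) = 5..7 for l=1)")

print("\nkernel closed forms (k=3):")
for l1, l2 in [(1, 1), (1, 2), (1, 3), (1, 4), (2, 9)]:
    x1 = encode_token(Token("A", l1), EncodingScheme("lbsize", w=6, k=3, M=10))
    x2 = encode_token(Token("A", l2), EncodingScheme("lbsize", w=6, k=3, M=10))
    print(
        f"  l1={l1} l2={l2}: dot={int(x1 @ x2)} (closed form {loop_dot(l1, l2, 3)}), "
        f"||x1-x2||^2={int(((x1 - x2) ** 2).sum())} "
        f"(closed form {loop_sqdist(l1, l2, 3)})"
    )
# Similarity decays linearly with the loop-length difference and is zero
# once |l1-l2| >= k: that is the whole point of the k-ones pattern.
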