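"""Binary feature-space mappings for labeled windows.

Four per-token schemes are supported (per-token dimension d in brackets):

* ``seq-binary`` [4] -- plain nucleotide one-hot; structure ignored.  The
  full vector uses the arm-side tokens only (4w dimensions).
* ``struct-binary`` [4] -- nucleotide one-hot, but a loop/bulge position
  encodes as all zeros.
* ``extended-binary`` [5] -- 5-symbol one-hot over {A, U, C, G, L}: a
  loop/bulge position is the fifth symbol regardless of its length.
* ``lbsize`` [M+k+3] -- the loop-LENGTH-aware pattern.  Nucleotides occupy
  a one-hot in the first four slots; a loop token of length l carries k
  ones in 1-based slots (4+l)..(k+3+l).  M is the maximum loop/bulge run
  length in the training data and fixes d; k controls how fast kernel
  similarity decays with loop-length difference:

      x1 . x2            = max{k - |l1 - l2|, 0}
      ||x1 - x2||^2      = 2 * min{|l1 - l2|, k}

  both exact consequences of the slot rule (each loop vector has exactly
  k ones, overlapping in k - |l1-l2| slots when |l1-l2| < k).

All structure-aware schemes concatenate the w arm tokens with the w
complementary-strand tokens (2wd dimensions).  Gap placeholders encode as
all zeros under every scheme.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .dataset import LabeledWindow, Token

logger = logging.getLogger(__name__)

__all__ = [
    "SCHEME_NAMES",
    "EncodingScheme",
    "encode_token",
    "encode_tokens",
    "encode_window",
    "encode_windows",
    "loop_dot",
    "loop_sqdist",
]

SCHEME_NAMES = ("seq-binary", "struct-binary", "extended-binary", "lbsize")

_ALIASES = {
    "seq": "seq-binary",
    "struct": "struct-binary",
    "extended": "extended-binary",
    "lbsize": "lbsize",
}

_ONEHOT = {"A": 0, "U": 1, "C": 2, "G": 3}


@dataclass(frozen=True)
class EncodingScheme:
    """A named binary mapping with its window size and parameters.

    ``k`` (number of ones per loop token) and ``M`` (dataset-wide maximum
    loop/bulge length) are meaningful for ``lbsize`` only.
    """

    name: str
    w: int
    k: int = 1
    M: int = 0

    def __post_init__(self) -> None:
        name = _ALIASES.get(self.name, self.name)
        object.__setattr__(self, "name", name)
        if name not in SCHEME_NAMES:
            raise ValueError(
                f"unknown scheme {self.name!r}; expected one of {SCHEME_NAMES}"
            )
        if self.w < 2 or self.w % 2 != 0:
            raise ValueError(f"window size must be even and >= 2, got {self.w}")
        if name == "lbsize":
            if self.k < 1:
                raise ValueError(f"k must be a positive integer, got {self.k}")
            if self.M < 0:
                raise ValueError(f"M must be >= 0, got {self.M}")

    @property
    def token_dim(self) -> int:
        if self.name in ("seq-binary", "struct-binary"):
            return 4
        if self.name == "extended-binary":
            return 5
        return self.M + self.k + 3

    @property
    def n_features(self) -> int:
        """Full-vector length: 4w for seq-binary (arm only), else 2wd."""
        if self.name == "seq-binary":
            return 4 * self.w
        return 2 * self.w * self.token_dim


def encode_token(token: Token, scheme: EncodingScheme) -> np.ndarray:
    """Binary vector of length ``scheme.token_dim`` for one token."""
    d = scheme.token_dim
    vec = np.zeros(d, dtype=np.float64)
    if token.is_gap:
        return vec
    if scheme.name == "seq-binary" or not token.is_loop:
        vec[_ONEHOT[token.base]] = 1.0
        return vec
    # loop token under a structure-aware scheme
    if scheme.name == "struct-binary":
        return vec
    if scheme.name == "extended-binary":
        vec[4] = 1.0
        return vec
    l = token.loop
    if l > scheme.M:
        warnings.warn(
            f"loop length {l} exceeds training maximum M={scheme.M}; "
            "clipping to M",
            stacklevel=2,
        )
        l = scheme.M
    # k ones in 1-based slots (4+l)..(k+3+l)  ->  0-based [3+l, 3+l+k)
    vec[3 + l : 3 + l + scheme.k] = 1.0
    return vec


def encode_tokens(tokens, scheme: EncodingScheme) -> np.ndarray:
    """Concatenated token encodings (one arm's worth of features)."""
    if not tokens:
        return np.zeros(0)
    return np.concatenate([encode_token(t, scheme) for t in tokens])


def encode_window(window: LabeledWindow, scheme: EncodingScheme) -> np.ndarray:
    """Full feature vector for a labeled window.

    seq-binary encodes the arm-side tokens only (4w features); every other
    scheme concatenates arm then complementary tokens (2wd features).
    """
    if window.w != scheme.w:
        raise ValueError(
            f"window size {window.w} does not match scheme w={scheme.w}"
        )
    if scheme.name == "seq-binary":
        return encode_tokens(window.arm_tokens, scheme)
    return np.concatenate(
        [
            encode_tokens(window.arm_tokens, scheme),
            encode_tokens(window.comp_tokens, scheme),
        ]
    )


def encode_windows(windows, scheme: EncodingScheme):
    """Feature matrix X (n x n_features) and label vector y (±1)."""
    windows = list(windows)
    X = np.zeros((len(windows), scheme.n_features))
    y = np.zeros(len(windows), dtype=np.int64)
    for i, win in enumerate(windows):
        X[i] = encode_window(win, scheme)
        y[i] = win.label
    return X, y


def loop_dot(l1: int, l2: int, k: int) -> int:
    """Inner product of two loop-token patterns: max{k - |l1 - l2|, 0}.

    Two loop vectors carry k ones each, shifted by |l1 - l2| slots, so
    they overlap in k - |l1 - l2| slots when that is positive.
    """
    if l1 < 1 or l2 < 1 or k < 1:
        raise ValueError("loop lengths and k must be >= 1")
    return max(k - abs(l1 - l2), 0)


def loop_sqdist(l1: int, l2: int, k: int) -> int:
    """Squared Euclidean distance of two loop patterns: 2 * min{|l1 - l2|, k}.

    Follows from |x|^2 = k for both vectors and the inner product above:
    ||x1 - x2||^2 = 2k - 2 max{k - |l1 - l2|, 0} = 2 min{|l1 - l2|, k}.
    """
    if l1 < 1 or l2 < 1 or k < 1:
        raise ValueError("loop lengths and k must be >= 1")
    return 2 * min(abs(l1 - l2), k)
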