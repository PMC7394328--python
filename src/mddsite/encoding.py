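"""Sequence-feature encodings for lysine-centred windows.

Three composition encodings over the 21-letter alphabet (20 amino acids + X):

AAC
    Amino-acid composition: 21 letter frequencies, normalised by the window
    length 2n+1.
AAPC
    Amino-acid-pair (adjacent dipeptide) composition: 441 = 21x21 ordered
    adjacent-pair frequencies, normalised by the 2n adjacent slots.
CKSAAP(k)
    Composition of k-spaced amino-acid pairs: 441 ordered-pair frequencies
    where the two residues are separated by exactly k arbitrary residues
    ("GxA" for k=1 means G, any one residue, then A), normalised by the
    2n-k available slots.

All encoders are pure functions; every vector is non-negative and sums to 1.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .alphabet import AA20, AA_INDEX, ALPHABET
from .seqio import Fragment

N_SYMBOLS = len(ALPHABET)  # 21
SCHEMES = ("aac", "aapc", "cksaap")


def _codes(sequence: str) -> np.ndarray:
    return np.fromiter((AA_INDEX[c] for c in sequence), dtype=np.intp, count=len(sequence))


def encode_aac(fragment: Fragment, denominator: str = "window") -> np.ndarray:
    """21-component letter-frequency vector.

    Parameters
    ----------
    denominator
        "window" (default): divide all 21 counts by the window length, so the
        vector lies on the simplex regardless of X padding. "native": divide
        by the count of the 20 standard residues only (sensitivity variant).
    """
    counts = np.bincount(_codes(fragment.sequence), minlength=N_SYMBOLS).astype(float)
    if denominator == "window":
        denom = len(fragment.sequence)
    elif denominator == "native":
        denom = counts[: len(AA20)].sum()
        if denom == 0:
            raise ValueError("fragment has no standard residues")
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return counts / denom


def encode_aapc(fragment: Fragment) -> np.ndarray:
    """441-component adjacent-pair composition; index = 21*first + second."""
    codes = _codes(fragment.sequence)
    pair_idx = codes[:-1] * N_SYMBOLS + codes[1:]
    counts = np.bincount(pair_idx, minlength=N_SYMBOLS * N_SYMBOLS).astype(float)
    return counts / (len(fragment.sequence) - 1)


def encode_cksaap(fragment: Fragment, k: int) -> np.ndarray:
    """441-component k-spaced pair composition (pairs at offsets t, t+k+1)."""
    length = len(fragment.sequence)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > length - 2:
        raise ValueError(f"k={k} too large for window length {length}")
    codes = _codes(fragment.sequence)
    pair_idx = codes[: length - k - 1] * N_SYMBOLS + codes[k + 1 :]
    counts = np.bincount(pair_idx, minlength=N_SYMBOLS * N_SYMBOLS).astype(float)
    return counts / (length - k - 1)


def encode_fragment(fragment: Fragment, scheme: str = "aac", k: int | None = None) -> np.ndarray:
    """Dispatch to one encoder by scheme name ('aac', 'aapc', 'cksaap')."""
    if scheme == "aac":
        return encode_aac(fragment)
    if scheme == "aapc":
        return encode_aapc(fragment)
    if scheme == "cksaap":
        if k is None:
            raise ValueError("cksaap requires k")
        return encode_cksaap(fragment, k)
    raise ValueError(f"unknown encoding scheme {scheme!r}")


def encode_matrix(
    fragments: Sequence[Fragment], scheme: str = "aac", k: int | None = None
) -> np.ndarray:
    """Stack per-fragment encodings into an (n_fragments, dim) float array."""
    if not fragments:
        raise ValueError("no fragments to encode")
    return np.vstack([encode_fragment(f, scheme, k) for f in fragments])


def encode_cksaap_concat(fragment: Fragment, ks: Iterable[int] = (1, 2, 3)) -> np.ndarray:
    """Concatenate CKSAAP vectors for several spacings into one vector."""
    return np.concatenate([encode_cksaap(fragment, k) for k in ks])


def feature_names(scheme: str = "aac", k: int | None = None) -> list[str]:
    """Column names matching the encoder output order."""
    if scheme == "aac":
        return list(ALPHABET)
    if scheme == "aapc":
        return [a + b for a in ALPHABET for b in ALPHABET]
    if scheme == "cksaap":
        if k is None:
            raise ValueError("cksaap requires k")
        return [a + "x" * k + b for a in ALPHABET for b in ALPHABET]
    raise ValueError(f"unknown encoding scheme {scheme!r}")
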