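"""Position-pair interdependence and two-sample positional enrichment.

The interdependence between two window positions i and j is measured with a
chi-square statistic on the 21x21 contingency table of residue co-occurrence:

    chi2(X_i, X_j) = sum_mn (Y_mn - E_mn)^2 / E_mn,   E_mn = Y_mc * Y_rn / Y

where Y_mn counts fragments with residue m at i and n at j, Y_mc / Y_rn are
row / column sums and Y the number of fragments. Cells with zero expected
count contribute nothing (no smoothing), which keeps the statistic exactly
the textbook formula on sparse tables.

Positional enrichment between a positive and a negative fragment set is a
two-proportion z-test (pooled variance) per (position, residue), with
Fisher's exact test available for small counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .alphabet import AA20, AA_INDEX, ALPHABET
from .seqio import Fragment

N_SYMBOLS = len(ALPHABET)


def _position_column(fragments: Sequence[Fragment], offset: int) -> np.ndarray:
    """Alphabet codes of the residue at a window offset, over fragments."""
    return np.fromiter(
        (AA_INDEX[f.residue_at(offset)] for f in fragments), dtype=np.intp, count=len(fragments)
    )


def chi2_from_counts(observed: np.ndarray) -> tuple[float, np.ndarray]:
    """Chi-square statistic and expected table; zero-expected cells skipped."""
    observed = np.asarray(observed, dtype=float)
    total = observed.sum()
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / total
    mask = expected > 0
    chi2 = float(((observed[mask] - expected[mask]) ** 2 / expected[mask]).sum())
    return chi2, expected


@dataclass(frozen=True)
class PositionPairTable:
    """Residue-level co-occurrence table for one window position pair."""

    i: int
    j: int
    observed: np.ndarray  # (21, 21) counts
    expected: np.ndarray
    chi2: float

    @property
    def total(self) -> int:
        return int(self.observed.sum())


def position_pair_chi2(fragments: Sequence[Fragment], i: int, j: int) -> PositionPairTable:
    """21x21 residue-level chi-square between window positions *i* and *j*."""
    if i == j:
        raise ValueError("positions i and j must differ")
    if len(fragments) < 2:
        raise ValueError("need at least 2 fragments")
    ci = _position_column(fragments, i)
    cj = _position_column(fragments, j)
    observed = np.zeros((N_SYMBOLS, N_SYMBOLS), dtype=np.int64)
    np.add.at(observed, (ci, cj), 1)
    chi2, expected = chi2_from_counts(observed)
    return PositionPairTable(i=i, j=j, observed=observed, expected=expected, chi2=chi2)


@dataclass(frozen=True)
class DependencyGraph:
    """Symmetric pairwise chi-square over flanking positions (centre excluded,
    being constant K)."""

    positions: tuple[int, ...]
    chi2: np.ndarray  # symmetric, NaN diagonal

    def value(self, i: int, j: int) -> float:
        return float(self.chi2[self.positions.index(i), self.positions.index(j)])

    def max_edge(self) -> tuple[int, int, float]:
        m = np.where(np.isnan(self.chi2), -np.inf, self.chi2)
        a, b = divmod(int(np.argmax(m)), len(self.positions))
        return self.positions[a], self.positions[b], float(m[a, b])


def dependency_graph(fragments: Sequence[Fragment]) -> DependencyGraph:
    """All-pairs residue-level chi-square over the flanking positions."""
    if not fragments:
        raise ValueError("no fragments")
    n = fragments[0].half_width
    if any(f.half_width != n for f in fragments):
        raise ValueError("fragments must share one window size")
    positions = tuple(p for p in range(-n, n + 1) if p != 0)
    k = len(positions)
    mat = np.full((k, k), np.nan)
    for a in range(k):
        for b in range(a + 1, k):
            c = position_pair_chi2(fragments, positions[a], positions[b]).chi2
            mat[a, b] = mat[b, a] = c
    return DependencyGraph(positions=positions, chi2=mat)


@dataclass(frozen=True)
class EnrichmentRecord:
    """Per-(position, residue) frequency difference between the positive and
    negative sets."""

    position: int
    residue: str
    freq_pos: float
    freq_neg: float
    direction: Literal["enriched", "depleted"]
    p_value: float

    @property
    def difference(self) -> float:
        return self.freq_pos - self.freq_neg


def two_sample_position_test(
    positives: Sequence[Fragment],
    negatives: Sequence[Fragment],
    position: int,
    residue: str,
    method: Literal["z", "fisher"] = "z",
) -> EnrichmentRecord | None:
    """Two-sided two-proportion test of residue frequency at one position.

    Returns None when the residue occurs in neither set (frequency-zero
    guard). ``method='z'`` is the pooled-variance z-test; ``'fisher'`` uses
    Fisher's exact test, preferable for small counts.
    """
    if residue not in ALPHABET:
        raise ValueError(f"residue {residue!r} not in alphabet")
    if not positives or not negatives:
        raise ValueError("both fragment sets must be non-empty")
    x1 = sum(f.residue_at(position) == residue for f in positives)
    x2 = sum(f.residue_at(position) == residue for f in negatives)
    n1, n2 = len(positives), len(negatives)
    if x1 == 0 and x2 == 0:
        return None
    p1, p2 = x1 / n1, x2 / n2
    if method == "z":
        pooled = (x1 + x2) / (n1 + n2)
        se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        p_value = 1.0 if se == 0 else float(2 * stats.norm.sf(abs(p1 - p2) / se))
    elif method == "fisher":
        _, p_value = stats.fisher_exact([[x1, n1 - x1], [x2, n2 - x2]])
        p_value = float(p_value)
    else:
        raise ValueError(f"unknown method {method!r}")
    direction = "enriched" if p1 >= p2 else "depleted"
    return EnrichmentRecord(position, residue, p1, p2, direction, min(p_value, 1.0))


def two_sample_logo_table(
    positives: Sequence[Fragment],
    negatives: Sequence[Fragment],
    alpha: float = 0.01,
    method: Literal["z", "fisher"] = "z",
) -> list[EnrichmentRecord]:
    """All (flanking position, standard residue) records with p < *alpha*,
    sorted by position then |frequency difference| descending.

    No multiple-testing correction is applied: records are per-test
    significance calls in the style of two-sample sequence logos.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    n = positives[0].half_width
    records: list[EnrichmentRecord] = []
    for position in range(-n, n + 1):
        if position == 0:
            continue
        for residue in AA20:
            rec = two_sample_position_test(positives, negatives, position, residue, method)
            if rec is not None and rec.p_value < alpha:
                records.append(rec)
    records.sort(key=lambda r: (r.position, -abs(r.difference)))
    return records
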