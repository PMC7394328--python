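"""Homology reduction for aligned peptide windows.

Windows are equal-length and pre-aligned by construction (the lysine sits at
the centre), so percent identity is a plain column-wise match fraction and a
greedy all-vs-all scan reproduces the usual identity-threshold clustering
exactly at this scale — no external clustering binary, no heuristics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seqio import Fragment

logger = logging.getLogger(__name__)


def fragment_identity(a: Fragment, b: Fragment) -> float:
    """Fraction of window positions with identical letters (X matches only X)."""
    if len(a.sequence) != len(b.sequence):
        raise ValueError(
            f"fragments have unequal window lengths ({len(a.sequence)} vs {len(b.sequence)})"
        )
    matches = sum(x == y for x, y in zip(a.sequence, b.sequence))
    return matches / len(a.sequence)


@dataclass
class ClusterResult:
    """Greedy identity clustering: representatives (in founding order) and
    their members."""

    representatives: list[Fragment]
    members: dict[int, list[Fragment]] = field(repr=False)  # rep index -> cluster
    identity_cutoff: float = 0.4

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    def cluster_of(self, index: int) -> list[Fragment]:
        return self.members[index]


def greedy_cluster(fragments: Sequence[Fragment], cutoff: float = 0.4) -> ClusterResult:
    """Greedy single-pass identity clustering.

    Fragments are scanned in input order; each joins the first existing
    representative with identity >= *cutoff*, otherwise it founds a new
    cluster. Deterministic: a pure function of input order and cutoff.
    """
    if not 0 < cutoff <= 1:
        raise ValueError(f"identity cutoff must be in (0, 1], got {cutoff}")
    reps: list[Fragment] = []
    members: dict[int, list[Fragment]] = {}
    for frag in fragments:
        for ri, rep in enumerate(reps):
            if fragment_identity(frag, rep) >= cutoff:
                members[ri].append(frag)
                break
        else:
            reps.append(frag)
            members[len(reps) - 1] = [frag]
    logger.info(
        "greedy clustering at %.0f%% identity: %d fragments -> %d clusters",
        cutoff * 100, len(fragments), len(reps),
    )
    return ClusterResult(representatives=reps, members=members, identity_cutoff=cutoff)


def cross_set_dedup(
    positives: Sequence[Fragment], negatives: Sequence[Fragment]
) -> list[Fragment]:
    """Drop negatives whose window sequence exactly equals any positive window.

    When the same window appears in both classes only the positive instance
    is kept (incomplete annotation makes such clashes likely false
    negatives). Duplicates *within* the negative set are left alone.
    """
    positive_windows = {p.sequence for p in positives}
    kept = [f for f in negatives if f.sequence not in positive_windows]
    dropped = len(negatives) - len(kept)
    if dropped:
        logger.info("cross-set dedup: dropped %d negatives identical to a positive", dropped)
    return kept


def subsample_negatives(
    negatives: Sequence[Fragment],
    positives: Sequence[Fragment],
    ratio: float = 2.0,
    seed: int = 0,
) -> list[Fragment]:
    """Uniformly subsample negatives to ``round(ratio * |positives|)``.

    Capped at the available negatives (with a warning). Reproducible for a
    fixed seed; input order of the selected subset is preserved.
    """
    if ratio <= 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    target = round(ratio * len(positives))
    if target >= len(negatives):
        if target > len(negatives):
            logger.warning(
                "requested %d negatives but only %d available; returning all",
                target, len(negatives),
            )
        return list(negatives)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(negatives), size=target, replace=False))
    return [negatives[i] for i in idx]
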