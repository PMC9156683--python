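"""Pairwise character compatibility and the MCPTP matrix-structure test.

Two binary characters are compatible when some tree fits both without
homoplasy; for complete binary data this is exactly the four-gamete
condition — they are incompatible iff all four joint patterns
(0,0), (0,1), (1,0), (1,1) occur among the taxa.  The matrix
compatibility permutation tail probability (MCPTP) test asks whether a
matrix has fewer incompatible character pairs than expected when each
column is permuted independently across taxa (column state frequencies
preserved).  The null must permute columns independently: permuting
whole rows relabels taxa simultaneously in every character and provably
leaves the incompatibility count unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from biogeofit.parsimony import _as_matrix


class CompatError(ValueError):
    pass


@dataclass(frozen=True)
class CompatResult:
    n_incompatible_pairs: int
    n_pairs: int
    p_value: float
    n_perm: int
    seed: Optional[int]

    def to_dict(self) -> dict:
        return {
            "n_incompatible_pairs": self.n_incompatible_pairs,
            "n_pairs": self.n_pairs, "p_value": self.p_value,
            "n_perm": self.n_perm, "seed": self.seed,
        }


def pair_compatible(c1, c2) -> bool:
    """Four-gamete compatibility of two complete binary characters."""
    a = np.asarray(c1, dtype=bool)
    b = np.asarray(c2, dtype=bool)
    if a.shape != b.shape:
        raise CompatError("character length mismatch")
    patterns = {(bool(x), bool(y)) for x, y in zip(a, b)}
    return len(patterns) < 4


def _incompat_count(entries: np.ndarray) -> int:
    """Incompatible pairs among all columns, via joint-pattern counts."""
    m = entries.astype(np.int64)
    c = 1 - m
    n11 = m.T @ m
    n10 = m.T @ c
    n01 = c.T @ m
    n00 = c.T @ c
    bad = (n11 > 0) & (n10 > 0) & (n01 > 0) & (n00 > 0)
    return int(np.triu(bad, k=1).sum())


def incompatibility_count(matrix) -> int:
    """Number of unordered character pairs failing the four-gamete test."""
    _, entries = _as_matrix(matrix)
    if entries.shape[1] < 2:
        raise CompatError("need at least 2 characters")
    return _incompat_count(entries)


def mcptp_test(matrix, n_perm: int = 10_000,
               seed: Optional[int] = None, *,
               rng: Optional[np.random.Generator] = None) -> CompatResult:
    """Matrix compatibility permutation tail probability test.

    One-sided toward *small* incompatibility counts (fewer
    incompatibilities = more hierarchical structure), with the add-one
    estimator p = (#{count_perm ≤ observed} + 1)/(n_perm + 1).
    """
    if getattr(matrix, "untestable", False):
        raise CompatError("matrix flagged untestable")
    _, entries = _as_matrix(matrix)
    n_taxa, k = entries.shape
    variable = ((entries.sum(axis=0) > 0) & (entries.sum(axis=0) < n_taxa)).sum()
    if k < 2 or variable < 2:
        raise CompatError("need at least 2 variable characters")
    if rng is None:
        if seed is None:
            raise CompatError("a seed (or rng) is required")
        rng = np.random.default_rng(seed)

    observed = _incompat_count(entries)
    tail = 0
    for _ in range(n_perm):
        idx = rng.random((n_taxa, k)).argsort(axis=0)
        perm = np.take_along_axis(entries, idx, axis=0)
        if _incompat_count(perm) <= observed:
            tail += 1
    p = (tail + 1) / (n_perm + 1)
    return CompatResult(
        n_incompatible_pairs=observed, n_pairs=k * (k - 1) // 2,
        p_value=p, n_perm=n_perm, seed=seed,
    )
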