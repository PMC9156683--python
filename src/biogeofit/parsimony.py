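"""Unordered parsimony of binary characters on arbitrary rooted trees.

Character lengths are computed with Hartigan's generalisation of the
Fitch algorithm, which is exact for multifurcating trees: polytomies are
treated as *hard* — the tree is scored as given, with no credit for
hypothetical resolutions.  The implementation is vectorised so that many
characters (and many permuted replicates of a matrix) are scored in a
single postorder sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from biogeofit.phylo import PhyloTree


class ParsimonyError(ValueError):
    pass


def _leaf_state_arrays(tree: PhyloTree, taxa: list[str],
                       states: np.ndarray) -> dict[str, np.ndarray]:
    """Map leaf label -> row of ``states`` (rows indexed like ``taxa``)."""
    index = {t: i for i, t in enumerate(taxa)}
    missing = [lab for lab in tree.leaf_labels if lab not in index]
    if missing:
        raise ParsimonyError(f"leaves without character states: {sorted(missing)}")
    return {lab: states[index[lab]] for lab in tree.leaf_labels}


def tree_lengths(tree: PhyloTree, leaf_states: dict[str, np.ndarray]) -> np.ndarray:
    """Minimum state changes for each binary character on ``tree``.

    ``leaf_states`` maps every leaf label to an integer array of 0/1
    states with a common shape S; the result has shape S with one
    parsimony length per character.  Hartigan downpass: at each internal
    node the optimal state set is the set of states occurring in a
    maximal number of children's optimal sets, and the node contributes
    (number of children − that maximum) changes.
    """
    shape = None
    for lab in tree.leaf_labels:
        if lab not in leaf_states:
            raise ParsimonyError(f"leaf {lab!r} has no character state")
        arr = np.asarray(leaf_states[lab])
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ParsimonyError("inconsistent state array shapes across leaves")
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ParsimonyError("non-binary character state encountered")

    steps = np.zeros(shape, dtype=np.int64)
    # has0/has1: whether 0 (resp. 1) is in the node's optimal state set
    sets: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            s = np.asarray(leaf_states[node.label])
            sets[id(node)] = (s == 0, s == 1)
        else:
            n0 = np.zeros(shape, dtype=np.int64)
            n1 = np.zeros(shape, dtype=np.int64)
            for child in node.children:
                h0, h1 = sets.pop(id(child))
                n0 += h0
                n1 += h1
            k = np.maximum(n0, n1)
            steps += len(node.children) - k
            sets[id(node)] = (n0 == k, n1 == k)
    return steps


def character_length(tree: PhyloTree, char: dict[str, int]) -> int:
    """Parsimony length of a single binary character.

    ``char`` maps every leaf label to a state in {0, 1}.  The result is
    invariant to root placement (unrooted parsimony length).
    """
    leaf_states = {}
    for lab in tree.leaf_labels:
        if lab not in char:
            raise ParsimonyError(f"leaf {lab!r} has no state")
        leaf_states[lab] = np.asarray(char[lab])
    return int(tree_lengths(tree, leaf_states))


def character_bounds(column: np.ndarray) -> tuple[int, int]:
    """(MINL, MAXL) for a binary character column.

    MINL is the number of observed states minus one; MAXL is the number
    of leaves minus the majority-state count — for binary data simply
    min(#0, #1), the length on a star tree.
    """
    col = np.asarray(column)
    if col.size == 0:
        raise ParsimonyError("empty character column")
    if not np.isin(col, (0, 1)).all():
        raise ParsimonyError("non-binary character state encountered")
    n1 = int(col.sum())
    n0 = col.size - n1
    minl = (n0 > 0) + (n1 > 0) - 1
    maxl = min(n0, n1)
    return minl, maxl


@dataclass(frozen=True)
class CharacterFit:
    """Per-character parsimony lengths and the ensemble CI/RI."""

    lengths: np.ndarray        # observed steps per character
    min_lengths: np.ndarray    # MINL per character
    max_lengths: np.ndarray    # MAXL per character
    sum_length: int
    sum_min: int
    sum_max: int
    ci: float
    ri: float

    @property
    def n_characters(self) -> int:
        return len(self.lengths)


def matrix_lengths(tree: PhyloTree, taxa: list[str], matrix: np.ndarray) -> np.ndarray:
    """Per-character parsimony lengths of a taxa × characters 0/1 matrix."""
    matrix = np.asarray(matrix)
    leaf_states = _leaf_state_arrays(tree, taxa, matrix)
    return tree_lengths(tree, leaf_states)


def ensemble_fit(tree: PhyloTree, matrix) -> CharacterFit:
    """Ensemble consistency and retention indices of a binary matrix on a tree.

    CI = ΣMINL/ΣL and RI = (ΣMAXL − ΣL)/(ΣMAXL − ΣMINL), summing over
    characters.  The matrix may be a :class:`~biogeofit.regions.RegionMatrix`
    or a (taxa, entries) pair; its taxa must equal the tree's leaves.
    """
    taxa, entries = _as_matrix(matrix)
    if set(taxa) != set(tree.leaf_labels):
        raise ParsimonyError("matrix taxa and tree leaves differ")
    lengths = matrix_lengths(tree, taxa, entries)
    bounds = [character_bounds(entries[:, j]) for j in range(entries.shape[1])]
    minl = np.array([b[0] for b in bounds])
    maxl = np.array([b[1] for b in bounds])
    sum_l, sum_min, sum_max = int(lengths.sum()), int(minl.sum()), int(maxl.sum())
    if sum_l == 0:
        raise ParsimonyError("no variable characters: ensemble length is zero")
    if sum_max == sum_min:
        raise ParsimonyError(
            "all characters parsimony-uninformative (ΣMAXL = ΣMINL); RI undefined"
        )
    ci = sum_min / sum_l
    ri = (sum_max - sum_l) / (sum_max - sum_min)
    return CharacterFit(
        lengths=lengths, min_lengths=minl, max_lengths=maxl,
        sum_length=sum_l, sum_min=sum_min, sum_max=sum_max, ci=ci, ri=ri,
    )


def _as_matrix(matrix) -> tuple[list[str], np.ndarray]:
    """Accept a RegionMatrix-like object or a (taxa, array) pair."""
    if hasattr(matrix, "taxa") and hasattr(matrix, "entries"):
        return list(matrix.taxa), np.asarray(matrix.entries)
    taxa, entries = matrix
    return list(taxa), np.asarray(entries)
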