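"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive: exhaustive enumeration of tree
topologies, of internal-state assignments, and of permutation groups.
None of it shares code with the package's implementations.
"""

from __future__ import annotations

import itertools

import numpy as np

from biogeofit.phylo import Node, PhyloTree


# -- topology enumeration ----------------------------------------------------


def set_partitions(items: list, min_blocks: int = 1):
    """All partitions of ``items`` into at least ``min_blocks`` blocks."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        # put `first` into an existing block
        for i in range(len(partition)):
            candidate = partition[:i] + [[first] + partition[i]] + partition[i + 1:]
            if len(candidate) >= min_blocks:
                yield candidate
        candidate = [[first]] + partition
        if len(candidate) >= min_blocks:
            yield candidate


def all_rooted_topologies(leaves: list[str], bifurcating: bool = False):
    """Nested-tuple encodings of every rooted leaf-labelled tree."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    for partition in set_partitions(list(leaves), min_blocks=2):
        if bifurcating and len(partition) != 2:
            continue
        block_trees = [list(all_rooted_topologies(block, bifurcating))
                       for block in partition]
        for combo in itertools.product(*block_trees):
            yield tuple(combo)


def tuple_to_tree(encoding) -> PhyloTree:
    def build(enc) -> Node:
        if isinstance(enc, str):
            return Node(enc)
        node = Node()
        for sub in enc:
            node.add_child(build(sub))
        return node
    return PhyloTree(build(encoding))


def random_topology(leaves: list[str], rng: np.random.Generator):
    """One uniformly-structured random rooted (multifurcating) tree."""
    if len(leaves) == 1:
        return leaves[0]
    k = int(rng.integers(2, len(leaves) + 1))
    # random surjection of leaves onto k blocks
    while True:
        assignment = rng.integers(0, k, size=len(leaves))
        if len(set(assignment)) == k:
            break
    blocks = [[lf for lf, a in zip(leaves, assignment) if a == b] for b in range(k)]
    return tuple(random_topology(b, rng) for b in blocks)


# -- brute-force parsimony ---------------------------------------------------


def brute_force_lengths(tree: PhyloTree, chars: np.ndarray,
                        taxa: list[str]) -> np.ndarray:
    """Minimum changes per character by enumerating ALL internal labelings.

    ``chars`` is (n_taxa, n_chars); returns (n_chars,) minimum edge
    mismatch counts over every assignment of {0,1} to internal nodes.
    """
    internals = tree.internal_nodes()
    index = {id(node): i for i, node in enumerate(internals)}
    leaf_state = {t: chars[i] for i, t in enumerate(taxa)}
    n_int = len(internals)
    assigns = np.array(list(itertools.product((0, 1), repeat=n_int)))  # (A, I)
    cost = np.zeros((len(assigns), chars.shape[1]), dtype=np.int64)
    for node in internals:
        pcol = assigns[:, index[id(node)]]
        for child in node.children:
            if child.is_leaf:
                cost += np.abs(pcol[:, None] - leaf_state[child.label][None, :])
            else:
                cost += np.abs(pcol - assigns[:, index[id(child)]])[:, None]
    return cost.min(axis=0)


def brute_force_length_single(tree: PhyloTree, char: dict[str, int]) -> int:
    taxa = tree.leaf_labels
    chars = np.array([[char[t]] for t in taxa])
    return int(brute_force_lengths(tree, chars, taxa)[0])


def all_binary_columns(n: int) -> np.ndarray:
    """(2**n, n) array of every binary column on n taxa."""
    return np.array(list(itertools.product((0, 1), repeat=n)), dtype=np.int8)


# -- exhaustive permutation nulls --------------------------------------------


def exhaustive_row_permutation_lengths(tree: PhyloTree, taxa: list[str],
                                       entries: np.ndarray) -> list[int]:
    """Ensemble length for every one of the n! row reassignments."""
    out = []
    for perm in itertools.permutations(range(len(taxa))):
        permuted = entries[list(perm)]
        out.append(int(brute_force_lengths(tree, permuted, taxa).sum()))
    return out
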