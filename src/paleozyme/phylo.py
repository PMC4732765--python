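"""Likelihood-based phylogenetics: pruning likelihood, distances, tree search.

The tree likelihood is computed with the pruning (sum-product) algorithm over
reversible amino-acid models, with per-column rescaling against underflow,
gaps/ambiguous residues as missing data, and optional discrete-gamma rate
averaging.  Tree search is a maximum-likelihood surrogate at desk scale:
neighbour-joining start tree from pairwise ML distances, then alternating
per-branch Brent optimisation and best-improving nearest-neighbour
interchanges until no move improves the log-likelihood.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .models import SubstitutionModel
from .msa import Alignment

_BL_MIN, _BL_MAX = 1e-9, 20.0


def label_internal_nodes(tree: dendropy.Tree, prefix: str = "N") -> None:
    """Assign stable preorder labels N0, N1, ... to unlabeled internal nodes."""
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if not node.label:
            node.label = f"{prefix}{i}"
        i += 1


# ---------------------------------------------------------------------------
# tree indexing


class _TreeIndex:
    """Flat postorder view of a dendropy tree for vectorised pruning."""

    def __init__(self, tree: dendropy.Tree):
        self.nodes = list(tree.postorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.children = [
            [self.index[id(c)] for c in n.child_nodes()] for n in self.nodes
        ]
        self.lengths = [
            (n.edge.length or 0.0) for n in self.nodes
        ]
        self.labels = [
            n.taxon.label if n.is_leaf() else n.label for n in self.nodes
        ]
        self.is_leaf = [n.is_leaf() for n in self.nodes]
        self.root = len(self.nodes) - 1


def _leaf_partial(states: np.ndarray, k: int) -> np.ndarray:
    """(k, ncols) indicator partial; missing (-1) columns are all-ones."""
    ncols = states.size
    partial = np.zeros((k, ncols))
    observed = states >= 0
    partial[:, ~observed] = 1.0
    partial[states[observed], np.nonzero(observed)[0]] = 1.0
    return partial


def encode_alignment(aln: Alignment, model: SubstitutionModel) -> dict[str, np.ndarray]:
    return {label: model.encode(seq) for label, seq in aln.rows.items()}


def _pruning_pass(
    idx: _TreeIndex,
    data: dict[str, np.ndarray],
    model: SubstitutionModel,
    rate: float,
) -> tuple[list[np.ndarray], np.ndarray, list[np.ndarray]]:
    """Upward partials for one rate category.

    Returns (partials per node, per-column log scale at the root accumulated
    over all nodes, transition matrices per node edge).  Partials are rescaled
    per column; the common scale cancels in posterior ratios and is added back
    for absolute likelihoods.
    """
    k = model.n_states
    ncols = next(iter(data.values())).size
    partials: list[np.ndarray] = [None] * len(idx.nodes)
    pmats: list[np.ndarray] = [None] * len(idx.nodes)
    logscale = np.zeros(ncols)
    for i, _ in enumerate(idx.nodes):
        if idx.is_leaf[i]:
            partials[i] = _leaf_partial(data[idx.labels[i]], k)
        else:
            part = np.ones((k, ncols))
            for c in idx.children[i]:
                if pmats[c] is None:
                    pmats[c] = model.transition_matrix(idx.lengths[c], rate=rate)
                part = part * (pmats[c] @ partials[c])
            scale = part.max(axis=0)
            scale[scale == 0] = 1.0
            part /= scale
            logscale += np.log(scale)
            partials[i] = part
    return partials, logscale, pmats


def tree_log_likelihood(
    tree: dendropy.Tree, aln: Alignment, model: SubstitutionModel,
    data: dict[str, np.ndarray] | None = None,
) -> float:
    """Log-likelihood of the alignment on the tree under the model.

    Gamma rate categories are averaged with equal weights; gaps and ambiguous
    residues contribute a partial of one for every state (missing data).
    """
    idx = _TreeIndex(tree)
    leaf_labels = {idx.labels[i] for i in range(len(idx.nodes)) if idx.is_leaf[i]}
    if data is None:
        if leaf_labels != set(aln.rows):
            raise ValueError("tree leaf labels do not match alignment rows")
        data = encode_alignment(aln, model)
    pi = model.frequencies
    rates = model.rate_categories()
    percol = []
    for rate in rates:
        partials, logscale, _ = _pruning_pass(idx, data, model, float(rate))
        percol.append(np.log(pi @ partials[idx.root]) + logscale)
    if len(percol) == 1:
        return float(np.sum(percol[0]))
    return float(np.sum(logsumexp(np.stack(percol), axis=0) - np.log(len(rates))))


# ---------------------------------------------------------------------------
# distances and neighbour joining


def ml_distances(aln: Alignment, model: SubstitutionModel) -> tuple[np.ndarray, list[str]]:
    """Pairwise maximum-likelihood branch lengths under the model.

    For each pair, the distance maximises sum over shared ungapped columns of
    log(pi_a * P_ab(t)); identical pairs get distance 0.
    """
    labels = aln.labels
    data = encode_alignment(aln, model)
    pi = model.frequencies
    k = model.n_states
    n = len(labels)
    dist = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = data[labels[i]], data[labels[j]]
        mask = (a >= 0) & (b >= 0)
        counts = np.zeros((k, k))
        np.add.at(counts, (a[mask], b[mask]), 1.0)
        if counts.sum() == 0:
            continue
        if np.trace(counts) == counts.sum():
            continue  # identical -> 0

        def neg_ll(t):
            p = model.transition_matrix(t)
            return -float(np.sum(counts * np.log(pi[:, None] * p + 1e-300)))

        res = minimize_scalar(neg_ll, bounds=(_BL_MIN, _BL_MAX), method="bounded")
        dist[i, j] = dist[j, i] = float(res.x)
    return dist, labels


def nj_tree(distances: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Neighbour-joining topology (deterministic); negative branch lengths
    clamped to zero."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    distances = np.asarray(distances, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    if distances.shape != (n, n) or not np.allclose(np.diag(distances), 0):
        raise ValueError("distances must be square with zero diagonal")
    if not np.all(np.isfinite(distances)):
        raise ValueError("distances must be finite")
    newick = str(nj(DistanceMatrix(distances, list(labels))))
    tree = dendropy.Tree.get(data=newick, schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return tree


def ensure_rooted_binary(tree: dendropy.Tree) -> dendropy.Tree:
    """Root an unrooted (trifurcating-root) tree by splitting one root edge."""
    root = tree.seed_node
    if len(root.child_nodes()) <= 2:
        tree.is_rooted = True
        return tree
    child = root.child_nodes()[0]
    length = child.edge.length or 0.0
    tree.reroot_at_edge(child.edge, length1=length / 2.0, length2=length / 2.0)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# branch-length optimisation and NNI search


def optimize_branch_lengths(
    tree: dendropy.Tree,
    aln: Alignment,
    model: SubstitutionModel,
    tol: float = 1e-3,
    max_rounds: int = 20,
) -> float:
    """Round-robin Brent optimisation of every branch length, in place.

    Returns the final log-likelihood; iterates until a full round improves by
    less than ``tol``.
    """
    data = encode_alignment(aln, model)
    edges = [
        n for n in tree.preorder_node_iter() if n.parent_node is not None
    ]
    current = tree_log_likelihood(tree, aln, model, data=data)
    for _ in range(max_rounds):
        before = current
        for node in edges:
            def neg_ll(t):
                node.edge.length = t
                return -tree_log_likelihood(tree, aln, model, data=data)

            res = minimize_scalar(
                neg_ll, bounds=(_BL_MIN, _BL_MAX), method="bounded",
                options={"xatol": 1e-6},
            )
            node.edge.length = float(res.x)
            current = -float(res.fun)
        if current - before < tol:
            break
    return current


def _nni_sites(tree: dendropy.Tree):
    """Internal nodes (non-root, with children) where an NNI can pivot."""
    for node in tree.preorder_internal_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        siblings = [c for c in parent.child_nodes() if c is not node]
        if len(siblings) != 1 or len(node.child_nodes()) != 2:
            continue
        yield node, siblings[0]


def _swap(node_child: dendropy.Node, sibling: dendropy.Node) -> None:
    """Exchange a child of an internal node with that node's sibling."""
    inner = node_child.parent_node
    parent = inner.parent_node
    inner.remove_child(node_child)
    parent.remove_child(sibling)
    inner.add_child(sibling)
    parent.add_child(node_child)


def nni_ml_search(
    start: dendropy.Tree,
    aln: Alignment,
    model: SubstitutionModel,
    tol: float = 1e-2,
    max_iter: int = 50,
) -> tuple[dendropy.Tree, float]:
    """Hill-climb over nearest-neighbour interchanges.

    Alternates full branch-length optimisation with the best-improving NNI;
    stops when no interchange improves the log-likelihood by more than
    ``tol``.  The returned likelihood never decreases below the start value.
    Ties are broken by the first-encountered pivot in a fixed traversal.
    """
    tree = ensure_rooted_binary(start.clone(depth=1))
    current = optimize_branch_lengths(tree, aln, model, tol=tol)
    for _ in range(max_iter):
        best_gain = 0.0
        best_move = None
        for node, sibling in list(_nni_sites(tree)):
            for child in list(node.child_nodes()):
                _swap(child, sibling)
                ll = tree_log_likelihood(tree, aln, model)
                _swap(sibling, child)  # undo
                if ll - current > best_gain + 1e-12:
                    best_gain = ll - current
                    best_move = (child, sibling)
        if best_move is None or best_gain <= tol:
            break
        _swap(*best_move)
        current = optimize_branch_lengths(tree, aln, model, tol=tol)
    return tree, current


# ---------------------------------------------------------------------------
# rooting


def root_with_outgroup(tree: dendropy.Tree, outgroup: set[str]) -> dendropy.Tree:
    """Root on the branch separating a monophyletic outgroup from the ingroup,
    splitting that branch 50:50."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    outgroup = set(outgroup)
    if not outgroup or not outgroup < leaves:
        raise ValueError("outgroup must be a proper nonempty subset of the leaves")
    work = tree.clone(depth=1)
    work.is_rooted = True

    # view the tree as unrooted: an edge whose leaf-side set equals the
    # outgroup or its complement separates the two groups
    target = None
    for node in work.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if below == outgroup or below == leaves - outgroup:
            target = node
            break
    if target is None:
        mrca = work.mrca(taxon_labels=sorted(outgroup))
        spanned = {lf.taxon.label for lf in mrca.leaf_iter()}
        offending = sorted(spanned - outgroup)
        raise ValueError(
            f"outgroup is not monophyletic; intruding leaves: {', '.join(offending)}"
        )
    length = target.edge.length or 0.0
    work.reroot_at_edge(target.edge, length1=length / 2.0, length2=length / 2.0)
    work.is_rooted = True
    return work


def total_tree_length(tree: dendropy.Tree) -> float:
    return sum(e.length or 0.0 for e in tree.preorder_edge_iter())
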