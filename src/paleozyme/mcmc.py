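"""Bayesian tree sampling with convergence diagnostics and consensus trees.

A Metropolis-Hastings sampler over (topology, branch lengths): topology moves
are random nearest-neighbour interchanges (symmetric proposal), branch-length
moves are multiplier proposals on a random edge, under a uniform topology
prior and independent exponential(10) branch-length priors.  Several
independent chains are compared through the split-frequency discrepancy index
(maxdiff) and per-chain effective sample sizes; a majority-rule consensus
tree greedily extended with compatible splits summarises the pooled
post-burnin sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .models import SubstitutionModel
from .msa import Alignment
from .phylo import (
    _nni_sites,
    _swap,
    encode_alignment,
    ensure_rooted_binary,
    ml_distances,
    nj_tree,
    total_tree_length,
    tree_log_likelihood,
)

BRANCH_PRIOR_RATE = 10.0  # exponential prior on branch lengths


Split = frozenset  # side of a leaf bipartition not containing the reference leaf


@dataclass
class ChainTrace:
    trees: list[str]                 # newick strings, one per sample
    splits: list[frozenset]          # frozenset of Splits per sample
    loglik: np.ndarray
    tree_length: np.ndarray


@dataclass
class McmcRun:
    chains: list[ChainTrace]
    n_samples: int
    burnin: int
    taxa: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.burnin >= self.n_samples:
            raise ValueError("burnin must be smaller than n_samples")


@dataclass
class SplitSupportTree:
    tree: dendropy.Tree
    supports: dict[frozenset, float]


# ---------------------------------------------------------------------------
# split bookkeeping


def tree_splits(tree: dendropy.Tree, taxa: list[str]) -> frozenset:
    """Nontrivial unrooted splits, each as the side excluding the reference
    (first) taxon."""
    ref = taxa[0]
    full = set(taxa)
    n = len(taxa)
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        side = below if ref not in below else full - below
        if 2 <= len(side) <= n - 2:
            out.add(frozenset(side))
    return frozenset(out)


def split_frequencies(chain: ChainTrace, burnin: int) -> dict[frozenset, float]:
    post = chain.splits[burnin:]
    if not post:
        raise ValueError("empty post-burnin sample")
    counts: dict[frozenset, int] = {}
    for splitset in post:
        for s in splitset:
            counts[s] = counts.get(s, 0) + 1
    return {s: c / len(post) for s, c in counts.items()}


def maxdiff(run: McmcRun, burnin: int | None = None) -> float:
    """Maximum over chain pairs and observed nontrivial splits of the absolute
    split-frequency difference; 0 for perfectly agreeing chains, 1 for chains
    that never overlap on some split."""
    if len(run.chains) < 2:
        raise ValueError("maxdiff needs at least 2 chains")
    burnin = run.burnin if burnin is None else burnin
    freqs = [split_frequencies(c, burnin) for c in run.chains]
    all_splits = set().union(*freqs)
    worst = 0.0
    for i in range(len(freqs)):
        for j in range(i + 1, len(freqs)):
            for s in all_splits:
                d = abs(freqs[i].get(s, 0.0) - freqs[j].get(s, 0.0))
                if d > worst:
                    worst = d
    return worst


def ess(trace) -> float:
    """Effective sample size N / (1 + 2 * sum rho_k), truncating the
    autocorrelation sum at the first non-positive term; capped at N."""
    x = np.asarray(trace, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("trace too short for an ESS estimate")
    var = x.var()
    if var == 0:
        warnings.warn("constant trace; ESS undefined, returning N")
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (var * n)
    s = 0.0
    for k in range(1, n):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(min(n, n / (1.0 + 2.0 * s)))


def min_ess(run: McmcRun, burnin: int | None = None) -> float:
    """Smallest ESS over chains and traced scalars (log-likelihood, tree length)."""
    burnin = run.burnin if burnin is None else burnin
    vals = []
    for c in run.chains:
        vals.append(ess(c.loglik[burnin:]))
        vals.append(ess(c.tree_length[burnin:]))
    return min(vals)


# ---------------------------------------------------------------------------
# sampler


def _log_prior(tree: dendropy.Tree) -> float:
    lp = 0.0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            lp += np.log(BRANCH_PRIOR_RATE) - BRANCH_PRIOR_RATE * edge.length
    return lp


def mcmc_sample(
    aln: Alignment,
    model: SubstitutionModel,
    n_chains: int = 4,
    n_samples: int = 2000,
    seed: int = 0,
    burnin_frac: float = 0.1,
    start: dendropy.Tree | None = None,
) -> McmcRun:
    """Sample trees with independent Metropolis-Hastings chains.

    Each iteration proposes either a random NNI (probability 1/2, symmetric)
    or a branch-length multiplier on a random edge (Hastings ratio equal to
    the multiplier).  Chains are independent given distinct sub-seeds derived
    from ``seed``; identical seeds give identical traces.
    """
    if n_chains < 1:
        raise ValueError("need at least one chain")
    taxa = sorted(aln.rows)
    data = None
    if start is None:
        d, labels = ml_distances(aln, model)
        start = nj_tree(d, labels)
    start = ensure_rooted_binary(start.clone(depth=1))
    for edge in start.preorder_edge_iter():
        if edge.length is not None and edge.length <= 0:
            edge.length = 1e-6

    chains = []
    for c in range(n_chains):
        rng = np.random.default_rng((seed + 1000003 * c) % (2**31 - 1))
        tree = start.clone(depth=1)
        if data is None:
            data = encode_alignment(aln, model)
        ll = tree_log_likelihood(tree, aln, model, data=data)
        lp = _log_prior(tree)
        trees, splitsets = [], []
        logliks = np.empty(n_samples)
        tlens = np.empty(n_samples)
        for it in range(n_samples):
            if rng.random() < 0.5:
                # random NNI, symmetric
                sites = list(_nni_sites(tree))
                if sites:
                    node, sibling = sites[int(rng.integers(len(sites)))]
                    child = node.child_nodes()[int(rng.integers(2))]
                    _swap(child, sibling)
                    new_ll = tree_log_likelihood(tree, aln, model, data=data)
                    new_lp = _log_prior(tree)
                    if np.log(rng.random() + 1e-300) < (new_ll + new_lp) - (ll + lp):
                        ll, lp = new_ll, new_lp
                    else:
                        _swap(sibling, child)
            else:
                edges = [
                    n for n in tree.preorder_node_iter() if n.parent_node is not None
                ]
                node = edges[int(rng.integers(len(edges)))]
                old = node.edge.length or 1e-6
                factor = np.exp(1.0 * (rng.random() - 0.5))
                node.edge.length = old * factor
                new_ll = tree_log_likelihood(tree, aln, model, data=data)
                new_lp = _log_prior(tree)
                log_hastings = np.log(factor)
                if np.log(rng.random() + 1e-300) < (new_ll + new_lp) - (ll + lp) + log_hastings:
                    ll, lp = new_ll, new_lp
                else:
                    node.edge.length = old
            trees.append(tree.as_string(schema="newick").strip())
            splitsets.append(tree_splits(tree, taxa))
            logliks[it] = ll
            tlens[it] = total_tree_length(tree)
        chains.append(ChainTrace(trees, splitsets, logliks, tlens))
    burnin = int(burnin_frac * n_samples)
    return McmcRun(chains=chains, n_samples=n_samples, burnin=burnin, taxa=taxa)


def topology_posterior(run: McmcRun, reference: dendropy.Tree, burnin: int | None = None) -> float:
    """Posterior probability of the reference (unrooted) topology in the
    pooled post-burnin sample."""
    burnin = run.burnin if burnin is None else burnin
    ref_splits = tree_splits(reference, run.taxa)
    hits = total = 0
    for chain in run.chains:
        for splitset in chain.splits[burnin:]:
            total += 1
            if splitset == ref_splits:
                hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# consensus


def _compatible(a: frozenset, b: frozenset) -> bool:
    return a <= b or b <= a or not (a & b)


def consensus_with_support(run: McmcRun, burnin: int | None = None) -> SplitSupportTree:
    """Majority-rule consensus of the pooled chains, greedily extended with
    compatible lower-frequency splits; node supports are pooled frequencies."""
    burnin = run.burnin if burnin is None else burnin
    counts: dict[frozenset, int] = {}
    total = 0
    for chain in run.chains:
        post = chain.splits[burnin:]
        total += len(post)
        for splitset in post:
            for s in splitset:
                counts[s] = counts.get(s, 0) + 1
    freqs = {s: c / total for s, c in counts.items()}

    # deterministic order: frequency desc, then by sorted member tuple
    ordered = sorted(freqs, key=lambda s: (-freqs[s], tuple(sorted(s))))
    accepted: list[frozenset] = []
    for s in ordered:
        if freqs[s] <= 0.5 and accepted and any(
            not _compatible(s, t) for t in accepted
        ):
            continue
        if all(_compatible(s, t) for t in accepted):
            accepted.append(s)

    taxa = run.taxa
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = False
    full = frozenset(taxa)
    # nest accepted splits by containment (largest first)
    accepted_sorted = sorted(accepted, key=len, reverse=True)
    parent_of: dict[frozenset, frozenset] = {}
    for i, s in enumerate(accepted_sorted):
        candidates = [t for t in accepted_sorted[:i] if s < t]
        parent_of[s] = min(candidates, key=len) if candidates else full

    nodes: dict[frozenset, dendropy.Node] = {full: tree.seed_node}
    for s in accepted_sorted:
        node = nodes[parent_of[s]].new_child()
        node.label = f"{freqs[s]:.4f}"
        nodes[s] = node
    for leaf_label in taxa:
        host = full
        for s in accepted_sorted:
            if leaf_label in s and len(s) < len(host):
                host = s
        leaf = nodes[host].new_child()
        leaf.taxon = tns.get_taxon(leaf_label)

    supports = {s: freqs[s] for s in accepted}
    for label in taxa:  # trivial splits always have support 1
        supports[frozenset({label})] = 1.0
    return SplitSupportTree(tree=tree, supports=supports)
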