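"""Marginal ancestral sequence reconstruction with indel reconstruction.

For every internal node of a rooted tree, the per-column posterior over
residues is computed by combining the upward (pruning) partials of the
subtree below the node with the downward partials of the rest of the tree:

    P(state | data) ∝ up(state) * outside(state)

where ``outside(root) = pi`` and, for a child v of u,
``outside(v) = P_v^T (outside(u) * prod_{siblings w} P_w up(w))``.

Residue presence at a column is modelled separately with a two-state
reversible gain/loss process on the gap pattern; the most-likely ancestral
sequence emits the posterior-argmax residue wherever the presence posterior
favours a residue over a gap, and a gap elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.special import logsumexp

from .models import GAP, SubstitutionModel, presence_absence
from .msa import Alignment
from .phylo import _pruning_pass, _TreeIndex, encode_alignment


@dataclass
class AncestralReconstruction:
    """Per-column residue posteriors and presence posteriors at one node.

    ``ml_sequence`` has one character per alignment column: the posterior
    argmax residue where ``presence_posterior >= 0.5`` (ties favour presence),
    the gap character elsewhere.  Argmax ties between residues are broken
    alphabetically.  ``mean_posterior`` averages the chosen residue's
    posterior over emitted (non-gap) columns.
    """

    node_id: str
    residue_posteriors: np.ndarray  # (ncols, n_states)
    presence_posterior: np.ndarray  # (ncols,)
    ml_sequence: str
    mean_posterior: float


def _require_rooted(tree: dendropy.Tree) -> None:
    nchild = len(tree.seed_node.child_nodes())
    if not tree.is_rooted or nchild != 2:
        raise ValueError("ancestral reconstruction requires a rooted binary tree")
    labels = [n.label for n in tree.preorder_internal_node_iter()]
    if any(not lab for lab in labels) or len(set(labels)) != len(labels):
        from .phylo import label_internal_nodes

        for node in tree.preorder_internal_node_iter():
            node.label = None
        label_internal_nodes(tree)


def _marginal_node_posteriors(
    tree: dendropy.Tree,
    data: dict[str, np.ndarray],
    model: SubstitutionModel,
) -> dict[str, np.ndarray]:
    """(ncols, k) marginal posterior per internal-node label, averaging over
    gamma categories weighted by their per-column likelihoods."""
    idx = _TreeIndex(tree)
    k = model.n_states
    ncols = next(iter(data.values())).size
    rates = model.rate_categories()
    pi = model.frequencies

    internal = [i for i in range(len(idx.nodes)) if not idx.is_leaf[i]]
    # per category: log joint (state, node, col) up to a per-column constant
    log_joint = {i: [] for i in internal}
    log_colden = []
    for rate in rates:
        partials, logscale, pmats = _pruning_pass(idx, data, model, float(rate))
        outside: list[np.ndarray] = [None] * len(idx.nodes)
        outside[idx.root] = np.tile(pi[:, None], (1, ncols))
        for i in reversed(range(len(idx.nodes))):  # preorder on postorder list
            if idx.is_leaf[i]:
                continue
            children = idx.children[i]
            msgs = [pmats[c] @ partials[c] for c in children]
            for pos, c in enumerate(children):
                rest = outside[i].copy()
                for q, msg in enumerate(msgs):
                    if q != pos:
                        rest *= msg
                outside[c] = pmats[c].T @ rest
        col_lik = np.log((partials[idx.root] * outside[idx.root]).sum(axis=0)) + logscale
        log_colden.append(col_lik)
        for i in internal:
            with np.errstate(divide="ignore"):
                log_joint[i].append(
                    np.log(partials[i] * outside[i]) + logscale[None, :]
                )

    log_colden = np.stack(log_colden)  # (ncat, ncols)
    log_total = logsumexp(log_colden, axis=0)
    out = {}
    for i in internal:
        lj = np.stack(log_joint[i])  # (ncat, k, ncols)
        post = np.exp(logsumexp(lj, axis=0) - log_total[None, :])
        post /= post.sum(axis=0, keepdims=True)
        out[idx.labels[i]] = post.T  # (ncols, k)
    return out


def marginal_posteriors(
    tree: dendropy.Tree, aln: Alignment, model: SubstitutionModel
) -> dict[str, np.ndarray]:
    """Residue posterior distributions, (ncols, 20) per internal node."""
    _require_rooted(tree)
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if leaves != set(aln.rows):
        raise ValueError("tree leaf labels do not match alignment rows")
    data = encode_alignment(aln, model)
    return _marginal_node_posteriors(tree, data, model)


def reconstruct_indels(
    aln: Alignment, tree: dendropy.Tree, gain_loss_rate: float = 1.0
) -> dict[str, np.ndarray]:
    """Presence posterior per internal node from the gap pattern.

    Each column is recoded present/absent and evolved under a two-state
    reversible model with equal equilibrium (0.5/0.5) and flip rate
    ``gain_loss_rate`` per unit branch length.  Columns without any gap carry
    no indel signal and are assigned presence 1 everywhere.
    """
    _require_rooted(tree)
    pa = presence_absence(gain_loss_rate)
    data = {
        label: np.array([0 if c == GAP else 1 for c in seq], dtype=np.int64)
        for label, seq in aln.rows.items()
    }
    posts = _marginal_node_posteriors(tree, data, pa)
    gapless = np.ones(next(iter(data.values())).size, dtype=bool)
    for states in data.values():
        gapless &= states == 1
    out = {}
    for node, p in posts.items():
        pres = p[:, 1].copy()
        pres[gapless] = 1.0
        out[node] = pres
    return out


def reconstruct_ancestors(
    tree: dendropy.Tree,
    aln: Alignment,
    model: SubstitutionModel,
    gain_loss_rate: float = 1.0,
) -> dict[str, AncestralReconstruction]:
    """Full marginal reconstruction (residues + indels) at every internal node."""
    residue = marginal_posteriors(tree, aln, model)
    presence = reconstruct_indels(aln, tree, gain_loss_rate)
    alphabet = model.alphabet
    out = {}
    for node, post in residue.items():
        pres = presence[node]
        chars = []
        chosen_p = []
        for j in range(post.shape[0]):
            if pres[j] >= 0.5:
                best = post[j].max()
                cands = [i for i in range(len(alphabet)) if post[j, i] >= best - 1e-12]
                pick = min(cands, key=lambda i: alphabet[i])
                chars.append(alphabet[pick])
                chosen_p.append(post[j, pick])
            else:
                chars.append(GAP)
        out[node] = AncestralReconstruction(
            node_id=node,
            residue_posteriors=post,
            presence_posterior=pres,
            ml_sequence="".join(chars),
            mean_posterior=float(np.mean(chosen_p)) if chosen_p else float("nan"),
        )
    return out


def extract_ancestor(
    recons: dict[str, AncestralReconstruction],
    tree: dendropy.Tree,
    clade: set[str],
    aln: Alignment | None = None,
) -> AncestralReconstruction:
    """Reconstruction at the most recent common ancestor of the clade.

    The MRCA of a single leaf is that leaf itself; its "reconstruction" is
    degenerate (posterior one at each observed residue, built from the
    alignment row) — callers wanting the leaf's parent must ask for the
    parent's clade explicitly.
    """
    clade = set(clade)
    if not clade:
        raise ValueError("clade must be nonempty")
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = clade - leaves
    if missing:
        raise ValueError(f"clade leaves not in tree: {sorted(missing)}")
    mrca = tree.mrca(taxon_labels=sorted(clade))
    if mrca.is_leaf():
        if aln is None:
            raise ValueError(
                "MRCA of a singleton clade is the leaf itself; pass the "
                "alignment to build its degenerate reconstruction"
            )
        label = mrca.taxon.label
        row = aln.rows[label]
        k = 20
        from .models import AA_ALPHABET

        post = np.zeros((len(row), k))
        pres = np.zeros(len(row))
        for j, c in enumerate(row):
            if c != GAP and c in AA_ALPHABET:
                post[j, AA_ALPHABET.index(c)] = 1.0
                pres[j] = 1.0
        return AncestralReconstruction(
            node_id=label,
            residue_posteriors=post,
            presence_posterior=pres,
            ml_sequence=row,
            mean_posterior=1.0,
        )
    return recons[mrca.label]


def write_ancestors_fasta(recons: dict[str, AncestralReconstruction], path) -> None:
    with open(path, "w") as fh:
        for node, rec in recons.items():
            fh.write(f">{node}\n{rec.ml_sequence}\n")


def write_posterior_tsv(recons: dict[str, AncestralReconstruction],
                        alphabet: str, path, min_prob: float = 0.01) -> None:
    """Long-format TSV (node, column, residue, prob), 1-based columns."""
    with open(path, "w") as fh:
        fh.write("node\tcolumn\tresidue\tprob\n")
        for node, rec in recons.items():
            for j in range(rec.residue_posteriors.shape[0]):
                for i, letter in enumerate(alphabet):
                    p = rec.residue_posteriors[j, i]
                    if p >= min_prob:
                        fh.write(f"{node}\t{j + 1}\t{letter}\t{p:.4f}\n")
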