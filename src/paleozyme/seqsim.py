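"""Synthetic-data generation with known ground truth.

Everything downstream (synteny scan, alignment, tree inference, ancestral
reconstruction, similarity networks, kinetics fitting) is exercised on data
produced here, so each generator retains its generating truth: simulated
protein families keep every ancestral sequence, synthetic genomes know which
species carry the marker genes as neighbours, identity-block families know
their block structure, and progress curves know the rate constants that
produced them.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .kinetics import ProgressCurve, _mm_rate
from .models import AA_ALPHABET, GAP, SubstitutionModel, jtt
from .msa import Alignment
from .phylo import label_internal_nodes

from scipy.integrate import solve_ivp

#: geometric length parameter for indel events (mean length 1/p)
INDEL_LENGTH_P = 0.3


@dataclass
class SimulatedFamily:
    """A protein family evolved along a known tree.

    ``true_ancestors`` maps internal-node labels to ungapped sequences;
    ``ancestor_rows`` holds the same sequences gapped into the leaf
    alignment's coordinate system (the oracle for reconstruction and for
    column bookkeeping).
    """

    tree: dendropy.Tree
    leaf_alignment: Alignment
    true_ancestors: dict[str, str]
    ancestor_rows: dict[str, str]
    seed: int

    def __post_init__(self):
        leaves = {lf.taxon.label for lf in self.tree.leaf_node_iter()}
        if leaves != set(self.leaf_alignment.rows):
            raise ValueError("tree leaves and alignment rows disagree")

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.leaf_alignment.to_fasta(outdir / "leaves.fasta")
        with open(outdir / "ancestors.fasta", "w") as fh:
            for label, seq in self.true_ancestors.items():
                fh.write(f">{label}\n{seq}\n")
        self.tree.write(path=str(outdir / "tree.nwk"), schema="newick")
        with open(outdir / "params.json", "w") as fh:
            json.dump({"seed": self.seed, "n_leaves": len(self.leaf_alignment.rows)}, fh)


@dataclass
class Gene:
    index: int  # 1-based gene-order index on the contig
    name: str
    strand: str  # '+' or '-'
    protein: str


@dataclass
class SyntheticGenome:
    species_id: str
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self):
        idx = [g.index for g in self.genes]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValueError("gene indices must be strictly increasing")


# ---------------------------------------------------------------------------
# trees


def sample_yule_tree(n_taxa: int, birth_rate: float, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) tree with ``n_taxa`` leaves, branch lengths in
    expected substitutions per site.

    The root splits at time zero; each extant lineage splits independently at
    ``birth_rate``; the process is stopped one exponential waiting time after
    the last split, so all pendant branches are positive.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    root = tree.seed_node
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = root.new_child()
        active.append((child, 0.0))
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        k = int(rng.integers(len(active)))
        node, birth = active.pop(k)
        node.edge.length = t - birth
        for _ in range(2):
            active.append((node.new_child(), t))
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for node, birth in active:
        node.edge.length = t - birth
    root.edge.length = None

    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = tns.new_taxon(f"T{i + 1}")
    label_internal_nodes(tree)
    return tree




# ---------------------------------------------------------------------------
# sequence evolution


def _sample_states(rng, states: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Evolve an index vector one branch: states[i] -> draw from p[states[i]]."""
    out = np.empty_like(states)
    cum = np.cumsum(p, axis=1)
    u = rng.random(states.size)
    for s in np.unique(states):
        mask = states == s
        out[mask] = np.searchsorted(cum[s], u[mask], side="right")
    np.clip(out, 0, p.shape[0] - 1, out=out)
    return out


def evolve_alignment(
    tree: dendropy.Tree,
    root_length: int,
    model: SubstitutionModel | None = None,
    indel_rate: float = 0.0,
    seed: int = 0,
) -> SimulatedFamily:
    """Evolve a root sequence down a tree, recording every ancestral sequence.

    The root is drawn from the model's equilibrium frequencies.  On each
    branch of length t, residues substitute via P(t); the expected number of
    indel events is ``indel_rate * t * length``, each an insertion or deletion
    (1:1) of geometric length (p=0.3) at a uniform position.  Insertions open
    fresh alignment columns; deleted columns stay in the coordinate system, so
    the leaf alignment is consistent across lineages.
    """
    if root_length < 1:
        raise ValueError("root_length must be >= 1")
    if indel_rate < 0:
        raise ValueError("indel_rate must be non-negative")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length")
    if model is None:
        model = jtt()
    rng = np.random.default_rng(seed)
    label_internal_nodes(tree)

    k = model.n_states
    pi = model.frequencies
    rates = model.rate_categories()

    next_col = root_length
    master: list[int] = list(range(root_length))
    root_states = rng.choice(k, size=root_length, p=pi)
    # per-site rate category, shared down the whole tree (rates-across-sites)
    site_rates = rng.choice(rates.size, size=root_length)

    # node -> list of (column id, state); site rate travels with the column id
    col_rate: dict[int, int] = {c: site_rates[c] for c in range(root_length)}
    seqs: dict[int, list[tuple[int, int]]] = {
        id(tree.seed_node): list(zip(master, root_states))
    }

    p_cache: dict[tuple[float, int], np.ndarray] = {}

    def p_matrix(t: float, cat: int) -> np.ndarray:
        key = (t, cat)
        if key not in p_cache:
            p_cache[key] = model.transition_matrix(t, rate=float(rates[cat]))
        return p_cache[key]

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[id(node.parent_node)]
        t = node.edge.length or 0.0
        seq = list(parent_seq)

        if t > 0 and seq:
            cols = np.array([c for c, _ in seq])
            states = np.array([s for _, s in seq])
            cats = np.array([col_rate[c] for c in cols])
            new_states = states.copy()
            for cat in np.unique(cats):
                mask = cats == cat
                new_states[mask] = _sample_states(rng, states[mask], p_matrix(t, int(cat)))
            seq = list(zip(cols.tolist(), new_states.tolist()))

        if indel_rate > 0 and t > 0:
            n_events = rng.poisson(indel_rate * t * len(seq))
            for _ in range(n_events):
                if not seq:
                    break
                length = int(rng.geometric(INDEL_LENGTH_P))
                if rng.random() < 0.5:  # deletion
                    start = int(rng.integers(len(seq)))
                    del seq[start : start + length]
                else:  # insertion
                    pos = int(rng.integers(len(seq) + 1))
                    new_ids = list(range(next_col, next_col + length))
                    next_col += length
                    new_states = rng.choice(k, size=length, p=pi)
                    for c in new_ids:
                        col_rate[c] = int(rng.choice(rates.size))
                    if pos > 0:
                        anchor = master.index(seq[pos - 1][0]) + 1
                    else:
                        anchor = master.index(seq[0][0]) if seq else len(master)
                    master[anchor:anchor] = new_ids
                    seq[pos:pos] = list(zip(new_ids, new_states.tolist()))
        seqs[id(node)] = seq

    order = {c: i for i, c in enumerate(master)}
    ncols = len(master)

    def gapped(seq: list[tuple[int, int]]) -> str:
        row = [GAP] * ncols
        for c, s in seq:
            row[order[c]] = model.alphabet[s]
        return "".join(row)

    rows = {
        leaf.taxon.label: gapped(seqs[id(leaf)]) for leaf in tree.leaf_node_iter()
    }
    true_ancestors = {}
    ancestor_rows = {}
    for node in tree.preorder_internal_node_iter():
        label = node.label
        true_ancestors[label] = "".join(model.alphabet[s] for _, s in seqs[id(node)])
        ancestor_rows[label] = gapped(seqs[id(node)])

    return SimulatedFamily(
        tree=tree,
        leaf_alignment=Alignment(rows),
        true_ancestors=true_ancestors,
        ancestor_rows=ancestor_rows,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# genomes


def _random_protein(rng, length: int) -> str:
    return "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, size=length))


def make_genomes(
    families: dict[str, dict[str, str]],
    neighbor_fraction: float,
    decoy_genes: int = 8,
    seed: int = 0,
) -> list[SyntheticGenome]:
    """Synthetic genomes where a controlled fraction of species carry the
    hisA/hisF/hisH markers as strict gene neighbours.

    Exactly ``round(neighbor_fraction * n_species)`` genomes place the three
    markers at consecutive gene-order indices (random internal order, shared
    strand); the rest either scatter them with at least two intervening decoy
    genes or drop one marker entirely.
    """
    for marker in ("hisA", "hisF", "hisH"):
        if marker not in families:
            raise ValueError(f"families must include {marker!r}")
    if not 0.0 <= neighbor_fraction <= 1.0:
        raise ValueError("neighbor_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    species = sorted(families["hisA"])
    n_pass = round(neighbor_fraction * len(species))
    passing = set(list(rng.permutation(species))[:n_pass])

    genomes = []
    markers = ["hisA", "hisF", "hisH"]
    for sp in species:
        decoys = [
            (f"decoy_{i + 1:03d}", _random_protein(rng, 200))
            for i in range(decoy_genes)
        ]
        strand = "+" if rng.random() < 0.5 else "-"
        order = list(rng.permutation(markers))
        slots: list[tuple[str, str, str]] = []  # (name, strand, protein)
        if sp in passing:
            insert_at = int(rng.integers(len(decoys) + 1))
            for i, (name, prot) in enumerate(decoys):
                if i == insert_at:
                    for m in order:
                        slots.append((m, strand, families[m][sp]))
                slots.append((name, "+" if rng.random() < 0.5 else "-", prot))
            if insert_at == len(decoys):
                for m in order:
                    slots.append((m, strand, families[m][sp]))
        else:
            drop = rng.random() < 0.5 or decoy_genes < 5
            if drop:
                kept = order[:2]
                positions = sorted(
                    rng.choice(len(decoys) + 1, size=2, replace=True)
                )
                slots = list(
                    _scatter(decoys, kept, positions, strand, families, sp)
                )
            else:
                # >= 2 intervening decoys between consecutive markers
                gap = max(2, (len(decoys) - 1) // 2)
                positions = [0, gap, 2 * gap]
                slots = list(
                    _scatter(decoys, order, positions, strand, families, sp)
                )
        genes = [
            Gene(index=i + 1, name=name, strand=s, protein=prot)
            for i, (name, s, prot) in enumerate(slots)
        ]
        genomes.append(SyntheticGenome(species_id=sp, genes=genes))
    return genomes


def _scatter(decoys, markers, positions, strand, families, sp):
    """Interleave markers into the decoy backbone at the given decoy offsets."""
    out = []
    pos_iter = list(zip(positions, markers))
    for i, (name, prot) in enumerate(decoys):
        while pos_iter and pos_iter[0][0] == i:
            _, m = pos_iter.pop(0)
            out.append((m, strand, families[m][sp]))
        out.append((name, "+", prot))
    for _, m in pos_iter:
        out.append((m, strand, families[m][sp]))
    return out


# ---------------------------------------------------------------------------
# kinetics curves


def simulate_progress_curves(
    kcat: float,
    km: float,
    E0: float,
    S0_list: list[float],
    ki: float | None = None,
    noise_sd: float = 0.0,
    dt: float = 1.0,
    t_end: float = 600.0,
    seed: int = 0,
) -> list[ProgressCurve]:
    """Noisy product progress curves from numerical integration of the
    Michaelis-Menten rate law (optionally with competitive product
    inhibition)."""
    if min(kcat, km, E0) <= 0 or dt <= 0 or t_end <= 0:
        raise ValueError("kinetic parameters, dt and t_end must be positive")
    if any(s <= 0 for s in S0_list):
        raise ValueError("all S0 must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_end + dt / 2, dt)
    curves = []
    for i, s0 in enumerate(S0_list):
        sol = solve_ivp(
            lambda _, p: _mm_rate(p, kcat, km, E0, s0, ki),
            (0.0, float(times[-1])),
            [0.0],
            t_eval=times,
            rtol=1e-9,
            atol=1e-12,
            method="LSODA",
        )
        product = sol.y[0].copy()
        if noise_sd > 0:
            product[1:] += rng.normal(0.0, noise_sd, size=product.size - 1)
        product[0] = 0.0
        curves.append(
            ProgressCurve(curve_id=f"S0_{s0:g}_{i}", times=times.copy(),
                          product=product, E0=E0, S0=float(s0))
        )
    return curves


def write_progress_curves(curves: list[ProgressCurve], path) -> None:
    """TSV export: curve_id, t_s, P_uM."""
    with open(path, "w") as fh:
        fh.write("curve_id\tt_s\tP_uM\n")
        for c in curves:
            for t, p in zip(c.times, c.product):
                fh.write(f"{c.curve_id}\t{t:g}\t{p:.6g}\n")


# ---------------------------------------------------------------------------
# identity-structured families for network tests


def _identity_to_mutation_prob(identity: float) -> float:
    # pairwise identity of two seqs independently mutated from one ancestor:
    # c = (1-q)^2 + q^2/19  ->  solve for q
    a = 20.0 / 19.0
    disc = 1.0 - a * (1.0 - identity)
    if disc < 0:
        raise ValueError(f"identity {identity} below achievable range")
    return (1.0 - np.sqrt(disc)) / a


def make_family_with_identity(
    n_seqs: int,
    length: int,
    identity_blocks: list[tuple[int, float]],
    seed: int = 0,
) -> dict[str, str]:
    """Sequence blocks with controlled within-block pairwise identity.

    Each block descends from its own random ancestor; every member mutates
    each site independently with the probability that yields the requested
    expected pairwise identity.  Between-block identity stays near the random
    background (~5%).
    """
    if sum(b for b, _ in identity_blocks) != n_seqs:
        raise ValueError("block sizes must sum to n_seqs")
    background = 1.0 / 20.0
    for _, ident in identity_blocks:
        if not background <= ident <= 1.0:
            raise ValueError(
                f"target identity {ident} below background expectation {background}"
            )
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    member = 0
    for b, (size, ident) in enumerate(identity_blocks):
        ancestor = rng.integers(0, 20, size=length)
        q = _identity_to_mutation_prob(ident)
        for _ in range(size):
            member += 1
            seq = ancestor.copy()
            mutate = rng.random(length) < q
            # substitute uniformly among the other 19 residues
            shift = rng.integers(1, 20, size=length)
            seq[mutate] = (seq[mutate] + shift[mutate]) % 20
            seqs[f"B{b + 1}_S{member:03d}"] = "".join(
                AA_ALPHABET[i] for i in seq
            )
    return seqs
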