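"""Sequence similarity networks for enzyme superfamilies.

Pipeline: restrict to full-length sequences (length window), collapse
near-identical sequences (> identity threshold over the shorter sequence,
longest-first greedy clustering) into representative nodes, connect
representatives whose local-alignment E-value passes the cutoff, and report
connected components with cluster identity statistics and taxonomy
composition.

Local alignments are exact Smith-Waterman (affine gaps) and raw scores are
converted to bit scores and E-values with Karlin-Altschul statistics,

    S' = (lambda * S - ln K) / ln 2,      E = m * n * 2^(-S'),

with the published gapped BLOSUM62 parameters (lambda = 0.267, K = 0.041,
gaps 11/1) and the pairwise search space m*n.  Absolute E-values therefore
differ from a database search; thresholds are meaningful relative to one
another (monotone in the raw score), which is what the network construction
uses.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

KA_LAMBDA = 0.267
KA_K = 0.041


def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_GLOBAL = _aligner("global")
_LOCAL = _aligner("local")


def global_identity(a: str, b: str, denominator: str = "shorter") -> float:
    """Percent identity after global alignment.

    ``shorter``: identities / length of the shorter sequence (the greedy-
    clustering convention); ``aligned_columns``: identities / columns with at
    least one residue.
    """
    alignment = _GLOBAL.align(a, b)[0]
    ident = 0
    cols = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        cols += a1 - a0
        for x, y in zip(a[a0:a1], b[b0:b1]):
            if x == y:
                ident += 1
    if denominator == "shorter":
        denom = min(len(a), len(b))
    else:
        # aligned blocks plus gapped stretches (each gap column counts once)
        denom = len(a) + len(b) - cols
    return 100.0 * ident / denom


@dataclass
class SimilarityNetwork:
    """Representative-level network with member bookkeeping and taxonomy."""

    members: dict[str, list[str]]                 # representative -> member ids
    sequences: dict[str, str]                     # representative -> sequence
    taxonomy: dict[str, dict[str, str]] = field(default_factory=dict)
    edges: list[tuple[str, str, float, float, float]] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for rep, mem in self.members.items():
            tax = self.taxonomy.get(rep, {})
            g.add_node(rep, members=len(mem), phylum=tax.get("phylum", ""))
        for i, j, bits, evalue, pid in self.edges:
            g.add_edge(i, j, bitscore=bits, evalue=evalue, pid=pid)
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph(), str(path))

    def write_tsvs(self, node_path, edge_path) -> None:
        with open(node_path, "w") as fh:
            fh.write("representative\tn_members\tmembers\tphylum\n")
            for rep, mem in self.members.items():
                phylum = self.taxonomy.get(rep, {}).get("phylum", "")
                fh.write(f"{rep}\t{len(mem)}\t{','.join(mem)}\t{phylum}\n")
        with open(edge_path, "w") as fh:
            fh.write("source\ttarget\tbitscore\tevalue\tpid\n")
            for i, j, bits, evalue, pid in self.edges:
                fh.write(f"{i}\t{j}\t{bits:.2f}\t{evalue:.3e}\t{pid:.2f}\n")


def _degap(seqs: dict[str, str]) -> dict[str, str]:
    """Networks operate on unaligned sequences; strip alignment gaps."""
    return {k: v.replace("-", "").replace(".", "") for k, v in seqs.items()}


def filter_by_length(seqs: dict[str, str], min_len: int, max_len: int) -> dict[str, str]:
    """Keep sequences with min_len <= length <= max_len (inclusive window,
    the fragment filter)."""
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    return {k: v for k, v in seqs.items() if min_len <= len(v) <= max_len}


def collapse_representatives(
    seqs: dict[str, str], identity_threshold: float = 95.0
) -> dict[str, list[str]]:
    """Greedy incremental clustering, longest sequence first.

    A sequence joins the first (earliest-founded) representative it exceeds
    ``identity_threshold`` percent identity with (strictly greater, identity
    over the shorter sequence after global alignment); otherwise it founds a
    new cluster.  Exact duplicates always merge, so a threshold of 100 still
    collapses identical sequences and nothing else.
    """
    if not 0.0 < identity_threshold <= 100.0:
        raise ValueError("identity_threshold must be in (0, 100]")
    order = sorted(seqs, key=lambda k: (-len(seqs[k]), k))
    reps: list[str] = []
    members: dict[str, list[str]] = {}
    for name in order:
        home = None
        for rep in reps:
            if seqs[name] == seqs[rep] or (
                global_identity(seqs[name], seqs[rep]) > identity_threshold
            ):
                home = rep
                break
        if home is None:
            reps.append(name)
            members[name] = [name]
        else:
            members[home].append(name)
    return members


def karlin_altschul_evalue(
    raw_score: float, m: int, n: int,
    lam: float = KA_LAMBDA, k: float = KA_K,
) -> tuple[float, float]:
    """(bit score, E-value) for a local alignment raw score in search space m*n."""
    if lam <= 0 or k <= 0:
        raise ValueError("Karlin-Altschul parameters must be positive")
    bits = (lam * raw_score - math.log(k)) / math.log(2.0)
    evalue = m * n * 2.0 ** (-bits)
    return bits, evalue


def allbyall_edges(
    representatives: dict[str, str],
    evalue_cutoff: float = 1e-54,
    lam: float = KA_LAMBDA,
    k: float = KA_K,
) -> list[tuple[str, str, float, float, float]]:
    """Edges (i, j, bit score, E-value, percent identity) for every
    representative pair passing the E-value cutoff.  Each pair is aligned
    once; the network is undirected by construction."""
    edges = []
    for a, b in itertools.combinations(sorted(representatives), 2):
        sa, sb = representatives[a], representatives[b]
        raw = _LOCAL.score(sa, sb)
        bits, evalue = karlin_altschul_evalue(raw, len(sa), len(sb), lam, k)
        if evalue <= evalue_cutoff:
            pid = global_identity(sa, sb, denominator="shorter")
            edges.append((a, b, bits, evalue, pid))
    return edges


def build_network(
    seqs: dict[str, str],
    taxonomy: dict[str, dict[str, str]] | None = None,
    min_len: int = 230,
    max_len: int = 260,
    identity_threshold: float = 95.0,
    evalue_cutoff: float = 1e-54,
    length_filter: bool = True,
) -> SimilarityNetwork:
    """Full pipeline: length filter -> representative collapse -> E-value edges."""
    seqs = _degap(seqs)
    kept = filter_by_length(seqs, min_len, max_len) if length_filter else dict(seqs)
    members = collapse_representatives(kept, identity_threshold)
    reps = {r: kept[r] for r in members}
    edges = allbyall_edges(reps, evalue_cutoff)
    tax = {}
    if taxonomy:
        tax = {r: taxonomy.get(r, {}) for r in members}
    return SimilarityNetwork(
        members=members,
        sequences=reps,
        taxonomy=tax,
        edges=edges,
        parameters={
            "min_len": min_len,
            "max_len": max_len,
            "identity_threshold": identity_threshold,
            "evalue_cutoff": evalue_cutoff,
        },
    )


@dataclass
class ComponentStats:
    representatives: list[str]
    member_count: int
    mean_identity: float  # percent; NaN for single-representative components
    sd_identity: float
    taxonomy_composition: dict[str, int]


def components_and_stats(network: SimilarityNetwork) -> list[ComponentStats]:
    """Connected components with within-component identity statistics
    (aligned-columns convention over representative pairs) and taxonomy
    composition; sorted largest first."""
    g = network.graph()
    stats = []
    for comp in nx.connected_components(g):
        reps = sorted(comp)
        pids = [
            global_identity(
                network.sequences[a], network.sequences[b],
                denominator="aligned_columns",
            )
            for a, b in itertools.combinations(reps, 2)
        ]
        composition: dict[str, int] = {}
        for rep in reps:
            phylum = network.taxonomy.get(rep, {}).get("phylum", "")
            if phylum:
                composition[phylum] = composition.get(phylum, 0) + len(
                    network.members[rep]
                )
        stats.append(
            ComponentStats(
                representatives=reps,
                member_count=sum(len(network.members[r]) for r in reps),
                mean_identity=float(np.mean(pids)) if pids else float("nan"),
                sd_identity=float(np.std(pids, ddof=1)) if len(pids) > 1 else float("nan"),
                taxonomy_composition=composition,
            )
        )
    stats.sort(key=lambda s: -s.member_count)
    return stats
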