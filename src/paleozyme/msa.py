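"""Multiple sequence alignment: progressive aligner, gappy-column trimming, identity.

The progressive aligner builds a UPGMA guide tree from 3-mer cosine distances
and merges profiles by global affine-gap profile-profile alignment (expected
BLOSUM62 score between profile columns).  It replaces an external aligner at
desk scale; a pre-computed aligned FASTA can be loaded with
:func:`read_fasta_alignment` instead.

Column trimming implements the single rule "remove a column iff its gap
fraction exceeds the threshold" (default 0.5), keeping a map from retained
columns back to the original coordinates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

from .models import AA_ALPHABET, GAP

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
#: BLOSUM62 restricted to the 20 canonical residues, (20, 20) float array
BLOSUM62 = np.array(
    [[_BLOSUM62[a][b] for b in AA_ALPHABET] for a in AA_ALPHABET], dtype=float
)


@dataclass
class Alignment:
    """Equal-length gapped rows keyed by label, with a column provenance map.

    ``column_map[j]`` is the index of current column ``j`` in the original
    (untrimmed) alignment; the identity map for a freshly built alignment.
    """

    rows: dict[str, str]
    column_map: list[int] = field(default_factory=list)

    def __post_init__(self):
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows must have equal length")
        if not self.column_map:
            self.column_map = list(range(self.ncols))
        if list(self.column_map) != sorted(set(self.column_map)):
            raise ValueError("column_map must be strictly increasing")

    @property
    def ncols(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def labels(self) -> list[str]:
        return list(self.rows)

    def ungapped(self, label: str) -> str:
        return self.rows[label].replace(GAP, "")

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows.values())

    def gap_fraction(self, j: int) -> float:
        col = self.column(j)
        return col.count(GAP) / len(col)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for label, seq in self.rows.items():
                fh.write(f">{label}\n{seq}\n")


def read_fasta_alignment(path) -> Alignment:
    rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not rows:
        raise ValueError(f"no sequences in {path}")
    return Alignment(rows)


def read_fasta(path) -> dict[str, str]:
    """Unaligned FASTA as an ordered label -> sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for label, seq in seqs.items():
            fh.write(f">{label}\n{seq}\n")


# ---------------------------------------------------------------------------
# progressive alignment


def _kmer_profile(seq: str, k: int = 3) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def _cosine_distance(a: dict[str, int], b: dict[str, int]) -> float:
    shared = set(a) & set(b)
    dot = sum(a[k] * b[k] for k in shared)
    na = np.sqrt(sum(v * v for v in a.values()))
    nb = np.sqrt(sum(v * v for v in b.values()))
    if na == 0 or nb == 0:
        return 1.0
    return 1.0 - dot / (na * nb)


def _profile(rows: list[str]) -> np.ndarray:
    """(ncols, 20) residue-frequency profile; gaps excluded from the denominator."""
    idx = {c: i for i, c in enumerate(AA_ALPHABET)}
    ncols = len(rows[0])
    prof = np.zeros((ncols, 20))
    for row in rows:
        for j, c in enumerate(row):
            i = idx.get(c)
            if i is not None:
                prof[j, i] += 1
    denom = prof.sum(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    return prof / denom


def _align_profiles(
    rows_a: list[str],
    rows_b: list[str],
    matrix: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> tuple[list[str], list[str]]:
    """Global affine-gap alignment of two profiles (Gotoh three-state DP).

    A gap of length L costs ``gap_open + (L - 1) * gap_extend`` (both negative).
    Returns the two row blocks with gap columns inserted.
    """
    pa, pb = _profile(rows_a), _profile(rows_b)
    la, lb = pa.shape[0], pb.shape[0]
    score = pa @ matrix @ pb.T  # expected substitution score per column pair

    neg = -np.inf
    m = np.full((la + 1, lb + 1), neg)
    ix = np.full((la + 1, lb + 1), neg)  # gap in B (consumes A)
    iy = np.full((la + 1, lb + 1), neg)  # gap in A (consumes B)
    m[0, 0] = 0.0
    for i in range(1, la + 1):
        ix[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, lb + 1):
        iy[0, j] = gap_open + (j - 1) * gap_extend
    # traceback: 0=M, 1=Ix, 2=Iy
    tb_m = np.zeros((la + 1, lb + 1), dtype=np.int8)
    tb_x = np.zeros((la + 1, lb + 1), dtype=np.int8)
    tb_y = np.zeros((la + 1, lb + 1), dtype=np.int8)
    for i in range(1, la + 1):
        mi1 = m[i - 1]
        xi1 = ix[i - 1]
        yi1 = iy[i - 1]
        si = score[i - 1]
        for j in range(1, lb + 1):
            best = mi1[j - 1]
            state = 0
            if xi1[j - 1] > best:
                best, state = xi1[j - 1], 1
            if yi1[j - 1] > best:
                best, state = yi1[j - 1], 2
            m[i, j] = best + si[j - 1]
            tb_m[i, j] = state

            o = mi1[j] + gap_open
            e = xi1[j] + gap_extend
            if o >= e:
                ix[i, j], tb_x[i, j] = o, 0
            else:
                ix[i, j], tb_x[i, j] = e, 1

            o = m[i, j - 1] + gap_open
            e = iy[i, j - 1] + gap_extend
            if o >= e:
                iy[i, j], tb_y[i, j] = o, 0
            else:
                iy[i, j], tb_y[i, j] = e, 2

    i, j = la, lb
    state = int(np.argmax([m[i, j], ix[i, j], iy[i, j]]))
    ops: list[int] = []
    while i > 0 or j > 0:
        if state == 0:
            prev = tb_m[i, j]
            ops.append(0)
            i, j = i - 1, j - 1
        elif state == 1:
            prev = tb_x[i, j]
            ops.append(1)
            i -= 1
        else:
            prev = tb_y[i, j]
            ops.append(2)
            j -= 1
        state = prev if (i > 0 or j > 0) else 0
    ops.reverse()

    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = jb = 0
    for op in ops:
        if op == 0:
            for r, row in enumerate(rows_a):
                out_a[r] += row[ia]
            for r, row in enumerate(rows_b):
                out_b[r] += row[jb]
            ia += 1
            jb += 1
        elif op == 1:
            for r, row in enumerate(rows_a):
                out_a[r] += row[ia]
            for r in range(len(rows_b)):
                out_b[r] += GAP
            ia += 1
        else:
            for r in range(len(rows_a)):
                out_a[r] += GAP
            for r, row in enumerate(rows_b):
                out_b[r] += row[jb]
            jb += 1
    return out_a, out_b


def progressive_align(
    seqs: dict[str, str],
    matrix: np.ndarray | None = None,
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> Alignment:
    """Progressively align protein sequences along a UPGMA guide tree.

    Guide-tree distances are cosine distances between 3-mer count vectors;
    profile merges use global affine-gap alignment with expected BLOSUM62
    column scores.  Every input residue appears exactly once in its row.
    """
    if matrix is None:
        matrix = BLOSUM62
    labels = list(seqs)
    if len(labels) < 2:
        raise ValueError("progressive_align needs at least 2 sequences")
    for label in labels:
        if not seqs[label]:
            raise ValueError(f"empty sequence for {label!r}")

    if len(labels) == 2:
        a, b = (seqs[label] for label in labels)
        out_a, out_b = _align_profiles([a], [b], matrix, gap_open, gap_extend)
        return Alignment({labels[0]: out_a[0], labels[1]: out_b[0]})

    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    profiles = [_kmer_profile(seqs[label]) for label in labels]
    n = len(labels)
    dmat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        dmat[i, j] = dmat[j, i] = _cosine_distance(profiles[i], profiles[j])
    z = linkage(squareform(dmat, checks=False), method="average")

    # clusters[c] = (ordered labels, aligned row strings)
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([labels[i]], [seqs[labels[i]]]) for i in range(n)
    }
    for step, (ci, cj, _, _) in enumerate(z):
        la, ra = clusters.pop(int(ci))
        lb, rb = clusters.pop(int(cj))
        out_a, out_b = _align_profiles(ra, rb, matrix, gap_open, gap_extend)
        clusters[n + step] = (la + lb, out_a + out_b)
    (_, (merged_labels, merged_rows)) = clusters.popitem()
    ordered = {label: row for label, row in zip(merged_labels, merged_rows)}
    return Alignment({label: ordered[label] for label in labels})


# ---------------------------------------------------------------------------
# trimming and identity


def trim_gappy_columns(
    aln: Alignment, max_gap_frac: float = 0.5, strict: bool = True
) -> Alignment:
    """Drop columns whose gap fraction exceeds ``max_gap_frac``.

    With ``strict`` (default) a column is removed iff gap_fraction >
    max_gap_frac; with ``strict=False`` the rule is >=.  Idempotent.
    """
    if not 0.0 <= max_gap_frac <= 1.0:
        raise ValueError("max_gap_frac must be in [0, 1]")
    keep = []
    for j in range(aln.ncols):
        frac = aln.gap_fraction(j)
        removed = frac > max_gap_frac if strict else frac >= max_gap_frac
        if not removed:
            keep.append(j)
    rows = {
        label: "".join(seq[j] for j in keep) for label, seq in aln.rows.items()
    }
    return Alignment(rows, column_map=[aln.column_map[j] for j in keep])


def trim_report(aln: Alignment, max_gap_frac: float = 0.5) -> list[tuple[int, float, bool]]:
    """(original column, gap fraction, kept) per column, for the trim TSV."""
    return [
        (aln.column_map[j], aln.gap_fraction(j), aln.gap_fraction(j) <= max_gap_frac)
        for j in range(aln.ncols)
    ]


def percent_identity(a: str, b: str, denominator: str = "aligned_columns") -> float:
    """Percent identical residues between two gapped sequences.

    Columns gapped in both sequences are ignored.  ``denominator`` is either
    ``"aligned_columns"`` (columns with at least one residue; requires equal
    lengths) or ``"shorter"`` (ungapped length of the shorter sequence, the
    convention of greedy representative clustering).
    """
    if denominator not in ("aligned_columns", "shorter"):
        raise ValueError("denominator must be 'aligned_columns' or 'shorter'")
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    ident = cols = 0
    for x, y in zip(a, b):
        if x == GAP and y == GAP:
            continue
        cols += 1
        if x == y and x != GAP:
            ident += 1
    if denominator == "aligned_columns":
        denom = cols
    else:
        denom = min(len(a.replace(GAP, "")), len(b.replace(GAP, "")))
    if denom == 0:
        raise ZeroDivisionError("identity denominator is zero")
    return 100.0 * ident / denom
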