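"""Active-site motif mapping, matching and sequence logos.

The bi-functional PriA isomerases are characterised by eight strongly
conserved active-site residues, the motif D-R-E-D-R-G-W-D (residue numbering
on a reference structure; only some slot positions are resolved in print, so
the slot-to-position assignment is configuration).  Structure-anchored
residue positions on a reference row are mapped through the alignment to
columns, motifs are read off any row at those columns, and matched against
the reference motif either strictly or up to residue equivalence classes
(e.g. the basic residues R and K, since a basic residue at the central slot
is what matters for bi-functionality).

Logo heights follow the standard information-content convention:
R = log2(20) - H(column) bits, letter height = frequency * R, with gaps
excluded from the frequencies and no small-sample correction.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field

from .models import GAP
from .msa import Alignment
from .ssn import SimilarityNetwork

PRIA_MOTIF = "DREDRGWD"
#: residue equivalence classes used in 'equivalence' matching mode
DEFAULT_EQUIVALENCE: dict[str, set[str]] = {
    "basic": {"R", "K"},
    "acidic": {"D", "E"},
}


@dataclass
class MotifDefinition:
    """Eight ordered slots of (reference residue, reference position).

    ``positions`` may be None where the residue number on the reference
    structure is unresolved; resolved positions must increase along the
    motif.
    """

    letters: str = PRIA_MOTIF
    positions: list[int | None] = field(default_factory=lambda: [None] * 8)
    equivalence: dict[str, set[str]] = field(
        default_factory=lambda: {k: set(v) for k, v in DEFAULT_EQUIVALENCE.items()}
    )

    def __post_init__(self):
        if len(self.letters) != 8 or len(self.positions) != 8:
            raise ValueError("a motif definition has exactly 8 slots")
        resolved = [p for p in self.positions if p is not None]
        if resolved != sorted(resolved) or len(set(resolved)) != len(resolved):
            raise ValueError("resolved positions must be strictly increasing")

    @classmethod
    def from_json(cls, path) -> "MotifDefinition":
        with open(path) as fh:
            cfg = json.load(fh)
        return cls(
            letters=cfg.get("letters", PRIA_MOTIF),
            positions=cfg.get("positions", [None] * 8),
            equivalence={k: set(v) for k, v in cfg.get("equivalence", DEFAULT_EQUIVALENCE).items()},
        )

    def _same_class(self, a: str, b: str) -> bool:
        return any(a in cls_ and b in cls_ for cls_ in self.equivalence.values())


def map_reference_positions(
    aln: Alignment, reference_row: str, positions: list[int]
) -> list[int]:
    """1-based alignment columns of the given 1-based residue positions on the
    (gapped) reference row."""
    row = aln.rows[reference_row]
    residue_to_col = []
    for col, c in enumerate(row, start=1):
        if c != GAP:
            residue_to_col.append(col)
    out = []
    for pos in positions:
        if not 1 <= pos <= len(residue_to_col):
            raise ValueError(
                f"position {pos} beyond reference length {len(residue_to_col)}"
            )
        out.append(residue_to_col[pos - 1])
    return out


def extract_motif(aln: Alignment, row_label: str, columns: list[int]) -> str:
    """Residues of a row at the mapped 1-based columns, gaps allowed."""
    row = aln.rows[row_label]
    return "".join(row[col - 1] for col in columns)


def match_motif(
    observed: str, reference: MotifDefinition, mode: str = "strict"
) -> tuple[list[bool], int]:
    """Per-slot match flags and total match count (0-8).

    ``strict`` requires identity; ``equivalence`` also accepts residues in
    the same equivalence class.  A gap never matches.
    """
    if len(observed) != 8:
        raise ValueError("observed motif must have 8 letters")
    if mode not in ("strict", "equivalence"):
        raise ValueError("mode must be 'strict' or 'equivalence'")
    flags = []
    for obs, ref in zip(observed.upper(), reference.letters):
        if obs == GAP:
            flags.append(False)
        elif obs == ref:
            flags.append(True)
        elif mode == "equivalence" and reference._same_class(obs, ref):
            flags.append(True)
        else:
            flags.append(False)
    return flags, sum(flags)


def logo_heights(columns: list[str]) -> list[tuple[float, dict[str, float]]]:
    """Information content and letter heights per column.

    Each column is the string of residues observed across the cluster at one
    alignment position.  Returns (R in bits, letter -> height) per column;
    all-gap columns yield (nan, {}).
    """
    max_bits = math.log2(20)
    out = []
    for col in columns:
        residues = [c for c in col.upper() if c != GAP]
        if not residues:
            out.append((float("nan"), {}))
            continue
        counts = Counter(residues)
        n = len(residues)
        entropy = -sum(
            (c / n) * math.log2(c / n) for c in counts.values()
        )
        r = max_bits - entropy
        out.append((r, {letter: (c / n) * r for letter, c in counts.items()}))
    return out


def motif_logo(aln: Alignment, columns: list[int], rows: list[str] | None = None):
    """Logo data for the motif columns restricted to the given rows."""
    rows = rows or aln.labels
    col_strings = [
        "".join(aln.rows[r][col - 1] for r in rows) for col in columns
    ]
    return logo_heights(col_strings)


def write_logo_tsv(logo, path) -> None:
    with open(path, "w") as fh:
        fh.write("slot\tinformation_bits\tletter\theight\n")
        for slot, (r, heights) in enumerate(logo, start=1):
            if not heights:
                fh.write(f"{slot}\t{r:.4f}\t-\t0\n")
            for letter, h in sorted(heights.items(), key=lambda kv: -kv[1]):
                fh.write(f"{slot}\t{r:.4f}\t{letter}\t{h:.4f}\n")


def plot_logo(logo, path) -> None:  # pragma: no cover - plotting
    """Stacked-bar rendering of logo heights (one bar stack per slot)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.0 * len(logo), 3))
    for slot, (_, heights) in enumerate(logo, start=1):
        bottom = 0.0
        for letter, h in sorted(heights.items(), key=lambda kv: kv[1]):
            ax.bar(slot, h, bottom=bottom, width=0.8)
            if h > 0.15:
                ax.text(slot, bottom + h / 2, letter, ha="center", va="center")
            bottom += h
    ax.set_xlabel("motif slot")
    ax.set_ylabel("bits")
    ax.set_ylim(0, math.log2(20))
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def phylum_motif_table(
    network: SimilarityNetwork,
    aln: Alignment,
    motif_def: MotifDefinition,
    columns: list[int],
) -> dict[str, tuple[int, float]]:
    """Per-phylum count and percentage of members carrying the full reference
    motif (8/8 equivalence-mode match).  Phyla without members are omitted."""
    totals: dict[str, int] = {}
    carriers: dict[str, int] = {}
    for rep, members in network.members.items():
        phylum = network.taxonomy.get(rep, {}).get("phylum", "")
        if not phylum:
            continue
        for member in members:
            if member not in aln.rows:
                continue
            totals[phylum] = totals.get(phylum, 0) + 1
            observed = extract_motif(aln, member, columns)
            _, count = match_motif(observed, motif_def, mode="equivalence")
            if count == 8:
                carriers[phylum] = carriers.get(phylum, 0) + 1
    return {
        phylum: (carriers.get(phylum, 0), 100.0 * carriers.get(phylum, 0) / total)
        for phylum, total in totals.items()
    }


def write_motif_table(
    aln: Alignment,
    columns: list[int],
    motif_def: MotifDefinition,
    path,
    taxonomy: dict[str, dict[str, str]] | None = None,
) -> None:
    """TSV of (id, phylum, motif string, strict count, equivalence count)."""
    with open(path, "w") as fh:
        fh.write("id\tphylum\tmotif\tstrict_matches\tequivalence_matches\n")
        for label in aln.labels:
            observed = extract_motif(aln, label, columns)
            _, strict = match_motif(observed, motif_def, "strict")
            _, equiv = match_motif(observed, motif_def, "equivalence")
            phylum = (taxonomy or {}).get(label, {}).get("phylum", "")
            fh.write(f"{label}\t{phylum}\t{observed}\t{strict}\t{equiv}\n")
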