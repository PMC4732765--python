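"""Gene-neighbourhood screening and species-wise concatenation.

Species are retained when the three marker genes (hisA, hisF, hisH by
default) lie on one contig within a gene-order span allowing at most
``max_intervening`` genes between them (strict adjacency by default; strand
agreement is not required unless asked for).  Retained species contribute one
concatenated record, HisF + HisA + HisH, with 1-based inclusive partition
coordinates recording where each gene sits on the concatenation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .seqsim import Gene, SyntheticGenome

logger = logging.getLogger(__name__)

MARKERS = ("hisA", "hisF", "hisH")
CONCAT_ORDER = ("hisF", "hisA", "hisH")


@dataclass
class ConcatenatedRecord:
    """One species' concatenated marker proteins with partition coordinates."""

    species_id: str
    sequence: str
    partitions: list[tuple[str, int, int]]  # (gene, start, end), 1-based inclusive

    def __post_init__(self):
        pos = 1
        for gene, start, end in self.partitions:
            if start != pos or end < start:
                raise ValueError("partitions must tile the sequence without overlap")
            pos = end + 1
        if pos != len(self.sequence) + 1:
            raise ValueError("partitions must cover the full sequence")

    def segment(self, gene: str) -> str:
        for name, start, end in self.partitions:
            if name == gene:
                return self.sequence[start - 1 : end]
        raise KeyError(gene)


def _as_gene_table(genome) -> pd.DataFrame:
    """Normalise a SyntheticGenome or DataFrame to (contig, index, name, strand)."""
    if isinstance(genome, SyntheticGenome):
        return pd.DataFrame(
            {
                "contig": "chr",
                "index": [g.index for g in genome.genes],
                "name": [g.name for g in genome.genes],
                "strand": [g.strand for g in genome.genes],
            }
        )
    df = genome.copy()
    if "contig" not in df:
        df["contig"] = "chr"
    return df[["contig", "index", "name", "strand"]]


def scan_neighbor_triplets(
    genomes: list,
    marker_genes: tuple[str, str, str] = MARKERS,
    max_intervening: int = 0,
    require_same_strand: bool = False,
) -> list[str]:
    """Species whose three markers are gene neighbours.

    Inclusion rule: all three markers on one contig, and the number of genes
    strictly between the outermost markers, ``(max_idx - min_idx + 1) - 3``,
    at most ``max_intervening``.  Internal marker order is unconstrained.
    Species missing a marker are silently excluded; species with a duplicated
    marker are excluded with a warning.  The result is sorted, hence
    independent of genome input order.
    """
    if len(set(marker_genes)) != 3:
        raise ValueError("marker gene names must be three distinct labels")
    if max_intervening < 0:
        raise ValueError("max_intervening must be >= 0")
    passing = []
    for genome in genomes:
        species = (
            genome.species_id
            if isinstance(genome, SyntheticGenome)
            else genome.attrs.get("species_id", "unknown")
        )
        table = _as_gene_table(genome)
        hits = table[table["name"].isin(marker_genes)]
        if hits["name"].duplicated().any():
            logger.warning("species %s has duplicated marker genes; excluded", species)
            continue
        if len(hits) != 3 or hits["contig"].nunique() != 1:
            continue
        span = int(hits["index"].max() - hits["index"].min() + 1)
        if span - 3 > max_intervening:
            continue
        if require_same_strand and hits["strand"].nunique() != 1:
            continue
        passing.append(species)
    return sorted(passing)


def concatenate_species(
    passing: list[str],
    sequences: dict[str, dict[str, str]],
    order: tuple[str, ...] = CONCAT_ORDER,
) -> list[ConcatenatedRecord]:
    """One HisF+HisA+HisH concatenation per passing species."""
    records = []
    for species in passing:
        parts = []
        pos = 1
        chunks = []
        for gene in order:
            try:
                seq = sequences[gene][species]
            except KeyError:
                raise KeyError(f"no {gene} sequence for species {species!r}")
            if not seq:
                raise ValueError(f"zero-length {gene} sequence for {species!r}")
            parts.append((gene, pos, pos + len(seq) - 1))
            pos += len(seq)
            chunks.append(seq)
        records.append(
            ConcatenatedRecord(
                species_id=species, sequence="".join(chunks), partitions=parts
            )
        )
    return records


def split_record(record: ConcatenatedRecord) -> dict[str, str]:
    """Invert a concatenation via its partitions (round-trip with
    concatenate_species)."""
    return {gene: record.segment(gene) for gene, _, _ in record.partitions}


def write_concatenations(records: list[ConcatenatedRecord], fasta_path, partitions_path) -> None:
    with open(fasta_path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.species_id}\n{rec.sequence}\n")
    with open(partitions_path, "w") as fh:
        fh.write("species_id\tgene\tstart\tend\n")
        for rec in records:
            for gene, start, end in rec.partitions:
                fh.write(f"{rec.species_id}\t{gene}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# gene-table input


def read_gene_table_tsv(path, species_id: str | None = None) -> pd.DataFrame:
    """5-column gene table: contig, index, name, strand, protein (TSV)."""
    df = pd.read_csv(path, sep="\t", dtype={"index": int})
    required = {"contig", "index", "name", "strand"}
    if not required <= set(df.columns):
        raise ValueError(f"gene table needs columns {sorted(required)}")
    df.attrs["species_id"] = species_id or str(path)
    return df


def read_gene_table_gff(path, species_id: str | None = None) -> pd.DataFrame:
    """Gene features of a GFF3 file as a gene table (ordered by start per
    contig; gene name from the ``gene=`` attribute, falling back to ID)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        name = feat.attributes.get("gene", feat.attributes.get("ID", ["?"]))[0]
        rows.append((feat.seqid, feat.start, name, feat.strand))
    df = pd.DataFrame(rows, columns=["contig", "start", "name", "strand"])
    df["index"] = df.groupby("contig")["start"].rank(method="first").astype(int)
    df = df[["contig", "index", "name", "strand"]]
    df.attrs["species_id"] = species_id or str(path)
    return df
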