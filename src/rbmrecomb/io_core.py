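"""Data model and text-format I/O for genome collections.

The package works on assembled genomes with pre-called gene coordinates
(FASTA + GFF3; no gene prediction is performed here). Internally all
coordinates are 0-based half-open; GFF3 readers/writers convert at the
boundary so that a GFF -> internal -> GFF round trip is the identity map.

Tabular artifacts (reciprocal best-match tables, ANI matrices, simulation
truth logs) are plain TSV and round-trip losslessly through the matching
reader/writer pair in this module.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
import gffutils
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("rbmrecomb")

SHORT_GENE_FLAG_BP = 100  # genes shorter than this (e.g. contig-edge fragments) are flagged


class GenomeFormatError(ValueError):
    """Malformed FASTA/GFF input (missing contig, out-of-bounds feature, ...)."""


class ConfigError(ValueError):
    """Invalid configuration value."""


class UndefinedANIError(ValueError):
    """ANI requested for a genome pair with no shared (RBM) genes."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRecord:
    """A gene feature with its coding-strand nucleotide sequence.

    ``start``/``end`` are 0-based half-open coordinates on ``contig_id``.
    For minus-strand genes ``sequence`` is the reverse complement of the
    contig slice, so the stored sequence is always coding-strand.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise GenomeFormatError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.end <= self.start:
            raise GenomeFormatError(f"gene {self.gene_id}: end must exceed start")
        if len(self.sequence) != self.end - self.start:
            raise GenomeFormatError(
                f"gene {self.gene_id}: sequence length {len(self.sequence)} "
                f"!= span {self.end - self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """An assembled genome: ordered contigs plus an ordered list of genes.

    Genes are kept sorted by (contig order, start). Overlapping gene spans
    are allowed but flagged with a log message; they occur in real draft
    assemblies and do not break any downstream computation.
    """

    genome_id: str
    contigs: list[tuple[str, str]]
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self):
        lengths = {cid: len(seq) for cid, seq in self.contigs}
        order = {cid: i for i, (cid, _) in enumerate(self.contigs)}
        for g in self.genes:
            if g.contig_id not in lengths:
                raise GenomeFormatError(
                    f"genome {self.genome_id}: gene {g.gene_id} references "
                    f"unknown contig {g.contig_id!r}"
                )
            if g.end > lengths[g.contig_id]:
                raise GenomeFormatError(
                    f"genome {self.genome_id}: gene {g.gene_id} extends beyond "
                    f"contig {g.contig_id} ({g.end} > {lengths[g.contig_id]})"
                )
        self.genes.sort(key=lambda g: (order[g.contig_id], g.start))
        prev_end: dict[str, int] = {}
        n_overlap = n_short = 0
        for g in self.genes:
            if g.start < prev_end.get(g.contig_id, 0):
                n_overlap += 1
            prev_end[g.contig_id] = max(prev_end.get(g.contig_id, 0), g.end)
            if g.length < SHORT_GENE_FLAG_BP:
                n_short += 1
        if n_overlap:
            log.warning("genome %s: %d overlapping gene spans", self.genome_id, n_overlap)
        if n_short:
            log.warning(
                "genome %s: %d genes shorter than %d bp (possible contig-edge fragments)",
                self.genome_id, n_short, SHORT_GENE_FLAG_BP,
            )

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def contig_seq(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(contig_id)

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass(frozen=True)
class RBMPair:
    """A reciprocal best-match gene pair with its alignment statistics.

    ``mismatches`` counts substitution columns plus (internal) gap columns;
    ``identity`` is defined over all alignment columns, so the invariant
    identity == 100 * (aln_len - mismatches) / aln_len always holds.
    Position fields locate the gene on genome A (the reference frame used
    for segment and window analyses).
    """

    gene_a: str
    gene_b: str
    identity: float
    aln_len: int
    mismatches: int
    contig: str
    start_a: int
    end_a: int

    def __post_init__(self):
        expected = 100.0 * (self.aln_len - self.mismatches) / self.aln_len
        if abs(self.identity - expected) > 1e-9:
            raise ValueError(
                f"RBM pair {self.gene_a}/{self.gene_b}: identity {self.identity} "
                f"inconsistent with aln_len={self.aln_len}, mismatches={self.mismatches}"
            )
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity out of [0, 100]")

    @property
    def length_a(self) -> int:
        return self.end_a - self.start_a


@dataclass
class RBMTable:
    """All reciprocal best-match pairs between two genomes.

    Genes of either genome without a reciprocal best match are listed as
    unpaired (accessory with respect to this pair).
    """

    genome_a: str
    genome_b: str
    pairs: list[RBMPair]
    unpaired_a: list[str] = field(default_factory=list)
    unpaired_b: list[str] = field(default_factory=list)

    @property
    def identities(self) -> np.ndarray:
        return np.array([p.identity for p in self.pairs], dtype=float)

    @property
    def aln_lens(self) -> np.ndarray:
        return np.array([p.aln_len for p in self.pairs], dtype=float)

    def pair_for_gene_a(self, gene_id: str) -> RBMPair | None:
        return self._map_a().get(gene_id)

    def pair_for_gene_b(self, gene_id: str) -> RBMPair | None:
        return self._map_b().get(gene_id)

    def _map_a(self) -> dict[str, RBMPair]:
        if not hasattr(self, "_amap"):
            self._amap = {p.gene_a: p for p in self.pairs}
        return self._amap

    def _map_b(self) -> dict[str, RBMPair]:
        if not hasattr(self, "_bmap"):
            self._bmap = {p.gene_b: p for p in self.pairs}
        return self._bmap

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genomeA": self.genome_a,
                "genomeB": self.genome_b,
                "geneA_id": [p.gene_a for p in self.pairs],
                "geneB_id": [p.gene_b for p in self.pairs],
                "identity_pct": [p.identity for p in self.pairs],
                "aln_len": [p.aln_len for p in self.pairs],
                "mismatches": [p.mismatches for p in self.pairs],
                "geneA_start": [p.start_a for p in self.pairs],
                "geneA_end": [p.end_a for p in self.pairs],
                "contig": [p.contig for p in self.pairs],
            }
        )


AnnotationMap = dict[str, str]  # gene_id -> single COG category letter or "unannotated"


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------


def read_genome(fasta_path, gff_path, genome_id: str | None = None) -> Genome:
    """Read a genome assembly (FASTA) and its gene coordinates (GFF3).

    CDS features are used if present, otherwise ``gene`` features. GFF3
    1-based inclusive coordinates are converted to the internal 0-based
    half-open convention; minus-strand gene sequences are stored reverse
    complemented (coding strand).
    """
    fasta_path, gff_path = Path(fasta_path), Path(gff_path)
    contigs = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(fasta_path), "fasta")]
    if not contigs:
        raise GenomeFormatError(f"{fasta_path}: no FASTA records")
    contig_map = dict(contigs)
    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    feats = list(db.features_of_type("CDS")) or list(db.features_of_type("gene"))
    genes = []
    for f in feats:
        if f.seqid not in contig_map:
            raise GenomeFormatError(
                f"{gff_path}: feature {f.id!r} references contig {f.seqid!r} "
                f"absent from {fasta_path.name}"
            )
        start, end = f.start - 1, f.end  # GFF 1-based inclusive -> 0-based half-open
        if start < 0 or end > len(contig_map[f.seqid]):
            raise GenomeFormatError(
                f"{gff_path}: feature {f.id!r} at {f.start}..{f.end} out of bounds "
                f"for contig {f.seqid} (length {len(contig_map[f.seqid])})"
            )
        seq = contig_map[f.seqid][start:end]
        strand = f.strand if f.strand in ("+", "-") else "+"
        if strand == "-":
            seq = reverse_complement(seq)
        gene_id = f.attributes.get("ID", [f.id])[0]
        genes.append(GeneRecord(gene_id, f.seqid, start, end, strand, seq))
    return Genome(genome_id or fasta_path.stem, contigs, genes)


def write_genome_fasta(genome: Genome, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=cid, description=genome.genome_id)
        for cid, seq in genome.contigs
    ]
    SeqIO.write(records, str(path), "fasta")


def write_genes_gff(genome: Genome, path) -> None:
    """Write gene coordinates as GFF3 CDS features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.genes:
            fh.write(
                f"{g.contig_id}\trbmrecomb\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t0\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# RBM tables
# ---------------------------------------------------------------------------

RBM_COLUMNS = [
    "genomeA", "genomeB", "geneA_id", "geneB_id", "identity_pct",
    "aln_len", "mismatches", "geneA_start", "geneA_end", "contig",
]


def write_rbm_table(table: RBMTable, path) -> None:
    """Write an RBM table as TSV. Identity is printed with 2 fixed decimals;
    the exact value is recoverable from the integer aln_len/mismatch columns."""
    with open(path, "w") as fh:
        fh.write("\t".join(RBM_COLUMNS) + "\n")
        for p in table.pairs:
            fh.write(
                f"{table.genome_a}\t{table.genome_b}\t{p.gene_a}\t{p.gene_b}\t"
                f"{p.identity:.2f}\t{p.aln_len}\t{p.mismatches}\t"
                f"{p.start_a}\t{p.end_a}\t{p.contig}\n"
            )


def read_rbm_table(path, genome_a: Genome | None = None,
                   genome_b: Genome | None = None) -> RBMTable:
    """Read an RBM TSV written by :func:`write_rbm_table`.

    Identity is recomputed from aln_len and mismatches so the round trip is
    lossless. If the two genomes are supplied, unpaired gene lists are
    reconstructed.
    """
    df = pd.read_csv(path, sep="\t", dtype={"genomeA": str, "genomeB": str,
                                            "geneA_id": str, "geneB_id": str,
                                            "contig": str})
    if list(df.columns) != RBM_COLUMNS:
        raise GenomeFormatError(f"{path}: unexpected RBM table header")
    if len(df) == 0:
        ga = genome_a.genome_id if genome_a else ""
        gb = genome_b.genome_id if genome_b else ""
        table = RBMTable(ga, gb, [])
    else:
        ga, gb = df["genomeA"].iloc[0], df["genomeB"].iloc[0]
        pairs = [
            RBMPair(
                r.geneA_id, r.geneB_id,
                100.0 * (r.aln_len - r.mismatches) / r.aln_len,
                int(r.aln_len), int(r.mismatches),
                r.contig, int(r.geneA_start), int(r.geneA_end),
            )
            for r in df.itertuples()
        ]
        table = RBMTable(ga, gb, pairs)
    if genome_a is not None:
        paired = {p.gene_a for p in table.pairs}
        table.unpaired_a = [g.gene_id for g in genome_a.genes if g.gene_id not in paired]
    if genome_b is not None:
        paired = {p.gene_b for p in table.pairs}
        table.unpaired_b = [g.gene_id for g in genome_b.genes if g.gene_id not in paired]
    return table


# ---------------------------------------------------------------------------
# annotations, ANI matrices, config
# ---------------------------------------------------------------------------


def read_annotations(path, genome: Genome | None = None) -> AnnotationMap:
    """Read a gene_id -> COG category TSV (two columns, no header required).

    Categories are single letters (COG functional categories) or the literal
    string ``unannotated``.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "category"],
                     dtype=str, comment="#")
    out: AnnotationMap = {}
    for r in df.itertuples():
        cat = r.category.strip()
        if cat != "unannotated" and len(cat) != 1:
            raise GenomeFormatError(
                f"{path}: category {cat!r} for gene {r.gene_id} is not a single "
                "COG letter or 'unannotated'"
            )
        out[r.gene_id] = cat
    if genome is not None:
        known = {g.gene_id for g in genome.genes}
        unknown = set(out) - known
        if unknown:
            raise GenomeFormatError(
                f"{path}: {len(unknown)} annotation keys match no gene "
                f"(e.g. {sorted(unknown)[:3]})"
            )
    return out


def write_ani_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.6f")


def read_ani_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = [str(c) for c in df.columns]
    df.index = [str(i) for i in df.index]
    if list(df.columns) != list(df.index):
        raise GenomeFormatError(f"{path}: ANI matrix is not square/aligned")
    return df


def load_config(path) -> dict:
    """Load a YAML configuration file (thresholds, simulator settings)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return data


def setup_logging(verbose: bool = False, logfile=None) -> None:
    """Log to stderr, optionally duplicating to a file."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    log.setLevel(logging.DEBUG if verbose else logging.INFO)
    log.handlers.clear()
    for h in handlers:
        h.setFormatter(fmt)
        log.addHandler(h)
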