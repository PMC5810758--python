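"""Isoform-resolved gene models built from a genome FASTA and a GTF/GFF annotation.

The design stage needs, per gene, the CDS exon structure of every annotated
isoform: guides are preferentially placed in the first translated exon whose
genomic CDS interval is identical across all isoforms, falling back to the
most 5' CDS exon of the designated primary isoform (the RefSeq "variant 1"
analogue) when no exon is shared.

Coordinates are 1-based closed throughout (GTF convention). CDS exon lists are
kept in translation order: ascending genomic coordinates on the + strand,
descending on the - strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import gffutils
from pyfaidx import Fasta

from ._util import revcomp

Interval = tuple[int, int]


class Genome:
    """Thin strand-aware wrapper over an indexed FASTA.

    ``fetch`` returns the upper-case + strand sequence of a 1-based closed
    interval; ``fetch_oriented`` reverse-complements for - strand queries.
    """

    def __init__(self, path: str):
        self._fasta = Fasta(str(path), sequence_always_upper=True)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fasta

    def chrom_length(self, chrom: str) -> int:
        return len(self._fasta[chrom])

    @property
    def chroms(self) -> list[str]:
        return list(self._fasta.keys())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._fasta:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        if start < 1 or end > len(self._fasta[chrom]) or start > end:
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds"
            )
        return self._fasta[chrom][start - 1 : end].seq

    def fetch_oriented(self, chrom: str, start: int, end: int, strand: str) -> str:
        seq = self.fetch(chrom, start, end)
        return revcomp(seq) if strand == "-" else seq

    def sequence(self, chrom: str) -> str:
        """Whole-chromosome + strand sequence."""
        return str(self._fasta[chrom][:].seq)


@dataclass
class Transcript:
    """One isoform's CDS structure.

    cds_exons are 1-based closed genomic intervals in translation order
    (5'->3' of the mRNA); on the - strand genomic coordinates descend.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    cds_exons: list[Interval]
    is_primary: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        span_sorted = sorted(self.cds_exons)
        for (s1, e1), (s2, e2) in zip(span_sorted, span_sorted[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"{self.transcript_id}: overlapping CDS exons {s1}-{e1}, {s2}-{e2}"
                )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_exons)

    @property
    def frame_ok(self) -> bool:
        """CDS length divisible by 3; kept as a flag, never a hard failure."""
        return self.cds_length % 3 == 0

    def cds_offset(self, genomic_pos: int) -> int:
        """1-based offset of a genomic position within the spliced CDS.

        Strand-aware: offset 1 is the first translated base. Raises
        ``ValueError`` for positions outside every CDS exon.
        """
        walked = 0
        for s, e in self.cds_exons:
            if s <= genomic_pos <= e:
                if self.strand == "+":
                    return walked + (genomic_pos - s) + 1
                return walked + (e - genomic_pos) + 1
            walked += e - s + 1
        raise ValueError(
            f"position {genomic_pos} outside CDS of {self.transcript_id}"
        )

    def genomic_position(self, offset: int) -> int:
        """Inverse of :meth:`cds_offset` (1-based CDS offset -> genomic)."""
        if not 1 <= offset <= self.cds_length:
            raise ValueError(f"offset {offset} outside CDS length {self.cds_length}")
        walked = 0
        for s, e in self.cds_exons:
            n = e - s + 1
            if offset <= walked + n:
                k = offset - walked  # 1-based within exon
                return s + k - 1 if self.strand == "+" else e - k + 1
            walked += n
        raise AssertionError("unreachable")

    def contains(self, genomic_pos: int) -> bool:
        return any(s <= genomic_pos <= e for s, e in self.cds_exons)


@dataclass
class GeneModel:
    gene_id: str
    symbol: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)
    category: str = ""

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: gene without transcripts")
        n_primary = sum(t.is_primary for t in self.transcripts)
        if n_primary != 1:
            raise ValueError(
                f"{self.gene_id}: expected exactly one primary transcript, got {n_primary}"
            )

    @property
    def primary(self) -> Transcript:
        return next(t for t in self.transcripts if t.is_primary)


def shared_cds_exons(gene: GeneModel) -> list[Interval]:
    """CDS exons genomically identical across ALL isoforms of ``gene``.

    Returned in translation order of the primary transcript. A single-isoform
    gene shares all of its exons with itself; genes whose isoforms have no
    identical CDS interval return an empty list.
    """
    exon_sets = [set(t.cds_exons) for t in gene.transcripts]
    common = set.intersection(*exon_sets)
    return [iv for iv in gene.primary.cds_exons if iv in common]


def target_exon_tiers(
    gene: GeneModel, genome: Genome
) -> list[list[tuple[Interval, str]]]:
    """Exon tiers to scan for guides, each as (interval, oriented sequence).

    Tier 0: exons shared by all isoforms, in translation order. Tier 1: the
    primary transcript's CDS exons 5'->3' (the fallback when no shared exon
    exists or selection cannot be satisfied on the shared set). Sequences are
    strand-oriented (the guide-design scanner re-orients internally).
    """
    primary = gene.primary
    if primary.cds_length == 0:
        raise ValueError(f"{gene.gene_id}: primary transcript has zero CDS")
    shared = shared_cds_exons(gene)
    tiers: list[list[tuple[Interval, str]]] = []
    tiers.append(
        [
            (iv, genome.fetch_oriented(gene.chrom, min(iv), max(iv), gene.strand))
            for iv in shared
        ]
    )
    fallback = [iv for iv in primary.cds_exons if iv not in set(shared)]
    tiers.append(
        [
            (iv, genome.fetch_oriented(gene.chrom, min(iv), max(iv), gene.strand))
            for iv in fallback
        ]
    )
    return tiers


def load_annotation(
    annotation_path: str,
    genome_path: str,
    *,
    gene_id_key: str = "gene_id",
    transcript_id_key: str = "transcript_id",
    symbol_key: str = "gene_name",
    primary_key: str = "primary",
    category_key: str = "gene_category",
) -> tuple[dict[str, GeneModel], Genome]:
    """Load a GTF/GFF annotation and its genome into gene models.

    The primary isoform is the transcript whose ``primary_key`` attribute is
    "1"/"true"/"yes"; if a gene flags none, the lexicographically first
    transcript id is designated primary with a warning. Transcripts without
    CDS features are dropped with a warning; an annotation referencing a
    chromosome absent from the genome is a hard error.
    """
    genome = Genome(genome_path)
    db = gffutils.create_db(
        str(annotation_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    # transcript_id -> accumulated CDS pieces
    tx_cds: dict[str, dict] = {}
    for feat in db.features_of_type("CDS"):
        tid = feat.attributes[transcript_id_key][0]
        rec = tx_cds.setdefault(
            tid,
            {
                "gene_id": feat.attributes[gene_id_key][0],
                "chrom": feat.seqid,
                "strand": feat.strand,
                "exons": [],
                "symbol": (feat.attributes.get(symbol_key) or [""])[0],
                "primary": _truthy((feat.attributes.get(primary_key) or [""])[0]),
                "category": (feat.attributes.get(category_key) or [""])[0],
            },
        )
        rec["exons"].append((feat.start, feat.end))
        if feat.seqid not in genome:
            raise KeyError(
                f"annotation references chromosome {feat.seqid!r} absent from genome"
            )

    # warn about transcript features that carry no CDS
    try:
        for feat in db.features_of_type("transcript"):
            tid = feat.attributes[transcript_id_key][0]
            if tid not in tx_cds:
                warnings.warn(f"transcript {tid} has no CDS; dropped", stacklevel=2)
    except gffutils.exceptions.FeatureNotFoundError:  # pragma: no cover
        pass

    by_gene: dict[str, list[Transcript]] = {}
    meta: dict[str, dict] = {}
    for tid, rec in tx_cds.items():
        exons = sorted(rec["exons"])
        for s, e in exons:
            if e > genome.chrom_length(rec["chrom"]):
                raise ValueError(
                    f"CDS {rec['chrom']}:{s}-{e} of {tid} exceeds chromosome length"
                )
        if rec["strand"] == "-":
            exons = exons[::-1]
        tx = Transcript(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            cds_exons=exons,
            is_primary=rec["primary"],
        )
        if not tx.frame_ok:
            warnings.warn(
                f"transcript {tid}: CDS length {tx.cds_length} not divisible by 3",
                stacklevel=2,
            )
        by_gene.setdefault(rec["gene_id"], []).append(tx)
        meta.setdefault(
            rec["gene_id"],
            {
                "symbol": rec["symbol"],
                "chrom": rec["chrom"],
                "strand": rec["strand"],
                "category": rec["category"],
            },
        )

    genes: dict[str, GeneModel] = {}
    for gid, txs in by_gene.items():
        txs = sorted(txs, key=lambda t: t.transcript_id)
        if not any(t.is_primary for t in txs):
            warnings.warn(
                f"gene {gid}: no transcript flagged primary; using {txs[0].transcript_id}",
                stacklevel=2,
            )
            txs[0].is_primary = True
        genes[gid] = GeneModel(
            gene_id=gid,
            symbol=meta[gid]["symbol"] or gid,
            chrom=meta[gid]["chrom"],
            strand=meta[gid]["strand"],
            transcripts=txs,
            category=meta[gid]["category"],
        )
    return genes, genome


def _truthy(value: str) -> bool:
    return str(value).strip().lower() in {"1", "true", "yes"}


def iter_genes(genes: dict[str, GeneModel]) -> Iterator[GeneModel]:
    """Genes in deterministic (gene_id) order."""
    for gid in sorted(genes):
        yield genes[gid]
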