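"""Synthetic study inputs with recorded ground truth.

Emulates the full experimental design end to end so every pipeline stage is
testable without external data: a multi-isoform annotation with shared and
unshared CDS exons over a guide-dense genome, per-guide pool abundances read
out as amplicon FASTQ, and target-enrichment SAM alignments carrying in/dels
at guide cut sites at chosen rates, alongside an untransduced control sharing
planted background events.

Every gene locus is built in transcript orientation as

    pad - exon1 - intron - exon2 (target) - intron - exon3 - pad

with NGG "PAM blocks" (random 20-mer + NGG) planted in each exon so
designability is guaranteed by construction, then placed on the genome on a
per-gene strand. The primary isoform uses all three exons; a second isoform
either trims only exon 1 (leaving exons 2-3 shared, so the designer targets
exon 2) or trims every exon (no shared exon, exercising the primary-variant
fallback tier). External "imported" guides are drawn from exon 3, genomically
disjoint from the designed set.

All randomness flows from a single seed; the same config emits byte-identical
files. Every 20-mer in the genome is unique (enforced by rejection during
construction) unless duplicate protospacer copies are explicitly planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from ._util import revcomp
from .annotation import Genome

READ_LEN = 150
#: constant amplicon flanks around the protospacer in pool-representation reads
POOL_FLANK_5 = "TATCTTGTGGAAAGGACG"
POOL_FLANK_3 = "GTTTTAGAGCTAGAAATA"

# locus geometry (transcript-local, 1-based); lengths keep CDS % 3 == 0
_PAM_BLOCK = 23
_N_BLOCKS = {"exon1": 8, "exon2": 10, "exon3": 4}
_EXON_PAD = {"exon1": 2, "exon2": 1, "exon3": 1}
_INTRON = 40
_LOCUS_PAD = 30
_SPACER = 60
_CHROM_LEAD = 100
_CHROM_TAIL = 300

#: background deletion planted in both edited and control samples; length 23
#: so its event key can never collide with a simulated edit (del <= 20, ins <= 10)
_BG_DEL_LEN = 23


@dataclass
class SimConfig:
    """Knobs of the simulated study.

    Defaults mirror the emulated design: 450 genes, 7 guides per gene,
    a tenth of genes without a shared exon, uniform pool abundance sequenced
    to 1e5 reads, and two replicates of 500 read pairs per validated site.
    """

    seed: int = 0
    n_genes: int = 450
    n_chroms: int = 8
    frac_no_shared_exon: float = 0.10
    pool_abundance_model: str = "uniform"  # or "lognormal"
    pool_sigma: float = 0.5
    read_depth: int = 100_000
    n_read_pairs_per_site: int = 500
    edit_rates: dict | float = 0.3
    background_indel_rate: float = 0.02
    frac_duplicates: float = 0.05
    frac_lowmapq: float = 0.05
    zero_abundance_guides: tuple = ()
    planted_duplicate_copies: int = 0

    def __post_init__(self) -> None:
        for r in (self.frac_no_shared_exon, self.background_indel_rate,
                  self.frac_duplicates, self.frac_lowmapq):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class SimulatedInputs:
    """Paths of the emitted design inputs plus per-gene ground truth."""

    fasta_path: str
    gtf_path: str
    external_path: str
    predicted_path: str
    truth: dict = field(default_factory=dict)  # gene_id -> dict


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _pam_block(rng: np.random.Generator) -> tuple[str, str]:
    """(block sequence, protospacer) for one planted NGG site."""
    proto = _rand_seq(rng, 20)
    pam = "ACGT"[rng.integers(0, 4)] + "GG"
    return proto + pam, proto


class _UniqueKmers:
    """Rejection helper guaranteeing genome-wide 20-mer uniqueness."""

    K = 20

    def __init__(self) -> None:
        self.seen: set[str] = set()

    def admissible(self, fragment: str, context: str) -> bool:
        s = context[-(self.K - 1):] + fragment
        kmers = {s[i : i + self.K] for i in range(len(s) - self.K + 1)}
        if len(kmers) < len(s) - self.K + 1:
            return False  # internal duplicate
        return not (kmers & self.seen)

    def commit(self, fragment: str, context: str) -> None:
        s = context[-(self.K - 1):] + fragment
        for i in range(len(s) - self.K + 1):
            self.seen.add(s[i : i + self.K])


def _build_locus(rng: np.random.Generator, shared: bool) -> dict:
    """One gene locus in transcript orientation with local exon coordinates."""
    parts: list[str] = []
    pos = 0

    def _append(s: str) -> tuple[int, int]:
        nonlocal pos
        start = pos + 1
        parts.append(s)
        pos += len(s)
        return (start, pos)

    _append(_rand_seq(rng, _LOCUS_PAD))
    exons: dict[str, tuple[int, int]] = {}
    planted: dict[str, list[dict]] = {}
    for name in ("exon1", "exon2", "exon3"):
        blocks = []
        protos = []
        for _ in range(_N_BLOCKS[name]):
            block, proto = _pam_block(rng)
            blocks.append(block)
            protos.append(proto)
        seq = "".join(blocks) + _rand_seq(rng, _EXON_PAD[name])
        start, end = _append(seq)
        exons[name] = (start, end)
        planted[name] = [
            {
                "protospacer": protos[i],
                "local_start": start + i * _PAM_BLOCK,
                "local_end": start + i * _PAM_BLOCK + 19,
            }
            for i in range(_N_BLOCKS[name])
        ]
        if name != "exon3":
            _append(_rand_seq(rng, _INTRON))
    _append(_rand_seq(rng, _LOCUS_PAD))

    # second isoform: trim exon starts so trimmed exons are distinct intervals
    iso_b = {}
    for name, (s, e) in exons.items():
        if name == "exon1" or not shared:
            iso_b[name] = (s + 3, e)
        else:
            iso_b[name] = (s, e)
    return {
        "sequence": "".join(parts),
        "length": pos,
        "exons_primary": exons,
        "exons_alt": iso_b,
        "planted": planted,
        "shared": shared,
    }


def _to_genomic(local: tuple[int, int], gstart: int, llen: int, strand: str):
    a, b = local
    if strand == "+":
        return (gstart + a - 1, gstart + b - 1)
    return (gstart + llen - b, gstart + llen - a)


def simulate_genome(config: SimConfig, out_dir: str) -> SimulatedInputs:
    """Emit FASTA + GTF + external-guide TSV + predicted-score TSV.

    Raises before emission if the locus geometry cannot guarantee at least
    5 + 3 designable NGG sites in every target exon (it can by construction;
    the check guards future geometry edits).
    """
    if config.n_genes < 1:
        raise ValueError("need at least one gene")
    if _N_BLOCKS["exon1"] < 8 or _N_BLOCKS["exon2"] < 8:
        raise ValueError("PAM density too low to guarantee designability")
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    n_fallback = int(round(config.frac_no_shared_exon * config.n_genes))
    shared_flags = np.array(
        [False] * n_fallback + [True] * (config.n_genes - n_fallback)
    )
    rng.shuffle(shared_flags)

    uniq = _UniqueKmers()
    chrom_seqs = {f"chr{i + 1}": "" for i in range(config.n_chroms)}
    for c in chrom_seqs:
        lead = _rand_seq(rng, _CHROM_LEAD)
        while not uniq.admissible(lead, ""):
            lead = _rand_seq(rng, _CHROM_LEAD)  # pragma: no cover
        uniq.commit(lead, "")
        chrom_seqs[c] = lead

    truth: dict = {}
    gtf_lines: list[str] = []
    ext_rows: list[dict] = []
    planted_protos: list[str] = []

    for gi in range(config.n_genes):
        gid = f"G{gi + 1:04d}"
        chrom = f"chr{gi % config.n_chroms + 1}"
        strand = "+" if gi % 2 == 0 else "-"
        shared = bool(shared_flags[gi])

        for _ in range(200):
            locus = _build_locus(rng, shared)
            spacer = _rand_seq(rng, _SPACER)
            oriented = (
                locus["sequence"] if strand == "+" else revcomp(locus["sequence"])
            )
            fragment = spacer + oriented
            if uniq.admissible(fragment, chrom_seqs[chrom]):
                break
        else:  # pragma: no cover
            raise RuntimeError(f"could not place unique locus for {gid}")
        uniq.commit(fragment, chrom_seqs[chrom])
        gstart = len(chrom_seqs[chrom]) + len(spacer) + 1
        chrom_seqs[chrom] += fragment
        llen = locus["length"]

        exons_g, exons_alt_g = {}, {}
        for name in ("exon1", "exon2", "exon3"):
            exons_g[name] = _to_genomic(
                locus["exons_primary"][name], gstart, llen, strand
            )
            exons_alt_g[name] = _to_genomic(
                locus["exons_alt"][name], gstart, llen, strand
            )
        for tid, exmap, primary in (
            (f"{gid}.tA", exons_g, True),
            (f"{gid}.tB", exons_alt_g, False),
        ):
            for name in ("exon1", "exon2", "exon3"):
                s, e = exmap[name]
                attrs = (
                    f'gene_id "{gid}"; transcript_id "{tid}"; '
                    f'gene_name "{gid}"; primary "{1 if primary else 0}";'
                )
                gtf_lines.append(
                    f"{chrom}\tsim\tCDS\t{s}\t{e}\t.\t{strand}\t0\t{attrs}"
                )

        planted_g = {}
        for name in ("exon1", "exon2", "exon3"):
            sites = []
            for site in locus["planted"][name]:
                gs, ge = _to_genomic(
                    (site["local_start"], site["local_end"]), gstart, llen, strand
                )
                sites.append(
                    {"protospacer": site["protospacer"], "start": gs, "end": ge}
                )
                planted_protos.append(site["protospacer"])
            planted_g[name] = sites

        # external (imported) guides: exon3 blocks 2-4, priority ordered
        for pr, site in enumerate(planted_g["exon3"][1:4], start=1):
            ext_rows.append(
                {
                    "gene_id": gid,
                    "protospacer": site["protospacer"],
                    "chrom": chrom,
                    "strand": strand,
                    "start": site["start"],
                    "end": site["end"],
                    "priority": pr,
                }
            )

        truth[gid] = {
            "chrom": chrom,
            "strand": strand,
            "shared": shared,
            "target_exon": list(exons_g["exon2"] if shared else exons_g["exon1"]),
            "exons_primary": {k: list(v) for k, v in exons_g.items()},
            "planted": planted_g,
        }

    for c in chrom_seqs:
        chrom_seqs[c] += _rand_seq(rng, _CHROM_TAIL)

    if config.planted_duplicate_copies > 0:
        dup = truth["G0001"]["planted"]["exon2"][0]["protospacer"]
        extra = "".join(
            _rand_seq(rng, 10) + dup + "AGG" + _rand_seq(rng, 10)
            for _ in range(config.planted_duplicate_copies)
        )
        chrom_seqs["chr1"] += extra
        truth["__planted_duplicate__"] = dup

    fasta_path = out / "genome.fa"
    with open(fasta_path, "w") as fh:
        for c, seq in chrom_seqs.items():
            fh.write(f">{c}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    gtf_path = out / "annotation.gtf"
    with open(gtf_path, "w") as fh:
        fh.write("\n".join(gtf_lines) + "\n")
    ext_path = out / "external_guides.tsv"
    pd.DataFrame(ext_rows).to_csv(ext_path, sep="\t", index=False)

    # RS2-like predicted activity in the published range for every planted
    # protospacer (incidental NGG sites carry no prediction)
    pred = pd.DataFrame(
        {
            "protospacer": planted_protos,
            "score": np.round(rng.uniform(0.04, 0.81, size=len(planted_protos)), 3),
        }
    )
    pred_path = out / "predicted_activity.tsv"
    pred.to_csv(pred_path, sep="\t", index=False)

    return SimulatedInputs(
        fasta_path=str(fasta_path),
        gtf_path=str(gtf_path),
        external_path=str(ext_path),
        predicted_path=str(pred_path),
        truth=truth,
    )


def write_truth(inputs: SimulatedInputs, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(inputs.truth, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# pool representation reads


def simulate_pool_reads(
    library_table: pd.DataFrame, config: SimConfig, out_fastq: str
) -> pd.DataFrame:
    """Amplicon FASTQ of the pooled library plus the true count table.

    Per-guide abundances are uniform or log-normal(sigma); reads are
    multinomial draws of ``read_depth`` with structure
    flank + protospacer + flank. Guides listed in
    ``zero_abundance_guides`` receive probability zero (undetected).
    """
    rng = np.random.default_rng(config.seed + 1)
    guides = list(library_table["guide_id"])
    protos = list(library_table["protospacer"])
    if config.pool_abundance_model == "uniform":
        w = np.ones(len(guides))
    elif config.pool_abundance_model == "lognormal":
        w = np.exp(rng.normal(0.0, config.pool_sigma, size=len(guides)))
    else:
        raise ValueError(f"unknown abundance model {config.pool_abundance_model!r}")
    zero = set(config.zero_abundance_guides)
    for i, g in enumerate(guides):
        if g in zero:
            w[i] = 0.0
    p = w / w.sum()
    counts = rng.multinomial(config.read_depth, p)

    with open(out_fastq, "w") as fh:
        for gid, proto, n in zip(guides, protos, counts):
            seq = POOL_FLANK_5 + proto + POOL_FLANK_3
            qual = "I" * len(seq)
            for k in range(n):
                fh.write(f"@{gid}:{k}\n{seq}\n+\n{qual}\n")
    return pd.DataFrame({"guide_id": guides, "true_count": counts})


# ---------------------------------------------------------------------------
# edited / control alignments


def _edit_rate(config: SimConfig, guide_id: str) -> float:
    if isinstance(config.edit_rates, dict):
        return float(config.edit_rates.get(guide_id, 0.0))
    return float(config.edit_rates)


def simulate_editing(
    sites_table: pd.DataFrame,
    genome: Genome,
    config: SimConfig,
    out_dir: str,
    n_replicates: int = 2,
) -> dict:
    """Edited SAMs (one per replicate) + untransduced-control SAM + truth.

    For every target site, ``n_read_pairs_per_site`` pairs spanning the cut
    are emitted per replicate. With probability edit_rate the pair's first
    read carries a CIGAR-encoded in/del (deletion 1-20 nt or insertion
    1-10 nt at cut_site +/- 2) and the pair is flagged non-proper; unedited
    pairs are proper with gapless CIGARs. A fixed per-site background
    deletion (length 23, so never key-identical to an edit) appears in both
    the edited and control samples at ``background_indel_rate``. Duplicate
    flags and MAPQ values {20, 37} are planted at configured fractions on
    edited reads to exercise the downstream filters.

    Returns {"edited": [paths], "control": path, "truth": DataFrame} where
    the truth has one row per read pair with its planted event and flags.
    """
    rng = np.random.default_rng(config.seed + 2)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chroms = genome.chroms
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": genome.chrom_length(c)} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}

    truth_rows: list[dict] = []
    edited_paths: list[str] = []

    def _pair(
        fh, name, chrom, s1, cigar1, seq1, flag1, mapq1, s2, seq2, flag2
    ) -> None:
        a = pysam.AlignedSegment()
        a.query_name = name
        a.reference_id = tid[chrom]
        a.reference_start = s1 - 1
        a.cigarstring = cigar1
        a.query_sequence = seq1
        a.flag = flag1
        a.mapping_quality = mapq1
        a.next_reference_id = tid[chrom]
        a.next_reference_start = s2 - 1
        fh.write(a)
        b = pysam.AlignedSegment()
        b.query_name = name
        b.reference_id = tid[chrom]
        b.reference_start = s2 - 1
        b.cigarstring = f"{READ_LEN}M"
        b.query_sequence = seq2
        b.flag = flag2
        b.mapping_quality = mapq1
        b.next_reference_id = tid[chrom]
        b.next_reference_start = s1 - 1
        fh.write(b)

    def _emit_sample(path: str, replicate: int | None) -> None:
        """replicate=None emits the untransduced control."""
        with pysam.AlignmentFile(path, "w", header=header) as fh:
            for row in sites_table.itertuples(index=False):
                cut = int(row.cut_site)
                chrom = row.chrom
                rate = 0.0 if replicate is None else _edit_rate(config, row.guide_id)
                s1 = cut - READ_LEN // 2
                s2 = s1 + READ_LEN + 10
                ref1 = genome.fetch(chrom, s1, s1 + READ_LEN - 1)
                ref2 = genome.fetch(chrom, s2, s2 + READ_LEN - 1)
                bg_pos = cut - 2
                for k in range(config.n_read_pairs_per_site):
                    name = (
                        f"{row.guide_id}:r{replicate if replicate is not None else 'C'}:{k}"
                    )
                    u = rng.random()
                    edited = u < rate
                    background = (not edited) and (
                        rng.random() < config.background_indel_rate
                    )
                    if (
                        replicate is None
                        and k == 0
                        and config.background_indel_rate > 0
                    ):
                        # the control always witnesses each planted background
                        # key so subtraction is exact, not sampling-dependent
                        edited, background = False, True
                    mapq = 60
                    dup = False
                    event = None
                    if edited:
                        if rng.random() < config.frac_lowmapq:
                            mapq = int(rng.choice([20, 37]))
                        if rng.random() < config.frac_duplicates:
                            dup = True
                        jitter = int(rng.integers(-2, 3))
                        if rng.random() < 0.5:
                            ev_len = int(rng.integers(1, 21))
                            event = ("deletion", cut + jitter, ev_len)
                        else:
                            ev_len = int(rng.integers(1, 11))
                            event = ("insertion", cut + jitter, ev_len)
                    elif background:
                        event = ("deletion", bg_pos, _BG_DEL_LEN)

                    if event is None:
                        _pair(
                            fh, name, chrom, s1, f"{READ_LEN}M", ref1,
                            0x1 | 0x2 | 0x20 | 0x40, 60, s2, ref2,
                            0x1 | 0x2 | 0x10 | 0x80,
                        )
                    else:
                        etype, epos, elen = event
                        if etype == "deletion":
                            pre = epos - s1
                            post = READ_LEN - pre
                            cigar = f"{pre}M{elen}D{post}M"
                            seq = genome.fetch(chrom, s1, epos - 1) + genome.fetch(
                                chrom, epos + elen, epos + elen + post - 1
                            )
                        else:
                            pre = epos - s1 + 1
                            post = READ_LEN - pre - elen
                            cigar = f"{pre}M{elen}I{post}M"
                            seq = (
                                genome.fetch(chrom, s1, epos)
                                + _rand_seq(rng, elen)
                                + genome.fetch(chrom, epos + 1, epos + post)
                            )
                        flag1 = 0x1 | 0x20 | 0x40 | (0x400 if dup else 0)
                        _pair(
                            fh, name, chrom, s1, cigar, seq, flag1, mapq,
                            s2, ref2, 0x1 | 0x10 | 0x80,
                        )
                    if replicate is not None:
                        truth_rows.append(
                            {
                                "guide_id": row.guide_id,
                                "replicate": replicate,
                                "read_name": name,
                                "edited": edited,
                                "background": background,
                                "event_type": event[0] if event else "",
                                "event_pos": event[1] if event else -1,
                                "event_len": event[2] if event else 0,
                                "mapq": mapq,
                                "duplicate": dup,
                            }
                        )

    for rep in range(1, n_replicates + 1):
        path = str(out / f"edited_rep{rep}.sam")
        _emit_sample(path, rep)
        edited_paths.append(path)
    control_path = str(out / "control.sam")
    _emit_sample(control_path, None)

    return {
        "edited": edited_paths,
        "control": control_path,
        "truth": pd.DataFrame(truth_rows),
    }
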