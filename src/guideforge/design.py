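"""sgRNA enumeration, scoring and tiered selection for SpCas9 (NGG) knockouts.

Per gene the designer emits up to five "designed" guides (groups 1-5) picked
from the first CDS exon shared by all isoforms — or, failing that, from the
5'-most exons of the primary isoform — plus up to two "imported" guides
(groups 6-7) taken from an externally supplied list under an overlap
constraint. Selection prefers guides with a specificity score of at least 70,
admits scores in [50, 70) as backups, and tries to keep at least three of the
selected guides mutually non-overlapping so that independent cut sites exist
for each gene.

Protospacers are stored as the 20-mer genomic target without the vector's
5' G; the cloning layer prepends nothing either (the expression vector
supplies the G during Golden Gate assembly).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import encode_seq, gc_fraction, overlap_bp, revcomp
from .annotation import GeneModel, Genome, Interval, target_exon_tiers

PROTOSPACER_LEN = 20
#: scission sits between protospacer positions 17 and 18; the cut-site
#: coordinate is position 17, i.e. 6 nt upstream of the end of guide+PAM
CUT_OFFSET_FROM_PAM = 6

_PLUS_SITE = re.compile(r"(?=([ACGTN]{21}GG))")
_MINUS_SITE = re.compile(r"(?=(CC[ACGTN]{21}))")


@dataclass
class DesignParams:
    """Tunable thresholds of the tiered selection policy."""

    score_threshold: float = 70.0
    backup_threshold: float = 50.0
    gc_band: tuple[float, float] = (0.35, 0.70)
    n_designed_per_gene: int = 5
    n_imported_per_gene: int = 2
    min_nonoverlapping_designed: int = 3
    imported_overlap_limit_bp: int = 15
    predicted_activity_flag_threshold: float = 0.4

    def __post_init__(self) -> None:
        if self.backup_threshold > self.score_threshold:
            raise ValueError("backup_threshold must be <= score_threshold")
        if not (0 <= self.backup_threshold and self.score_threshold <= 100):
            raise ValueError("score thresholds must lie in [0, 100]")


@dataclass
class GuideCandidate:
    """A 20-mer protospacer with NGG PAM, in guide (5'->3') orientation."""

    protospacer: str
    pam: str
    chrom: str
    strand: str
    start: int  # protospacer genomic span, 1-based closed
    end: int
    gene_id: str = ""
    gc_fraction: float = 0.0
    specificity_score: float | None = None
    predicted_activity: float | None = None
    peptide_remaining_pct: float | None = None
    group: int | None = None
    tier: int | None = None
    exon: Interval | None = None
    source: str = "designed"

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam) != 3 or self.pam[1:] != "GG":
            raise ValueError(f"PAM {self.pam!r} is not NGG")
        if self.group is not None and not 1 <= self.group <= 7:
            raise ValueError("group must be in 1..7")
        self.gc_fraction = gc_fraction(self.protospacer)

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def cut_site(self) -> int:
        return cut_site(self)

    @property
    def disruption_site(self) -> int:
        """Genomic coordinate of the final protospacer base before the PAM."""
        return self.end if self.strand == "+" else self.start


def cut_site(candidate: GuideCandidate) -> int:
    """Blunt-scission coordinate: 6 nt upstream of the end of guide+PAM.

    Equals protospacer position 17 in guide orientation; the double-strand
    break falls between this base and the next one toward the PAM.
    """
    if candidate.strand == "+":
        return candidate.end - 3
    return candidate.start + 3


def scan_pams(
    exon_sequence: str,
    exon_interval: Interval,
    strand_of_sequence: str,
    *,
    chrom: str = "",
    gene_id: str = "",
) -> tuple[list[GuideCandidate], int]:
    """Enumerate every NGG site on both genomic strands within an exon window.

    ``exon_sequence`` is the oriented sequence of ``exon_interval`` on
    ``strand_of_sequence``. Only sites whose full 20-mer protospacer and PAM
    lie inside the window are returned. Candidates containing N anywhere in
    protospacer+PAM are dropped; the second return value counts them.
    """
    lo, hi = min(exon_interval), max(exon_interval)
    if hi - lo + 1 != len(exon_sequence):
        raise ValueError("exon_interval length does not match sequence")
    plus_seq = (
        revcomp(exon_sequence) if strand_of_sequence == "-" else exon_sequence
    )
    candidates: list[GuideCandidate] = []
    n_dropped = 0
    for m in _PLUS_SITE.finditer(plus_seq):
        i = m.start()
        proto, pam = plus_seq[i : i + 20], plus_seq[i + 20 : i + 23]
        if "N" in proto or "N" in pam:
            n_dropped += 1
            continue
        candidates.append(
            GuideCandidate(
                protospacer=proto,
                pam=pam,
                chrom=chrom,
                strand="+",
                start=lo + i,
                end=lo + i + 19,
                gene_id=gene_id,
            )
        )
    for m in _MINUS_SITE.finditer(plus_seq):
        j = m.start()
        proto = revcomp(plus_seq[j + 3 : j + 23])
        pam = revcomp(plus_seq[j : j + 3])
        if "N" in proto or "N" in pam:
            n_dropped += 1
            continue
        candidates.append(
            GuideCandidate(
                protospacer=proto,
                pam=pam,
                chrom=chrom,
                strand="-",
                start=lo + j + 3,
                end=lo + j + 22,
                gene_id=gene_id,
            )
        )
    return candidates, n_dropped


def gc_content(protospacer: str) -> float:
    """(#G + #C) / 20 of a 20-mer protospacer."""
    if len(protospacer) != PROTOSPACER_LEN:
        raise ValueError("protospacer must be 20 nt")
    return gc_fraction(protospacer)


def peptide_remaining(
    candidate: GuideCandidate, primary_transcript
) -> float | None:
    """Predicted % of peptide left after a frameshift at the disruption site.

    The disrupting lesion is assumed at the final protospacer nucleotide
    before the PAM; the value is 100 x CDS offset of that base / CDS length.
    Returns None (flagged absent) when the base lies outside the CDS.
    """
    pos = candidate.disruption_site
    try:
        off = primary_transcript.cds_offset(pos)
    except ValueError:
        return None
    return 100.0 * off / primary_transcript.cds_length


class SpecificityIndex:
    """Exhaustive off-target counter over every NGG-adjacent 20-mer site.

    Sites are packed 2 bits/base into uint64, so a ≤3-mismatch scan is a
    vectorised XOR + popcount over the whole genome. The score is a documented
    monotone placeholder — 100 x 0.85^n for n off-target sites — not a
    reimplementation of any published specificity model; externally supplied
    scores always take precedence in :func:`design_library`.
    """

    _MASK01 = np.uint64(0x5555555555555555)
    decay = 0.85

    def __init__(self, genome: Genome):
        packed: list[np.ndarray] = []
        keys: list[tuple] = []
        for chrom in genome.chroms:
            seq = genome.sequence(chrom)
            codes = encode_seq(seq)
            for m in _PLUS_SITE.finditer(seq):
                i = m.start()
                w = codes[i : i + 20]
                if (w > 3).any():
                    continue
                keys.append((chrom, "+", i + 1))
                packed.append(w)
            for m in _MINUS_SITE.finditer(seq):
                j = m.start()
                w = codes[j + 3 : j + 23]
                if (w > 3).any():
                    continue
                keys.append((chrom, "-", j + 4))
                packed.append((3 - w)[::-1])
        if packed:
            arr = np.asarray(packed, dtype=np.uint64)
            weights = (np.uint64(4) ** np.arange(19, -1, -1, dtype=np.uint64))
            self._packed = (arr * weights).sum(axis=1, dtype=np.uint64)
        else:
            self._packed = np.empty(0, dtype=np.uint64)
        self._keys = keys
        self._key_index = {k: i for i, k in enumerate(keys)}

    def __len__(self) -> int:
        return len(self._keys)

    @staticmethod
    def _pack(protospacer: str) -> np.uint64:
        codes = encode_seq(protospacer)
        if (codes > 3).any():
            raise ValueError("protospacer contains non-ACGT base")
        weights = np.uint64(4) ** np.arange(19, -1, -1, dtype=np.uint64)
        return np.uint64((codes.astype(np.uint64) * weights).sum())

    def count_offtargets(
        self, candidate: GuideCandidate, max_mismatches: int = 3
    ) -> int:
        """NGG-adjacent sites within ``max_mismatches`` of the protospacer,
        excluding the candidate's own genomic site."""
        if len(self._packed) == 0:
            return 0
        x = self._packed ^ self._pack(candidate.protospacer)
        mism = np.bitwise_count((x | (x >> np.uint64(1))) & self._MASK01)
        hits = np.flatnonzero(mism <= max_mismatches)
        own = self._key_index.get((candidate.chrom, candidate.strand, candidate.start))
        return int(len(hits)) - int(own is not None and own in set(hits.tolist()))

    def score(self, candidate: GuideCandidate) -> float:
        return 100.0 * self.decay ** self.count_offtargets(candidate)


def specificity_score(
    candidate: GuideCandidate,
    index: SpecificityIndex,
    external_scores: Mapping[str, float] | None = None,
) -> float:
    """External score when supplied for this protospacer, else the built-in."""
    if external_scores and candidate.protospacer in external_scores:
        return float(external_scores[candidate.protospacer])
    return index.score(candidate)


@dataclass
class SelectionFlags:
    n_selected: int = 0
    all_threshold_met: bool = True
    backup_used: bool = False
    nonoverlap_met: bool = True
    unreachable: bool = False
    under_covered_imports: bool = False
    n_imported: int = 0


def _rank_key(c: GuideCandidate, params: DesignParams, gene_strand: str):
    score_tier = 0 if (c.specificity_score or 0) >= params.score_threshold else 1
    five_prime = c.cut_site if gene_strand == "+" else -c.cut_site
    return (c.tier, score_tier, five_prime, -(c.specificity_score or 0), c.protospacer)


def _max_nonoverlapping(selected: Sequence[GuideCandidate]) -> list[GuideCandidate]:
    """Largest mutually non-overlapping subset (interval scheduling greedy)."""
    out: list[GuideCandidate] = []
    last_end = None
    for c in sorted(selected, key=lambda c: (c.end, c.start)):
        if last_end is None or c.start > last_end:
            out.append(c)
            last_end = c.end
    return out


def select_guides(
    gene: GeneModel,
    candidates: Iterable[GuideCandidate],
    params: DesignParams,
    forbidden: set[str] | None = None,
) -> tuple[list[GuideCandidate], SelectionFlags]:
    """Tiered greedy selection of up to ``n_designed_per_gene`` guides.

    Candidates must be pre-scored and carry their tier (0 = shared exon,
    1 = primary-variant fallback). Ranking within a tier: score >= 70 before
    [50, 70); then the more 5' cut site; then higher score; then lexicographic
    protospacer. After the greedy pass, lower-ranked disjoint candidates are
    swapped in for overlapping ones until at least
    ``min_nonoverlapping_designed`` selected guides are mutually
    non-overlapping or no admissible swap remains.
    """
    forbidden = forbidden or set()
    flags = SelectionFlags()
    eligible = [
        c
        for c in candidates
        if c.specificity_score is not None
        and c.specificity_score >= params.backup_threshold
        and c.protospacer not in forbidden
    ]
    # dedupe genomically identical sites surfaced by both tiers
    seen_sites: set[tuple] = set()
    uniq: list[GuideCandidate] = []
    for c in sorted(eligible, key=lambda c: _rank_key(c, params, gene.strand)):
        site = (c.chrom, c.strand, c.start)
        if site in seen_sites:
            continue
        seen_sites.add(site)
        uniq.append(c)
    if not uniq:
        flags.unreachable = True
        flags.all_threshold_met = False
        flags.nonoverlap_met = False
        return [], flags

    ranked = uniq
    selected: list[GuideCandidate] = []
    used_protospacers: set[str] = set()
    for c in ranked:
        if len(selected) == params.n_designed_per_gene:
            break
        if c.protospacer in used_protospacers:
            continue
        selected.append(c)
        used_protospacers.add(c.protospacer)

    target_indep = min(params.min_nonoverlapping_designed, len(selected))
    for _ in range(len(ranked)):
        indep = _max_nonoverlapping(selected)
        if len(indep) >= target_indep:
            break
        indep_set = {id(c) for c in indep}
        replacement = next(
            (
                c
                for c in ranked
                if c not in selected
                and c.protospacer not in used_protospacers
                and all(overlap_bp(c.span, k.span) == 0 for k in indep)
            ),
            None,
        )
        if replacement is None:
            break
        # evict the worst-ranked selected guide that is not in the kept
        # independent set
        evictable = [c for c in selected if id(c) not in indep_set]
        victim = max(evictable, key=lambda c: _rank_key(c, params, gene.strand))
        selected[selected.index(victim)] = replacement
        used_protospacers.discard(victim.protospacer)
        used_protospacers.add(replacement.protospacer)

    selected = sorted(selected, key=lambda c: _rank_key(c, params, gene.strand))
    out = [replace(c, group=i + 1) for i, c in enumerate(selected)]
    flags.n_selected = len(out)
    flags.all_threshold_met = all(
        c.specificity_score >= params.score_threshold for c in out
    )
    flags.backup_used = any(
        c.specificity_score < params.score_threshold for c in out
    )
    flags.nonoverlap_met = len(_max_nonoverlapping(out)) >= min(
        params.min_nonoverlapping_designed, len(out)
    )
    return out, flags


def import_external_guides(
    gene: GeneModel,
    external: Sequence[GuideCandidate],
    selected: Sequence[GuideCandidate],
    params: DesignParams,
    forbidden: set[str] | None = None,
) -> tuple[list[GuideCandidate], bool]:
    """Admit up to ``n_imported_per_gene`` external guides (groups 6-7).

    External guides are taken in the given priority order; a guide is rejected
    when its protospacer span shares >= ``imported_overlap_limit_bp`` with any
    already accepted guide, designed or imported. Returns the imports and an
    under-covered flag when fewer than requested were admissible.
    """
    forbidden = forbidden or set()
    taken: list[GuideCandidate] = []
    existing = list(selected)
    group = params.n_designed_per_gene
    for c in external:
        if len(taken) == params.n_imported_per_gene:
            break
        if c.protospacer in forbidden:
            continue
        if any(
            k.chrom == c.chrom
            and overlap_bp(c.span, k.span) >= params.imported_overlap_limit_bp
            for k in existing
        ):
            continue
        group += 1
        taken.append(replace(c, group=group, source="imported"))
        existing.append(c)
    return taken, len(taken) < params.n_imported_per_gene


_LIBRARY_COLUMNS = [
    "guide_id",
    "gene_id",
    "symbol",
    "group",
    "source",
    "protospacer",
    "pam",
    "chrom",
    "strand",
    "start",
    "end",
    "cut_site",
    "gc_fraction",
    "specificity_score",
    "predicted_activity",
    "peptide_remaining_pct",
    "tier",
    "exon_start",
    "exon_end",
]


@dataclass
class LibraryDesign:
    """The designed library: one row per guide plus per-gene selection flags."""

    table: pd.DataFrame
    gene_flags: dict[str, SelectionFlags] = field(default_factory=dict)

    def diagnostics(self, params: DesignParams | None = None) -> dict:
        """Library-wide QC percentages over the designed guide groups 1-5,
        mirroring the design-summary views (specificity, 5'-targeting, GC,
        predicted activity, per-gene coverage)."""
        params = params or DesignParams()
        t = self.table
        d = t[t["source"] == "designed"]
        per_gene = t.groupby("gene_id")["guide_id"].count()
        hist = per_gene.value_counts().sort_index().to_dict()
        pred = t["predicted_activity"].dropna()
        return {
            "n_guides": int(len(t)),
            "n_genes": int(t["gene_id"].nunique()),
            "pct_score_ge_70": _pct(d["specificity_score"] >= params.score_threshold),
            "pct_peptide_le_25": _pct(d["peptide_remaining_pct"].dropna() <= 25),
            "pct_gc_in_band": _pct(
                (d["gc_fraction"] >= params.gc_band[0])
                & (d["gc_fraction"] <= params.gc_band[1])
            ),
            "pct_predicted_ge_threshold": _pct(
                pred >= params.predicted_activity_flag_threshold
            ),
            "guides_per_gene_hist": hist,
            "pct_genes_ge_4_guides": _pct(per_gene >= 4),
        }

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @staticmethod
    def read_tsv(path: str) -> "LibraryDesign":
        return LibraryDesign(pd.read_csv(path, sep="\t"))

    def to_bed(self, path: str) -> None:
        """Protospacer spans + cut sites, 0-based half-open BED."""
        t = self.table
        bed = pd.DataFrame(
            {
                "chrom": t["chrom"],
                "start": t["start"] - 1,
                "end": t["end"],
                "name": t["guide_id"],
                "score": t["specificity_score"].fillna(0).round(1),
                "strand": t["strand"],
                "thickStart": t["cut_site"] - 1,
                "thickEnd": t["cut_site"],
            }
        )
        bed.to_csv(path, sep="\t", index=False, header=False)


def _pct(mask) -> float:
    n = len(mask)
    return 100.0 * float(np.sum(mask)) / n if n else float("nan")


def design_library(
    genes: Mapping[str, GeneModel],
    genome: Genome,
    external_lists: Mapping[str, Sequence[GuideCandidate]] | None = None,
    params: DesignParams | None = None,
    external_scores: Mapping[str, float] | None = None,
    predicted_activity: Mapping[str, float] | None = None,
    specificity_index: SpecificityIndex | None = None,
) -> LibraryDesign:
    """Design the full library: per-gene tiered selection plus imports.

    Protospacer uniqueness is global: once a protospacer is taken by one gene
    it is forbidden for every later gene (genes processed in gene_id order),
    which re-triggers selection of the next-ranked candidate.
    """
    params = params or DesignParams()
    external_lists = external_lists or {}
    index = specificity_index or SpecificityIndex(genome)
    forbidden: set[str] = set()
    rows: list[dict] = []
    gene_flags: dict[str, SelectionFlags] = {}

    for gid in sorted(genes):
        gene = genes[gid]
        tiers = target_exon_tiers(gene, genome)
        cands: list[GuideCandidate] = []
        for tier_idx, tier in enumerate(tiers):
            for interval, seq in tier:
                found, _ = scan_pams(
                    seq,
                    interval,
                    gene.strand,
                    chrom=gene.chrom,
                    gene_id=gid,
                )
                for c in found:
                    c.tier = tier_idx
                    c.exon = (min(interval), max(interval))
                cands.extend(found)
        for c in cands:
            c.specificity_score = specificity_score(c, index, external_scores)
            c.peptide_remaining_pct = peptide_remaining(c, gene.primary)
            if predicted_activity:
                c.predicted_activity = predicted_activity.get(c.protospacer)

        selected, flags = select_guides(gene, cands, params, forbidden)
        forbidden.update(c.protospacer for c in selected)

        ext = list(external_lists.get(gid, []))
        for c in ext:
            if c.specificity_score is None and external_scores:
                c.specificity_score = external_scores.get(c.protospacer)
            if predicted_activity and c.predicted_activity is None:
                c.predicted_activity = predicted_activity.get(c.protospacer)
            if c.peptide_remaining_pct is None:
                c.peptide_remaining_pct = peptide_remaining(c, gene.primary)
        imported, under = import_external_guides(
            gene, ext, selected, params, forbidden
        )
        forbidden.update(c.protospacer for c in imported)
        flags.under_covered_imports = under
        flags.n_imported = len(imported)
        gene_flags[gid] = flags

        for c in selected + imported:
            rows.append(
                {
                    "guide_id": f"{gid}_g{c.group}",
                    "gene_id": gid,
                    "symbol": gene.symbol,
                    "group": c.group,
                    "source": c.source,
                    "protospacer": c.protospacer,
                    "pam": c.pam,
                    "chrom": c.chrom,
                    "strand": c.strand,
                    "start": c.start,
                    "end": c.end,
                    "cut_site": c.cut_site,
                    "gc_fraction": c.gc_fraction,
                    "specificity_score": c.specificity_score,
                    "predicted_activity": c.predicted_activity,
                    "peptide_remaining_pct": c.peptide_remaining_pct,
                    "tier": c.tier,
                    "exon_start": c.exon[0] if c.exon else pd.NA,
                    "exon_end": c.exon[1] if c.exon else pd.NA,
                }
            )

    table = pd.DataFrame(rows, columns=_LIBRARY_COLUMNS)
    if len(table) and table["protospacer"].duplicated().any():
        raise AssertionError("global protospacer uniqueness violated")
    return LibraryDesign(table=table, gene_flags=gene_flags)


def read_external_guides(path: str) -> dict[str, list[GuideCandidate]]:
    """External guide TSV (gene_id, protospacer, chrom, strand, start, end,
    optional pam/priority) -> per-gene priority-ordered candidate lists."""
    df = pd.read_csv(path, sep="\t")
    if "priority" in df.columns:
        df = df.sort_values(["gene_id", "priority"], kind="stable")
    out: dict[str, list[GuideCandidate]] = {}
    for row in df.itertuples(index=False):
        pam = str(getattr(row, "pam", "AGG"))
        if len(pam) != 3 or pam[1:] != "GG":
            pam = "AGG"  # PAM not recorded for imports; any NGG placeholder
        out.setdefault(row.gene_id, []).append(
            GuideCandidate(
                protospacer=row.protospacer,
                pam=pam,
                chrom=row.chrom,
                strand=row.strand,
                start=int(row.start),
                end=int(row.end),
                gene_id=row.gene_id,
                source="imported",
            )
        )
    return out


def read_score_table(path: str) -> dict[str, float]:
    """TSV with columns protospacer, score -> mapping."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["protospacer"], df["score"].astype(float)))
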