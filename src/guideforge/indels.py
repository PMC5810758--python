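"""Editing quantification from target-enrichment alignments.

Cas9 cleaves 3 bp upstream of the PAM; error-prone NHEJ repair leaves
insertions/deletions at the cut. The pipeline classifies aligned reads
(discarding proper pairs with gapless CIGARs as unedited molecules, then
duplicates and MAPQ < 38), extracts in/del events from CIGAR strings,
keeps events within +/-2 nt of each guide's cleavage site, removes events
also seen in an untransduced control, and summarises per-guide activity as
the Observed Activity Score

    OAS = mu_ID / ((sgR / TR) * 100)

where mu_ID is the mean valid in/del count across replicates, sgR the
guide's raw read count in the pool and TR the pool total — i.e. in/del yield
normalised to the guide's percentage representation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

MAPQ_MIN = 38
INDEL_MAX_LEN = 2000  # alignment-phase cap on in/del size


class IndelEvent(NamedTuple):
    """One insertion or deletion called from a CIGAR.

    position: for a deletion, the first deleted reference base; for an
    insertion, the reference base immediately left of the inserted sequence.
    """

    type: str  # "insertion" | "deletion"
    length: int
    chrom: str
    position: int
    read_id: str

    @property
    def span(self) -> tuple[int, int]:
        if self.type == "deletion":
            return (self.position, self.position + self.length - 1)
        return (self.position, self.position)

    @property
    def key(self) -> tuple:
        return (self.chrom, self.position, self.type, self.length)


@dataclass
class TargetSite:
    """A guide's cleavage site and validity window.

    The window is the six-base interval [cut_site - 2, cut_site + 3]: the two
    scission-flanking bases (protospacer positions 17 and 18) extended 2 nt
    both ways.
    """

    guide_id: str
    chrom: str
    cut_site: int
    window_pad: int = 2

    @property
    def window(self) -> tuple[int, int]:
        return (self.cut_site - self.window_pad, self.cut_site + self.window_pad + 1)


@dataclass
class ClassifyStats:
    n_input: int = 0
    n_unmapped: int = 0
    n_proper_gapless: int = 0
    n_duplicate: int = 0
    n_low_mapq: int = 0
    n_retained: int = 0


def _has_indel(cigartuples: Sequence[tuple[int, int]]) -> bool:
    return any(op in (pysam.CINS, pysam.CDEL) for op, _ in cigartuples)


def classify_reads(
    alignments: Iterable[pysam.AlignedSegment],
) -> tuple[list[pysam.AlignedSegment], ClassifyStats]:
    """Keep reads that can carry evidence of editing.

    Discards, in order: unmapped records (counted); reads aligned in a proper
    pair with a gapless CIGAR (unedited or correctly repaired molecules);
    duplicates; reads with MAPQ < 38.
    """
    stats_ = ClassifyStats()
    retained: list[pysam.AlignedSegment] = []
    for aln in alignments:
        stats_.n_input += 1
        if aln.is_unmapped or aln.cigartuples is None:
            stats_.n_unmapped += 1
            continue
        if aln.is_proper_pair and not _has_indel(aln.cigartuples):
            stats_.n_proper_gapless += 1
            continue
        if aln.is_duplicate:
            stats_.n_duplicate += 1
            continue
        if aln.mapping_quality < MAPQ_MIN:
            stats_.n_low_mapq += 1
            continue
        stats_.n_retained += 1
        retained.append(aln)
    return retained, stats_


_OP_CHARS = {
    "M": pysam.CMATCH,
    "I": pysam.CINS,
    "D": pysam.CDEL,
    "N": pysam.CREF_SKIP,
    "S": pysam.CSOFT_CLIP,
    "H": pysam.CHARD_CLIP,
    "P": pysam.CPAD,
    "=": pysam.CEQUAL,
    "X": pysam.CDIFF,
}
_REF_CONSUMING = {pysam.CMATCH, pysam.CDEL, pysam.CREF_SKIP, pysam.CEQUAL, pysam.CDIFF}


def indel_events(
    pos: int,
    cigar: Sequence[tuple[str, int]],
    chrom: str = "",
    read_id: str = "",
) -> list[IndelEvent]:
    """Walk a CIGAR (1-based leftmost ``pos``) and emit I/D events.

    M/=/X and N consume reference; S/H/P do not. An insertion is anchored to
    the reference base left of it; a deletion to its first deleted base.
    """
    events: list[IndelEvent] = []
    ref = pos
    for op_char, length in cigar:
        if length < 1:
            raise ValueError(f"malformed CIGAR for read {read_id!r}")
        op = _OP_CHARS.get(op_char)
        if op is None:
            raise ValueError(f"unknown CIGAR op {op_char!r} in read {read_id!r}")
        if op == pysam.CINS:
            events.append(IndelEvent("insertion", length, chrom, ref - 1, read_id))
        elif op == pysam.CDEL:
            events.append(IndelEvent("deletion", length, chrom, ref, read_id))
            ref += length
        elif op in _REF_CONSUMING:
            ref += length
    return events


_NUM_TO_CHAR = "MIDNSHP=X"


def extract_indels(read: pysam.AlignedSegment) -> list[IndelEvent]:
    """CIGAR in/del extraction from a SAM record retained by classify_reads."""
    if read.cigartuples is None:
        raise ValueError(f"read {read.query_name} has no CIGAR")
    cigar = [(_NUM_TO_CHAR[op], ln) for op, ln in read.cigartuples]
    return indel_events(
        read.reference_start + 1, cigar, read.reference_name or "", read.query_name
    )


def window_filter(
    events: Iterable[IndelEvent],
    site: TargetSite,
    deletion_rule: str = "span",
) -> list[IndelEvent]:
    """Events valid for ``site``: within +/-2 nt of the cleavage site.

    Insertions are valid when their anchor position lies inside the window;
    deletions (default "span" rule) when their deleted span intersects it,
    or (rule "point") when their leftmost deleted base lies inside it.
    """
    lo, hi = site.window
    valid = []
    for ev in events:
        if ev.chrom != site.chrom:
            continue
        if ev.type == "insertion":
            ok = lo <= ev.position <= hi
        elif deletion_rule == "span":
            s, e = ev.span
            ok = s <= hi and e >= lo
        else:
            ok = lo <= ev.position <= hi
        if ok:
            valid.append(ev)
    return valid


def subtract_control(
    events: Iterable[IndelEvent], control_events: Iterable[IndelEvent]
) -> list[IndelEvent]:
    """Drop events whose (chrom, position, type, length) key occurs in the
    untransduced control — background variation and alignment artefacts."""
    control_keys = {ev.key for ev in control_events}
    return [ev for ev in events if ev.key not in control_keys]


def compute_oas(mu_id: float, sgr: float, tr: float) -> float:
    """Observed Activity Score: mu_ID / ((sgR/TR) * 100).

    sgR = 0 leaves the score undefined (NaN): activity cannot be normalised
    for a guide undetected in the pool.
    """
    if tr <= 0:
        raise ValueError("total pool reads must be positive")
    if sgr <= 0:
        return float("nan")
    return mu_id / ((sgr / tr) * 100.0)


@dataclass
class ActivityTable:
    """Per-guide editing activity with pool normalisation."""

    table: pd.DataFrame
    classify_stats: list[ClassifyStats] = field(default_factory=list)

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _events_for_sam(
    path: str, sites: Sequence[TargetSite]
) -> tuple[list[IndelEvent], ClassifyStats]:
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        retained, st = classify_reads(fh)
    events: list[IndelEvent] = []
    for read in retained:
        events.extend(extract_indels(read))
    return events, st


def call_activity(
    edited_sams: Sequence[str],
    control_sam: str | None,
    sites: Sequence[TargetSite],
    pool_counts: pd.DataFrame,
    deletion_rule: str = "span",
) -> ActivityTable:
    """Run the full in/del pipeline over replicate alignments.

    ``edited_sams`` are one SAM/BAM per biological replicate; the control is
    processed with identical classify/extract steps but no window filter.
    ``pool_counts`` must carry guide_id and raw_reads (the representation
    count table). Returns one row per target site with per-replicate valid
    in/del counts, mu_ID, pool normalisation and OAS; ``active`` means
    mu_ID > 0 after all filters for a pool-detected guide.
    """
    control_events: list[IndelEvent] = []
    if control_sam is not None:
        control_events, _ = _events_for_sam(control_sam, sites)
    control_keys = {ev.key for ev in control_events}

    per_rep_counts: dict[str, list[int]] = {s.guide_id: [] for s in sites}
    all_stats: list[ClassifyStats] = []
    for sam in edited_sams:
        events, st = _events_for_sam(sam, sites)
        all_stats.append(st)
        events = [ev for ev in events if ev.key not in control_keys]
        by_chrom: dict[str, list[IndelEvent]] = {}
        for ev in events:
            by_chrom.setdefault(ev.chrom, []).append(ev)
        for site in sites:
            valid = window_filter(
                by_chrom.get(site.chrom, []), site, deletion_rule
            )
            per_rep_counts[site.guide_id].append(len(valid))

    counts = pool_counts.set_index("guide_id")["raw_reads"]
    tr = float(counts.sum())
    rows = []
    n_reps = len(edited_sams)
    for site in sites:
        reps = per_rep_counts[site.guide_id]
        mu = float(np.mean(reps)) if reps else 0.0
        sgr = float(counts.get(site.guide_id, 0))
        detected = sgr > 0
        oas = compute_oas(mu, sgr, tr) if tr > 0 else float("nan")
        row = {
            "guide_id": site.guide_id,
            "chrom": site.chrom,
            "cut_site": site.cut_site,
            **{f"indels_rep{i + 1}": reps[i] for i in range(n_reps)},
            "mu_id": mu,
            "sgR": sgr,
            "TR": tr,
            "normalized_count": 100.0 * sgr / tr if tr > 0 else float("nan"),
            "oas": oas,
            "detected_in_pool": detected,
            "active": bool(detected and mu > 0),
        }
        rows.append(row)
    return ActivityTable(pd.DataFrame(rows), all_stats)


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall rank correlation, tau-b variant (tie-corrected)."""
    if len(x) != len(y) or len(x) < 2:
        return float("nan")
    return float(stats.kendalltau(x, y, variant="b").statistic)


def activity_summary(
    activity: pd.DataFrame,
    library_table: pd.DataFrame | None = None,
    predicted: pd.DataFrame | None = None,
) -> dict:
    """Library-wide activity summary.

    Percent active among pool-detected guides, per guide group when the
    library table supplies groups; percent of genes with >= 1 active guide;
    Kendall tau-b between OAS and predicted activity over guides carrying
    both values (absent with < 2 pairs).
    """
    det = activity[activity["detected_in_pool"]]
    out: dict = {
        "n_sites": int(len(activity)),
        "n_detected_in_pool": int(len(det)),
        "pct_active_overall": (
            100.0 * float(det["active"].mean()) if len(det) else float("nan")
        ),
    }
    merged = activity
    if library_table is not None:
        merged = activity.merge(
            library_table[["guide_id", "gene_id", "group"]], on="guide_id", how="left"
        )
        by_group = {}
        for g, grp in merged[merged["detected_in_pool"]].groupby("group"):
            by_group[int(g)] = 100.0 * float(grp["active"].mean())
        out["pct_active_by_group"] = by_group
        per_gene = merged.groupby("gene_id")["active"].any()
        out["pct_genes_edited"] = 100.0 * float(per_gene.mean())
    if predicted is not None:
        paired = activity.merge(predicted, on="guide_id", how="inner")
        paired = paired.dropna(subset=["oas", "predicted_activity"])
        if len(paired) >= 2:
            out["kendall_tau_b"] = kendall_tau_b(
                paired["oas"].to_numpy(), paired["predicted_activity"].to_numpy()
            )
        else:
            out["kendall_tau_b"] = None
    return out


def write_summary(summary: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


def sites_from_library(library_table: pd.DataFrame, window_pad: int = 2) -> list[TargetSite]:
    return [
        TargetSite(
            guide_id=row.guide_id,
            chrom=row.chrom,
            cut_site=int(row.cut_site),
            window_pad=window_pad,
        )
        for row in library_table.itertuples(index=False)
    ]


def read_sites_tsv(path: str, window_pad: int = 2) -> list[TargetSite]:
    df = pd.read_csv(path, sep="\t")
    return sites_from_library(df, window_pad)
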