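"""sgRNA representation counting from pooled amplicon sequencing.

Reads from the pooled plasmid library contain the 20-nt protospacer between
constant vector flanks. Counting is exact-match by default: each read is
scanned (or sliced at a known trim offset) for a 20-mer equal to a library
protospacer, reads matching no guide are "unassigned" and reads matching two
or more are "ambiguous" and dropped. Normalised counts are percentages of the
assigned total; the fold-from-mean statistic underlies the representation QC
(fraction of guides within 2-fold of the mean, undetected guides, per-gene
coverage).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

PROTO_LEN = 20


@dataclass
class MatchingConfig:
    """How reads are matched to protospacers.

    trim_offset: 0-based position of the protospacer within the read when the
    amplicon structure is fixed; None scans every 20-mer window.
    max_mismatches: 0 (exact, default) or 1.
    """

    trim_offset: int | None = None
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        if self.max_mismatches not in (0, 1):
            raise ValueError("max_mismatches must be 0 or 1")


@dataclass
class CountTable:
    """Per-guide raw and normalised counts plus read-fate bookkeeping."""

    counts: pd.DataFrame  # guide_id, raw_reads, normalized_count, fold_from_mean, detected
    total_reads: int
    unassigned: int
    ambiguous: int

    @property
    def assigned(self) -> int:
        return int(self.counts["raw_reads"].sum())

    @property
    def empty(self) -> bool:
        return self.assigned == 0

    def to_tsv(self, path: str) -> None:
        self.counts.to_csv(path, sep="\t", index=False)

    @staticmethod
    def read_tsv(path: str) -> "CountTable":
        df = pd.read_csv(path, sep="\t")
        return _finalize(df[["guide_id", "raw_reads"]], 0, 0, total=None)


def _variants_1mm(seq: str) -> Iterable[str]:
    for i, base in enumerate(seq):
        for b in "ACGT":
            if b != base:
                yield seq[:i] + b + seq[i + 1 :]


def _build_lookup(
    protospacers: Mapping[str, str], max_mismatches: int
) -> dict[str, str | None]:
    """protospacer (or 1-mm variant) -> guide_id; None marks a collision."""
    lookup: dict[str, str | None] = {}
    for guide_id, proto in protospacers.items():
        if proto in lookup:
            raise ValueError(f"duplicate protospacer {proto}")
        lookup[proto] = guide_id
    if max_mismatches == 1:
        exact = dict(lookup)
        for guide_id, proto in protospacers.items():
            for var in _variants_1mm(proto):
                if var in exact:
                    continue  # a variant equal to another guide stays exact
                if var in lookup and lookup[var] != guide_id:
                    lookup[var] = None  # ambiguous between guides
                else:
                    lookup[var] = guide_id
    return lookup


def count_guides(
    reads: Iterable[str] | str,
    protospacers: Mapping[str, str],
    config: MatchingConfig | None = None,
) -> CountTable:
    """Count reads per guide.

    ``reads`` is either an iterable of read sequences or a FASTQ path
    (gzipped allowed). ``protospacers`` maps guide_id -> 20-mer. Each read
    increments exactly one guide, or the unassigned/ambiguous tallies.
    """
    config = config or MatchingConfig()
    lookup = _build_lookup(protospacers, config.max_mismatches)
    raw = {gid: 0 for gid in protospacers}
    unassigned = ambiguous = total = 0

    if isinstance(reads, str):
        with pysam.FastxFile(reads) as fh:
            seqs: Iterable[str] = [r.sequence for r in fh]
    else:
        seqs = reads

    for seq in seqs:
        total += 1
        seq = seq.upper()
        hits: set[str] = set()
        hit_none_collision = False
        if config.trim_offset is not None:
            windows = [seq[config.trim_offset : config.trim_offset + PROTO_LEN]]
        else:
            windows = [
                seq[i : i + PROTO_LEN] for i in range(len(seq) - PROTO_LEN + 1)
            ]
        for w in windows:
            g = lookup.get(w, "missing")
            if g is None:
                hit_none_collision = True
            elif g != "missing":
                hits.add(g)
        if len(hits) == 1 and not hit_none_collision:
            raw[next(iter(hits))] += 1
        elif len(hits) >= 2 or hit_none_collision:
            ambiguous += 1
        else:
            unassigned += 1

    df = pd.DataFrame(
        {"guide_id": list(protospacers), "raw_reads": [raw[g] for g in protospacers]}
    )
    return _finalize(df, unassigned, ambiguous, total)


def _finalize(
    df: pd.DataFrame, unassigned: int, ambiguous: int, total: int | None
) -> CountTable:
    assigned = int(df["raw_reads"].sum())
    mean = df["raw_reads"].mean()
    out = df.copy()
    if assigned > 0:
        out["normalized_count"] = 100.0 * out["raw_reads"] / assigned
    else:
        out["normalized_count"] = np.nan
    out["fold_from_mean"] = out["raw_reads"] / mean if mean > 0 else np.nan
    out["detected"] = out["raw_reads"] > 0
    return CountTable(
        counts=out,
        total_reads=assigned + unassigned + ambiguous if total is None else total,
        unassigned=unassigned,
        ambiguous=ambiguous,
    )


def representation_stats(
    table: CountTable,
    library_table: pd.DataFrame | None = None,
    fold_band: tuple[float, float] = (0.5, 2.0),
    outlier_fold: float = 10.0,
    min_guides_per_gene: int = 4,
) -> dict:
    """Representation QC summary.

    Percent detected guides; percent of detected guides within the open
    fold-from-mean band (default (0.5, 2): less than 2-fold from the mean);
    undetected guide list; fold outliers; and, when the library table is
    given, the per-gene detected-guide histogram and the percentage of genes
    with at least ``min_guides_per_gene`` detected guides.
    """
    c = table.counts
    if len(c) == 0:
        raise ValueError("empty count table")
    detected = c[c["detected"]]
    lo, hi = fold_band
    in_band = detected[
        (detected["fold_from_mean"] > lo) & (detected["fold_from_mean"] < hi)
    ]
    stats = {
        "n_guides": int(len(c)),
        "pct_detected": 100.0 * len(detected) / len(c),
        "pct_detected_within_band": (
            100.0 * len(in_band) / len(detected) if len(detected) else float("nan")
        ),
        "undetected_guides": list(c.loc[~c["detected"], "guide_id"]),
        "outliers": list(
            c.loc[c["fold_from_mean"] >= outlier_fold, "guide_id"]
        ),
    }
    if library_table is not None:
        merged = library_table[["guide_id", "gene_id"]].merge(
            c[["guide_id", "detected"]], on="guide_id", how="left"
        )
        per_gene = merged.groupby("gene_id")["detected"].sum()
        stats["detected_per_gene_hist"] = (
            per_gene.astype(int).value_counts().sort_index().to_dict()
        )
        stats["pct_genes_ge_min_guides"] = 100.0 * float(
            (per_gene >= min_guides_per_gene).mean()
        )
    return stats
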