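"""Physical library construction: cloning oligos, arrayed plate layout,
derived pools and target-enrichment probe regions.

The arrayed format puts one guide per well of 96-well plates (column-major
fill, plates opened on demand). Pools are derived three ways: one whole-library
pool, one pool per gene (all guides of that gene, themselves arrayed into
96-well plates), and one pool per guide group in {5, 6, 7} holding exactly one
guide per gene — the formats used for selection screens, high-content screens
and library-wide activity validation respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from ._util import revcomp

ROWS = "ABCDEFGH"
WELLS_PER_PLATE = 96


@dataclass
class VectorConfig:
    """Golden Gate overhangs added to annealed oligos.

    The defaults are the common U6/BsmBI sgRNA-vector overhangs; they are an
    assumption of this package, configurable per vector. The 5' G required
    for pol III transcription is supplied by the vector during cloning and is
    never written into the oligos.
    """

    forward_overhang: str = "ACCG"
    reverse_overhang: str = "AAAC"


@dataclass
class OligoPair:
    guide_id: str
    forward_oligo: str
    reverse_oligo: str


def make_oligos(
    guide_id: str, protospacer: str, vector: VectorConfig | None = None
) -> OligoPair:
    """Forward/reverse annealing oligos for one guide.

    forward = fwd_overhang + protospacer; reverse = rev_overhang +
    reverse-complement(protospacer): annealed, the cores form a perfect 20 bp
    duplex flanked by the vector-compatible 4 nt overhangs.
    """
    vector = vector or VectorConfig()
    if not vector.forward_overhang or not vector.reverse_overhang:
        raise ValueError("vector overhangs must be non-empty")
    return OligoPair(
        guide_id=guide_id,
        forward_oligo=vector.forward_overhang + protospacer,
        reverse_oligo=vector.reverse_overhang + revcomp(protospacer),
    )


def well_name(index: int) -> tuple[int, str]:
    """(plate, well) for the ``index``-th item (0-based), column-major fill:
    A1, B1, ... H1, A2, ... H12, then the next plate."""
    plate = index // WELLS_PER_PLATE
    within = index % WELLS_PER_PLATE
    row = ROWS[within % 8]
    col = within // 8 + 1
    return plate + 1, f"{row}{col}"


@dataclass
class LibraryLayout:
    """Bijective guide -> (plate, well) assignment."""

    assignments: pd.DataFrame  # guide_id, plate, well

    @property
    def n_plates(self) -> int:
        return int(self.assignments["plate"].max()) if len(self.assignments) else 0

    def to_tsv(self, path: str) -> None:
        self.assignments.to_csv(path, sep="\t", index=False)


def plate_layout(library_table: pd.DataFrame) -> LibraryLayout:
    """Array guides into 96-well plates in gene order, then group 1-7."""
    ordered = library_table.sort_values(["gene_id", "group"], kind="stable")
    rows = []
    for i, guide_id in enumerate(ordered["guide_id"]):
        plate, well = well_name(i)
        rows.append({"guide_id": guide_id, "plate": plate, "well": well})
    return LibraryLayout(pd.DataFrame(rows, columns=["guide_id", "plate", "well"]))


def oligo_sheets(
    library_table: pd.DataFrame,
    layout: LibraryLayout | None = None,
    vector: VectorConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward and reverse synthesis order sheets mirroring the arrayed
    layout (two files per plate set, as ordered from an oligo vendor)."""
    layout = layout or plate_layout(library_table)
    merged = layout.assignments.merge(
        library_table[["guide_id", "protospacer"]], on="guide_id"
    )
    fwd_rows, rev_rows = [], []
    for row in merged.itertuples(index=False):
        pair = make_oligos(row.guide_id, row.protospacer, vector)
        fwd_rows.append(
            {
                "plate": row.plate,
                "well": row.well,
                "oligo_name": f"{row.guide_id}_F",
                "sequence": pair.forward_oligo,
            }
        )
        rev_rows.append(
            {
                "plate": row.plate,
                "well": row.well,
                "oligo_name": f"{row.guide_id}_R",
                "sequence": pair.reverse_oligo,
            }
        )
    cols = ["plate", "well", "oligo_name", "sequence"]
    return pd.DataFrame(fwd_rows, columns=cols), pd.DataFrame(rev_rows, columns=cols)


@dataclass
class PoolSpec:
    pool_id: str
    pool_kind: str  # whole | gene | group
    guide_ids: list[str] = field(default_factory=list)


def build_pools(
    library_table: pd.DataFrame, group_pool_groups: tuple[int, ...] = (5, 6, 7)
) -> tuple[list[PoolSpec], LibraryLayout]:
    """Whole pool, per-gene pools (with their own 96-well arrayed layout) and
    one-guide-per-gene group pools.

    A gene lacking a group-k guide is simply absent from pool k; the gene-pool
    layout assigns one well per gene, column-major in gene order.
    """
    pools: list[PoolSpec] = [
        PoolSpec("whole", "whole", list(library_table["guide_id"]))
    ]
    gene_rows = []
    gene_ids = sorted(library_table["gene_id"].unique())
    for i, gid in enumerate(gene_ids):
        members = list(
            library_table.loc[library_table["gene_id"] == gid, "guide_id"]
        )
        pools.append(PoolSpec(f"gene:{gid}", "gene", members))
        plate, well = well_name(i)
        rows_well = {"guide_id": f"gene:{gid}", "plate": plate, "well": well}
        gene_rows.append(rows_well)
    for k in group_pool_groups:
        members = list(
            library_table.loc[library_table["group"] == k]
            .sort_values("gene_id", kind="stable")["guide_id"]
        )
        pools.append(PoolSpec(f"group:{k}", "group", members))
    gene_layout = LibraryLayout(
        pd.DataFrame(gene_rows, columns=["guide_id", "plate", "well"])
    )
    return pools, gene_layout


PROBE_REGION_LEN = 2000


def probe_regions(library_table: pd.DataFrame) -> pd.DataFrame:
    """2 kb capture regions per target site, 1-based closed.

    Each cut site gets a 2,000 bp interval centred on it (1,000 bp up,
    999 bp down). When two or more target sites fall in the same annotated
    exon, a single interval centred on that exon's midpoint
    (floor((start+end)/2)) replaces them. Intervals are clipped at position 1
    and returned sorted by (chrom, start).
    """
    half_up = PROBE_REGION_LEN // 2

    def _region(chrom: str, center: int, name: str) -> dict:
        start = max(1, center - half_up)
        return {
            "chrom": chrom,
            "start": start,
            "end": start + PROBE_REGION_LEN - 1,
            "name": name,
        }

    regions = []
    t = library_table.copy()
    has_exon = t["exon_start"].notna() & t["exon_end"].notna()
    with_exon = t[has_exon]
    for (chrom, es, ee), grp in with_exon.groupby(
        ["chrom", "exon_start", "exon_end"], sort=False
    ):
        if len(grp) >= 2:
            mid = (int(es) + int(ee)) // 2
            name = "exon:" + ",".join(grp["guide_id"])
            regions.append(_region(chrom, mid, name))
        else:
            row = grp.iloc[0]
            regions.append(_region(chrom, int(row["cut_site"]), row["guide_id"]))
    for row in t[~has_exon].itertuples(index=False):
        regions.append(_region(row.chrom, int(row.cut_site), row.guide_id))
    out = pd.DataFrame(regions, columns=["chrom", "start", "end", "name"])
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_bed(regions: pd.DataFrame, path: str) -> None:
    """Write 1-based closed regions as 0-based half-open BED."""
    bed = regions.copy()
    bed["start"] = bed["start"] - 1
    bed.to_csv(path, sep="\t", index=False, header=False)


def n_plates_needed(n_items: int) -> int:
    return math.ceil(n_items / WELLS_PER_PLATE)
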