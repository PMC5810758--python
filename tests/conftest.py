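"""Shared fixtures: a hand-written two-isoform annotation and a small
simulated study (genome, annotation, designed library)."""

from __future__ import annotations

import warnings

import pytest

from guideforge.annotation import load_annotation
from guideforge.design import (
    design_library,
    read_external_guides,
    read_score_table,
)
from guideforge.simulate import SimConfig, simulate_genome

HAND_FASTA = """>chrT
{seq}
"""

# chrT: 600 bp; gene GA (+ strand) with two isoforms sharing exons 2-3 but not
# exon 1; gene coordinates chosen so every CDS length is a multiple of 3.
HAND_GTF_LINES = [
    # isoform tA (primary): exons 101-160, 201-260, 301-330
    ("chrT", "CDS", 101, 160, "+", "GA", "GA.tA", 1),
    ("chrT", "CDS", 201, 260, "+", "GA", "GA.tA", 1),
    ("chrT", "CDS", 301, 330, "+", "GA", "GA.tA", 1),
    # isoform tB: exon 1 trimmed, exons 2-3 identical
    ("chrT", "CDS", 110, 160, "+", "GA", "GA.tB", 0),
    ("chrT", "CDS", 201, 260, "+", "GA", "GA.tB", 0),
    ("chrT", "CDS", 301, 330, "+", "GA", "GA.tB", 0),
    # gene GB on the minus strand, single isoform, two exons
    ("chrT", "CDS", 401, 430, "-", "GB", "GB.tA", 1),
    ("chrT", "CDS", 461, 520, "-", "GB", "GB.tA", 1),
]


def write_hand_annotation(tmpdir) -> tuple[str, str]:
    import random

    rng = random.Random(7)
    seq = "".join(rng.choice("ACGT") for _ in range(600))
    fasta = tmpdir / "hand.fa"
    fasta.write_text(HAND_FASTA.format(seq=seq))
    gtf = tmpdir / "hand.gtf"
    lines = []
    for chrom, feat, s, e, strand, gid, tid, primary in HAND_GTF_LINES:
        attrs = (
            f'gene_id "{gid}"; transcript_id "{tid}"; '
            f'gene_name "{gid}"; primary "{primary}";'
        )
        lines.append(f"{chrom}\ttest\t{feat}\t{s}\t{e}\t.\t{strand}\t0\t{attrs}")
    gtf.write_text("\n".join(lines) + "\n")
    return str(gtf), str(fasta)


@pytest.fixture(scope="session")
def hand_models(tmp_path_factory):
    gtf, fasta = write_hand_annotation(tmp_path_factory.mktemp("hand"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        genes, genome = load_annotation(gtf, fasta)
    return genes, genome


@pytest.fixture(scope="session")
def sim_inputs(tmp_path_factory):
    """12 simulated genes, ~10% without a shared exon."""
    cfg = SimConfig(seed=11, n_genes=12, frac_no_shared_exon=0.17)
    out = tmp_path_factory.mktemp("sim12")
    return cfg, simulate_genome(cfg, str(out))


@pytest.fixture(scope="session")
def sim_models(sim_inputs):
    _, inputs = sim_inputs
    genes, genome = load_annotation(inputs.gtf_path, inputs.fasta_path)
    return genes, genome


@pytest.fixture(scope="session")
def sim_library(sim_inputs, sim_models):
    _, inputs = sim_inputs
    genes, genome = sim_models
    return design_library(
        genes,
        genome,
        external_lists=read_external_guides(inputs.external_path),
        predicted_activity=read_score_table(inputs.predicted_path),
    )
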