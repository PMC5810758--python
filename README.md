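# guideforge

Design, build and quality-control an **arrayed CRISPR–Cas9 knockout sgRNA
library**, and quantify the editing activity of every guide from targeted
sequencing.

The package is aimed at groups producing focused knockout libraries — a few
hundred genes, several guides per gene, one construct per well — rather than
genome-wide pooled screens. It covers the full computational workflow:

1. **Isoform-aware guide design** (`guideforge.design`). For each gene,
   guides are placed in the first translated exon whose CDS interval is
   identical across all annotated isoforms, so that every isoform is
   disrupted; when no such exon exists, the most 5′ CDS exon of the primary
   isoform is used. Up to five guides per gene (groups 1–5) are selected
   preferring specificity scores ≥ 70 (scores in [50, 70) serve as backups)
   and keeping at least three selected guides mutually non-overlapping. Two
   further guides per gene (groups 6–7) are imported from an external,
   efficacy-optimised list, rejected if they share ≥ 15 bp with an existing
   guide. Protospacers are globally unique across the library.
2. **Library construction** (`guideforge.build`): Golden Gate annealing
   oligos (vector overhangs + protospacer / reverse complement), a
   column-major 96-well arrayed layout, derived pools (whole library,
   per-gene pools, and one-guide-per-gene group pools 5/6/7), and 2 kb
   capture-probe regions centred on each cut site (or on the exon midpoint
   when several sites share an exon).
3. **Representation QC** (`guideforge.representation`): exact-match counting
   of protospacers in pooled amplicon FASTQ, normalised counts, and the
   fold-from-mean diagnostics (detected fraction, fraction within 2-fold of
   the mean, undetected guides, per-gene coverage).
4. **Editing quantification** (`guideforge.indels`). From alignments of
   target-enriched reads, the pipeline discards proper pairs with gapless
   CIGARs (unedited molecules), duplicates and reads with MAPQ < 38,
   extracts insertions/deletions from CIGAR strings, keeps events within
   ±2 nt of each guide's cleavage site (6 nt upstream of the end of
   guide+PAM), removes events also present in an untransduced control, and
   scores each guide with the **Observed Activity Score**

   ```
   OAS = μID / ((sgR / TR) · 100)
   ```

   where μID is the mean valid in/del count across replicates, sgR the
   guide's raw read count in the pool and TR the pool total — in/del yield
   normalised to the guide's percentage representation, so unevenly
   represented guides are comparable.
5. **Synthetic data** (`guideforge.simulate`): a generator that emits a
   guide-dense genome with multi-isoform annotation, pool-abundance FASTQ
   and edited/control SAM files with per-read ground truth, so the whole
   pipeline is testable end to end.

Small closed-form bench helpers (Poisson MOI: P = 1 − e⁻ᵐ; caliper tumor
volume d²·D/2) live in `guideforge.wetlab`.

## Worked example

Everything below runs from the bundled simulator — no downloads needed.

```sh
guideforge simulate --seed 3 --n-genes 5 --out-dir sim
guideforge design --genome sim/genome.fa --annotation sim/annotation.gtf \
    --external sim/external_guides.tsv \
    --predicted sim/predicted_activity.tsv --out library.tsv
guideforge layout --library library.tsv --out-dir build
```

`design` prints the library diagnostics, e.g. for the 5-gene toy run: 35
guides over 5 genes, 100 % of designed guides with specificity score ≥ 70
and every gene carrying 7 guides. `layout` reports `1 plates, 9 pools`
(one arrayed plate; 1 whole pool + 5 gene pools + group pools 5/6/7) and
writes oligo order sheets, the well layout and probe-region BED.

Counting a simulated pool and calling editing activity:

```sh
guideforge count --fastq pool.fastq --library library.tsv \
    --out counts.tsv --trim-offset 18
# -> assigned 5000 / unassigned 0 / ambiguous 0
guideforge indel-call --bam edit/edited_rep1.sam --bam edit/edited_rep2.sam \
    --control edit/control.sam --sites sites.tsv \
    --pool-counts counts.tsv --out activity.tsv --summary summary.json
# -> 5/5 sites active
```

`activity.tsv` holds one row per guide with per-replicate in/del counts,
μID, pool representation and OAS; `summary.json` the percent-active
summary. The closed-form helpers print directly:

```sh
guideforge moi 1.0              # 0.632121  (fraction infected at MOI 1)
guideforge tumor-volume 4 8     # 64.000    (mm^3)
```

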