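# Methods

This note documents the models, conventions and numerical choices behind
guideforge, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and conventions

All genomic intervals at module interfaces are 1-based closed (the GTF/SAM
convention); BED output converts to 0-based half-open at the file boundary.
CDS exon lists are kept in translation order (descending genomic coordinates
on the − strand). Protospacers are stored as the 20-mer genomic target in
guide orientation, without the 5′ G that the expression vector prepends
during cloning; the oligo layer likewise never adds it.

## Isoform-aware target selection

A gene's designable exons are ranked in two tiers. Tier 0 contains exons
whose genomic CDS interval is **identical** in every annotated isoform,
ordered by translation position in the primary isoform; guides placed there
disrupt all isoforms. Strict interval identity was chosen over partial
overlap because it is the unambiguous reading of "shared"; isoforms that
share sequence but differ at one boundary therefore do not share the exon.
Tier 1 is the fallback: the primary isoform's CDS exons 5′→3′. Selection
simply continues into tier 1 when tier 0 is empty or cannot fill the quota.
The primary isoform is designated by a configurable annotation attribute
(`primary "1"` by default); a single-isoform gene shares all of its exons
with itself.

## Guide enumeration and scoring

`scan_pams` enumerates every NGG site on both genomic strands whose full
20-mer protospacer lies inside the exon window; candidates containing N are
dropped and counted. The cleavage site is 6 nt upstream of the end of
guide+PAM — protospacer position 17, with the blunt scission between
positions 17 and 18 — computed per strand (`end − 3` on +, `start + 3`
on −).

The predicted knockout severity of a guide is the "peptide remaining"
percentage: 100 × (CDS offset of the final protospacer base before the
PAM) / (CDS length of the primary isoform), i.e. the fraction of protein
N-terminal to an assumed frameshift at that base. Guides outside the
primary CDS carry no value and are flagged.

Off-target specificity uses external scores when a TSV is supplied
(protospacer → score, taking precedence). The built-in fallback scorer is a
deliberately simple, exhaustive and monotone placeholder, **not** a
reimplementation of any published specificity model: all NGG-adjacent
20-mer sites in the genome are packed 2 bits/base into uint64 and scanned by
XOR + popcount; a site within 3 mismatches of the candidate (excluding the
candidate's own locus) counts as an off-target, and the score is
100 × 0.85ⁿ for n off-targets. The form is monotone decreasing in n,
yields 100 for unique guides, and crosses the 70 and 50 thresholds at n = 3
and n = 5, so the tiered selection logic is exercised without external
tools.

## Tiered selection policy

Within a tier, candidates scoring ≥ 70 rank before those in [50, 70)
(backups); ties break by the more 5′ cut site in gene orientation, then the
higher score, then the lexicographically smaller protospacer. The policy is
fully deterministic: identical inputs give a byte-identical library table.
Greedy selection takes the top-ranked candidates up to five per gene; if
fewer than three of the selected guides are mutually non-overlapping
(0 bp protospacer-span overlap), the worst-ranked overlapping guide is
swapped for the best remaining candidate disjoint from the kept independent
set, repeating until the constraint holds or no swap remains. Imported
guides are taken in priority order, rejecting any whose span shares
≥ 15 bp with an already accepted guide — the overlap rule is read as
"shared span must be < 15 bp", which is configurable. Genes with no
candidate ≥ 50 anywhere are reported unreachable, never silently dropped.
Protospacer uniqueness is enforced library-wide: genes are processed in
gene-id order and a protospacer taken by an earlier gene is forbidden to
later ones, triggering re-selection.

## Construction layout

Wells fill column-major (A1, B1, … H1, A2, …), plates opening on demand;
no fill order is canonical, so column-major was fixed and documented. The
Golden Gate overhangs default to ACCG/AAAC (common U6/BsmBI sgRNA vectors)
and are an assumption — configure `VectorConfig` for other vectors. Probe
regions are exactly 2,000 bp: 1,000 bp up and 999 bp down of the centre
base under the closed-interval convention, the centre being the cut site,
or the exon midpoint floor((start+end)/2) when ≥ 2 target sites share an
annotated exon; regions are clipped at position 1. In a compact synthetic
genome neighbouring genes sit closer than 2 kb, so regions of different
genes may overlap; each cut site is still covered by the one region derived
from it.

## Representation counting

Counting is exact-match by default (a configurable 1-mismatch mode exists):
reproducible and conservative, since no mismatch tolerance is canonical for
short amplicon reads. Reads matching two or more guides are dropped as
ambiguous, never fractionally assigned. Normalised counts are percentages
of the assigned total; fold-from-mean uses the mean over **all** library
guides including zeros (a detected-only alternative is a flag), and the
"within 2-fold" band is the open interval (0.5, 2).

## In/del calling and OAS

The two alignment phases of the original strategy (first align disallowing
in/dels and discard proper pairs; then realign permissively) collapse into
one classification rule over a single indel-permissive alignment: a read
that is proper-paired **and** gapless is discarded as unedited; of the
rest, duplicates and MAPQ < 38 are removed. This produces the same read
partition without re-running an aligner. Pairing and duplicate flags are
consumed from the SAM, not recomputed.

CIGAR walking anchors an insertion to the reference base left of the
inserted sequence and a deletion to its first deleted base; `=`/`X` count
as matches, `N` as a reference skip emitting no event. The validity window
is the six-base interval [cut − 2, cut + 3] — the two scission-flanking
bases ± 2 nt. Insertions are valid by point membership of their anchor;
deletions by span intersection (a point-membership rule is available by
config) — a long deletion destroying the site should not be discarded
because its leftmost base lies upstream. Control subtraction removes events
whose exact (chrom, position, type, length) key occurs in the untransduced
sample, processed with identical classify/extract steps but no window
filter; fuzzy matching is out of scope.

OAS = μID / ((sgR/TR)·100) with μID the mean valid-event count over any
number of replicates. μID = 0 gives OAS = 0; sgR = 0 leaves OAS undefined
(NaN) and the guide excluded from percent-active summaries, which are
computed over pool-detected guides only. OAS is invariant under uniform
scaling of pool counts. Kendall tau-b (tie-corrected) relates OAS to
external predicted-activity scores; it is computed with
`scipy.stats.kendalltau(variant="b")` and cross-checked in the tests
against an all-pairs enumeration.

## Synthetic data: what it does and does not emulate

Each simulated gene is built in transcript orientation as
pad–exon1–intron–exon2–intron–exon3–pad, with 8/10/4 planted "PAM blocks"
(random 20-mer + NGG, 23 nt each) in the three exons, so every target exon
offers well over the 5 + margin sites needed and designability is
guaranteed by construction. A second isoform trims exon 1 by 3 nt (leaving
exons 2–3 shared) or, for a configurable fraction of genes (default 10 %),
trims every exon so no exon is shared and the fallback tier is exercised.
Imported-guide candidates come from exon 3, disjoint from the designed
set. Genes alternate strands and are spread over 8 chromosomes. Every
20-mer in the genome is unique — enforced by rejection sampling during
construction, junctions included — unless duplicate protospacer copies are
explicitly planted, so the built-in specificity scorer returns 100 for all
natural candidates.

Pool reads are flank + protospacer + flank drawn multinomially from uniform
or log-normal(σ = 0.5) abundances at a default depth of 10⁵. Editing
simulations emit, per site and replicate, 500 read pairs by default:
edited pairs carry a deletion of 1–20 nt or insertion of 1–10 nt at
cut ± 2 encoded in the CIGAR and are flagged non-proper; unedited pairs
are proper and gapless. A fixed per-site background deletion (length 23,
chosen so its event key can never collide with a simulated edit) appears
in both edited and control samples, and the control always witnesses each
background key so subtraction is exact rather than sampling-dependent.
Duplicate flags and MAPQ values of 37/20 are planted on 5 % of edited
reads each to exercise the filters, and MAPQ 38 sits exactly at the
retention boundary in the unit tests.

Deliberately not modelled: sequencing errors and quality scores, PCR bias
beyond the abundance distribution, substitution/HDR outcomes, off-target
editing, and in/dels longer than 20 nt in simulated reads (long-deletion
handling up to the 2,000 bp cap is unit-tested on hand-written records
instead). Passing tests therefore demonstrate the correctness of the
bookkeeping, coordinate arithmetic, filtering and normalisation — not
robustness to alignment artefacts or error-rich real data.

## Problem sizes and determinism

The study-scale runs use 450 genes (3,150 guides), representation QC uses a
105-guide pool at 10⁵ reads, and edit-rate recovery uses rates
{0, 0.05, 0.3, 0.7} at 500 read pairs per guide over 20 seeded runs —
sizes chosen to mirror the emulated design while keeping a full run in
seconds. All randomness flows from explicit seeds; a given seed reproduces
every emitted file byte-for-byte.

## Known limitations

- The built-in specificity score is a structural placeholder; real designs
  should supply external scores per protospacer.
- "Shared exon" requires exact CDS-interval identity; boundary-shifted but
  sequence-identical exons are treated as unshared.
- Control subtraction is exact-key; a control sequenced much shallower than
  the edited samples will under-subtract.
- Probe regions assume sites more than ~1 kb from chromosome starts except
  for explicit clipping at position 1; no clipping at chromosome ends is
  applied.
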