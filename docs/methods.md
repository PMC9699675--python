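# Methods

This note documents the models, conventions and deliberate design choices
behind each stage of the pipeline, and what the synthetic-data tests do and
do not demonstrate about real data.

## Coordinates and alphabets

All coordinates are 0-based, half-open, on the sense strand. 3′UTRs and
octamers are DNA (T); mature miRNAs are RNA (U); converters live in
`sequtils`. MREs function on the mRNA sense strand, so UTRs are never
scanned on the reverse strand.

## MRE definition and controls

The response element is the canonical 8mer-A1 site: the DNA reverse
complement of miRNA positions 2–8 (1-based) plus a trailing adenosine,
written 5′→3′ on the target mRNA. The trailing A is recognized positionally
by the silencing complex rather than through base pairing, so it is held
fixed everywhere: control octamers must end in A, and the one-off
enumeration (octamers one A-to-I event away from an MRE) never substitutes
it. The reverse-direction control set replaces one non-terminal A with G — a
change A-to-I editing cannot produce.

Control octamers preserve the source's dinucleotide multiset. Because the
octamers are only 8 nt, the implementation enumerates *all* Euler paths of
the dinucleotide de Bruijn multigraph exhaustively (at most 7! paths),
filters to those ending in A, differing from the source and avoiding every
annotated MRE, and samples without replacement. This gives exact sampling
semantics with no rejection loop; an infeasible source (e.g. a homopolymer)
yields an explicit empty result.

Windows containing N never match during scanning — conservative handling of
assembly gaps. Identical octamers arising from paralogous miRNAs are kept
per-miRNA by the pipeline (each miRNA's sites are tabulated separately);
`conservation_rates` deduplicates octamer *strings* within one call.

## UTR alignment and conservation

Orthologous UTR pairs are aligned globally with affine gap penalties
(match +1, mismatch −1, gap open −10, gap extend −0.5; a length-L gap costs
10 + 0.5·L). The engine is Biopython's `PairwiseAligner`; the first optimal
alignment is always taken, so results are deterministic. Precomputed
alignments (aligned FASTA / gapped string pairs) are accepted anywhere an
alignment is consumed, so externally aligned data can be scored unchanged.

"Same position" means same alignment columns: an occurrence is conserved iff
its eight reference positions occupy eight consecutive columns, gap-free in
both rows, and the ortholog characters spell the identical octamer. An indel
inside the window breaks conservation even when the flanks match, because it
changes the site itself. Occurrences are counted independently (multiple
occurrences per gene all count), and octamers observed fewer than 10 times
across the alignment set are flagged excluded from rate panels. Windows that
would run past the UTR end cannot arise from exact scanning and are tallied
separately as a safeguard.

## Codetection and group statistics

A miRNA–mRNA pair is codetected when at least one tissue has the miRNA at
≥ 100 CPM and the mRNA at ≥ 10 CPM simultaneously; comparisons are inclusive
("recovered at" a threshold includes the threshold). CPM is consumed, not
computed; `coexpression.cpm` converts raw counts when needed.

Arm scores from the 2×2 table are exact-match fractions; an empty arm is
`None` (undefined), never 0. Z-scores standardize one plotted panel — the
per-miRNA MRE scores together with their control rates — using the
population SD; this choice (which set defines the reference population is
otherwise open) centres control bars near zero. Group comparisons are
two-sided Mann–Whitney U tests; the Bonferroni factor is the number of
pairwise comparisons actually performed in the panel, capped at 1. Fully
tied inputs carry no rank information and are reported as p = 1. Both
site-level and gene-level counts are emitted so either pooling convention
can be inspected.

## Editing

"More than 10 reads" is strict (≥ 11) everywhere it occurs. An editing site
requires reference A, coverage ≥ 11, G ≥ 3 and absence from the DNA-variant
exclusion set (a precomputed position set; variant calling itself is out of
scope). The editing index is ΣG / Σ(A+G) over reference-A positions — C/T
reads are treated as sequencing error and excluded from the denominator —
which equals the coverage-weighted mean of per-site G fractions. Seed
editing summaries take, per miRNA, the maximum G proportion over reference-A
seed positions (2–8) with coverage ≥ 11, computed from per-position base
counts over the mature reference. The MRE coverage filter for the
editing/MRE intersection defaults to the *mean* of the eight positions
(≥ 11); "total coverage per 8-mer" is ambiguous between mean, minimum and
overlapping-read count, so minimum is available behind a flag.

## Splicing rates

Junctions concatenate up to 42 nt from each side (shorter exons contribute
their full length). Effective mappability is the number of fully contained
50-mers that occur exactly once across the entire junction set — a
deterministic exact-match unique-hit lookup rather than an external
aligner — giving at most 84 − 50 + 1 = 35 per junction; counts are adjusted
by 35/m and triplets with any junction below mappability 20 are excluded.
The rES and rIR formulas are implemented in their only [0,1]-bounded
reading; the major-junction eligibility rule (≥ 5 raw reads on E1E2+E2E3 for
ES, E1I+IE2 for IR) is read with E2E3 where the source text's "E2E2" is an
evident typo. The cross-tissue protocol samples, per repetition, 1000
eligible triplets without replacement and exactly 25,000 reads multinomially
(with replacement — the read-level resampling convention is not fixed by the
formulas) over the sampled triplets' raw junction counts, adjusts, computes
per-triplet rates and records their mean; 100 repetitions per tissue.

## 3′-end clustering

Pass 1 chains tags with pairwise distance < 20 bp (single linkage — chains
can span more than 20 bp in total, which the pairwise rule permits) and
assigns counts to the highest-count member, ties broken to the 3′-most
position on the tag's strand. Pass 2 merges clusters whose *representatives*
(not edges — the alternative is noted as open) are < 40 nt apart, keeping
the higher-count representative. Both passes conserve total counts. Cluster
filtering requires continuous short-read coverage ≥ 5 from the
representative to the assigned upstream stop codon, or a member read
overlapping the stop codon (tags may carry a read-start coordinate for this
purpose). The PAS table defaults to the 12 canonical metazoan hexamers
(AATAAA first) and is configurable; with multiple matches in the 50 nt
upstream window the dataset-wide most frequent motif wins.

## Synthetic data: what it emulates, and what it does not

The generators plant known parameters and are fully deterministic per
config + seed (each generator draws from its own stream spawned from
`rng_seed`).

- **UTR pairs.** Lengths are log-normal with median 350 nt (matching the
  reported median 3′UTR length of ~350–380 nt); background sequence is
  i.i.d. uniform. Orthologs differ by per-site substitutions (default 0.05)
  and 1–3 nt indels (default 0.01/site) — round numbers of the right order
  for closely related congeneric species, chosen once. Planted sites are
  copied intact with the arm's conservation probability; otherwise at least
  one substitution is forced inside the octamer. Indels never land inside
  planted octamers, so conservation truth is decided by substitutions alone
  and the generative alignment is exact.
- **Codetection realization.** Each synthetic miRNA is highly expressed
  (≥ 100 CPM) in exactly one tissue; a pair is codetected iff its gene
  clears 10 CPM there. When a gene's value in that tissue is already pinned
  by an earlier pair, later pairs take the implied label, keeping labels
  consistent with the expression matrices by construction.
- **Editing.** G counts are binomial at the planted fraction; DNA-variant
  positions get a heterozygous-like G proportion (~0.5) and must be rejected
  downstream.
- **Junctions.** Reads are multinomial over the three junctions with
  expected proportions chosen so the rate formula equals the planted value
  in expectation.

Real data differ in ways the generator deliberately ignores: compositional
bias and repeats (which depress alignability and mappability), rate
heterogeneity along UTRs, expression correlation structure across tissues,
sequencing error, and mapping artifacts. Passing tests therefore demonstrate
the *estimators* are correct and well-calibrated under their stated
assumptions, not that those assumptions hold in any particular dataset.

## Problem sizes and numerical choices

Parameter-recovery tests use 1,100 genes × 4 sites (≈ 2,200 sites per
codetection arm) over 20 seeds, with a 3-binomial-SE acceptance band per
arm — small enough to run comfortably on a laptop, large enough that the
planted 0.6/0.4 differential is detected at p < 0.001. Subsampling
comparisons use 400 generated triplets, 300 sampled per repetition, 10,000
reads, 50 repetitions. Scores are never rounded internally; the worked
example rounds to 3 decimals only for display. Division-by-zero cases
(empty arms, zero-coverage features, zero-mappability junctions with zero
reads) return explicit undefined markers rather than 0.

## Known limitations

- The alignment engine's tie-break among co-optimal alignments is the
  library's internal (deterministic) choice; co-optimal ties can in
  principle flip individual conservation calls near indels.
- Ortholog inference, CDS-to-genome mapping, read alignment, variant
  calling and isoform reconstruction are out of scope; the pipeline consumes
  their outputs (ortholog tables, pileups, junction counts, tags).
- Only exact 8-mer matches are scored: no 6mer/7mer site classes, no
  thermodynamics, no 3′-supplementary pairing.
- `mirna_seed_editing` consumes per-position base counts; it does not model
  the upstream read-mapping step (≤ 2 mismatches, unique hits) beyond its
  output.
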