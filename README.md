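# octomir

Reusable, tested implementations of the computational analyses used to study
the expanded miRNA repertoire of octopuses: miRNA response-element (MRE)
derivation and cross-species conservation scoring in orthologous 3′UTRs,
conditioned on miRNA–mRNA coexpression and compared against
dinucleotide-preserving control 8-mers; A-to-I editing site calling, editing
indices and editing/MRE intersection; mappability-adjusted exon-skipping and
intron-retention rates with a cross-tissue subsampling protocol; and
3′-end tag clustering with poly(A)-signal assignment. Every stage can be
exercised end-to-end on synthetic data with known planted parameters, so the
whole pipeline is testable without any external dataset.

It is written for computational biologists who want to apply (or audit) these
analyses on their own two-species UTR, expression, pileup, junction-count or
3′-end tag data.

## The statistics at the core

**MRE conservation.** For a mature miRNA with sequence *m*, the response
element is the 8mer-A1 site: the DNA reverse complement of seed positions
2–8 followed by a trailing adenosine (for let-7,
`UGAGGUAGUAGGUUGUAUAGUU` → `CTACCTCA`). An occurrence of this octamer at
position *p* of a reference 3′UTR counts as *conserved* when the global
pairwise alignment of the two orthologous UTRs places exactly the same
octamer in eight consecutive, gap-free columns at the homologous position.
Sites are split by *codetection* — the miRNA ≥ 100 CPM and the mRNA ≥ 10 CPM
in at least one shared tissue — into a 2×2 table, and each arm's
conservation score is

    score = n_exact_match / (n_exact_match + n_mismatch).

Scores are standardized to Z-scores per panel and groups are compared with
two-sided Mann–Whitney U tests under Bonferroni correction. Controls are
dinucleotide-preserving shuffles of the real MREs (Euler paths over the
dinucleotide de Bruijn multigraph) constrained to end in A.

**A-to-I editing.** A reference-A position is an editing site when it has
more than 10 mapped reads, at least 3 of them G, and is not a genomic DNA
variant. The per-feature editing index is ΣG / Σ(A+G) over reference-A
positions.

**Splicing rates.** For exon triplets (E1, E2, E3) with junction read counts
N adjusted by 35/mappability (mappability = uniquely occurring contained
50-mers, at most 35 per 84 nt junction):

    rES = N_E1E3 / ((N_E1E2 + N_E2E3)/2 + N_E1E3)
    rIR = mean(N_E1I, N_IE2) / (mean(N_E1I, N_IE2) + N_E1E2)

**3′-end clustering.** Tags closer than 20 bp merge to their most supported
member; clusters with representatives closer than 40 nt merge again; the
poly(A) signal is the hexamer in the 50 nt upstream window, dataset-wide
abundance breaking ties.

## Worked example

Parameter recovery on synthetic data — 400 genes, 12 miRNAs, planted
conservation probability 0.6 for codetected sites and 0.4 for
non-codetected sites:

```python
from octomir import pipeline
from octomir.synthetic import SyntheticConfig

cfg = SyntheticConfig(n_genes=400, n_mirnas=12, sites_per_gene=3, rng_seed=7)
rec = pipeline.recover_planted_rates(cfg)
print(f"codetected arm:     {rec.rate_codetected:.3f}  (n={rec.n_codetected} sites)")
print(f"non-codetected arm: {rec.rate_noncodetected:.3f}  (n={rec.n_noncodetected} sites)")
c = rec.comparison
print(f"Mann-Whitney U={c.u_statistic:.1f}, p={c.p_bonferroni:.2e} -> {c.label}")
```

prints

```
codetected arm:     0.630  (n=598 sites)
non-codetected arm: 0.365  (n=602 sites)
Mann-Whitney U=143.0, p=4.62e-05 -> ***
```

The two arms recover the planted probabilities within binomial sampling
error (3·SE ≈ 0.06 at n ≈ 600), and the per-miRNA score groups separate at
p < 0.001 — the effect direction the conservation analysis is designed to
detect. The same machinery runs on real inputs: FASTA for sequences, TSV for
CPM matrices and pileups, BED-like TSV for 3′-end tags.

A `octomir` command-line tool exposes the stages (`synth`, `mre`, `conserve`,
`coexpr`, `edit`, `splice`, `polya`, `run-all`); `octomir run-all --seed 5`
runs everything on synthetic inputs and prints a JSON report.

## Layout

- `src/octomir/synthetic.py` — generators for every input, with planted truth
- `src/octomir/seed_targets.py` — MRE derivation, UTR scanning, shuffled controls, one-off octamers
- `src/octomir/conservation.py` — pairwise UTR alignment and k-mer conservation rates
- `src/octomir/coexpression.py` — codetection, 2×2 tables, scores, Z-panels, group tests
- `src/octomir/editing.py` — editing-site calling, indices, MRE intersection
- `src/octomir/splicing.py` — junction triplets, mappability, rES/rIR, subsampling
- `src/octomir/polya.py` — 3′-end tag clustering and PAS assignment
- `src/octomir/pipeline.py`, `src/octomir/cli.py` — orchestration and CLI

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
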