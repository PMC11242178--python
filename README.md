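# methylbloom

Tools for asking whether DNA methylation of specific genes tracks a plant
phenotype — built around the Arabidopsis flowering-time setting, where
gene-body CG methylation of upstream autonomous-pathway regulators (*FVE*,
*FY*, *FLD*, *PEP*, *HDA5*, *PRP39-1*) varies across natural accessions
together with flowering time and gene expression.

The package covers four analysis stages plus a ground-truth simulator:

1. **Sequence contexts and regions** (`sequence_context`) — classify every
   cytosine as CG / CHG / CHH (H ∈ {A, C, T}) on either strand, and compute
   gene-body (CDS) and promoter (1500 bp upstream of ATG) windows with
   strand-aware, 0-based half-open arithmetic.
2. **Methylome summaries** (`methylome_summary`) — load allc-style
   per-cytosine call TSVs and produce per-gene, per-context
   methylated/total site counts. The headline statistic is **mC**, the
   total number of methylated sites in a gene's coding region; fractional
   levels m_c / n_c are emitted alongside.
3. **Association statistics** (`association`) — Spearman/Pearson
   correlation of methylation matrices against flowering time or leaf
   number (exact permutation p-values for n ≤ 8), a per-gene p < 0.05
   screen with Benjamini–Hochberg q-values, the 2^−ΔΔCt qPCR
   fold-change, Mann–Whitney U (exact by enumeration for combined n ≤ 12),
   and range/spread descriptives for treatment-compression claims.
4. **Bisulfite clone calling** (`bisulfite_clone_caller`) — per-site
   retention tallies across pre-aligned cloned bisulfite amplicons, with
   the 50% (CG) / 20% (CHG) / 20% (CHH) inclusive thresholds, plus
   shared-vs-novel site-set comparison between samples.
5. **Codon recoding** (`codon_recoding`) — the cytosine-depletion design:
   synonymously recode a CDS to minimize theoretically methylatable
   cytosines (greedy per-codon `min_C`, or a dynamic program `min_C_dp`
   that is provably optimal for the context-aware objective across codon
   junctions), with the codon adaptation index
   CAI = (∏ᵢ wᵢ)^(1/N) tracking how far recoding drifts codon usage.
6. **Synthetic cohorts** (`synthetic_data`) — generate genomes, gene
   models, per-accession methylomes in which causal-gene CG methylation
   drives flowering time linearly, expression negatively coupled to
   methylation, a 14–56% per-gene demethylation perturbation, and
   bisulfite clone reads with configurable conversion efficiency — all
   with a truth JSON for every latent variable.

## Worked example

```python
from methylbloom.synthetic_data import SimulationConfig, generate_study
from methylbloom.association import correlation_screen

study = generate_study(SimulationConfig(seed=3))   # 27 accessions, 27 genes, 6 causal
f = study.phenotype["flowering_days"]
print(round(f.min(), 1), "-", round(f.max(), 1))   # 18.7 - 52.6 days

screen = correlation_screen(study.mc_matrix, f)    # Spearman, p < 0.05
print(int(screen.loc[study.causal_genes, "significant"].sum()))          # 6
print(int(screen.drop(study.causal_genes)["significant"].sum()))         # 1
```

The cohort flowers between ~19 and ~53 days; the screen recovers all 6
methylation-coupled genes and flags 1 of the 21 null genes (consistent
with the 5% false-positive rate the p < 0.05 rule implies).

Recoding a CDS:

```python
from methylbloom.codon_recoding import recode_minimize_cytosines
r = recode_minimize_cytosines("ATGCTGTGCTGGTAA")
print(r.recoded_cds)                      # ATGTTGTGTTGGTAA
print(r.cytosines_before, r.cytosines_after)  # 2 0
```

A command-line interface mirrors the library:
`methylbloom simulate | annotate-contexts | summarize | associate |
call-clones | recode` (see `methylbloom --help`).

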