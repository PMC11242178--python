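# Methods

## Cytosine contexts and region arithmetic

A cytosine's methylation context is decided by the two bases 3′ of it on
its own strand: CG if the next base is G, CHG if the next is H (A/C/T) and
the one after is G, CHH if both are H. Reverse-strand sites anchor at Gs of
the forward sequence, with the trinucleotide read on the reverse
complement. Two edge rules are fixed here because no universal convention
exists: (i) a cytosine whose flank is truncated by the end of the supplied
sequence is classified UNKNOWN and excluded from methylatable-site counts
(with one exception — a terminal `CG` dinucleotide is already decided);
(ii) an N anywhere in the flank yields UNKNOWN, never matching H or G.
Because region summaries classify contexts on the extracted region
sequence, sites within 2 bp of a region edge are region-locally UNKNOWN
even when the chromosome continues; the generator and the summarizer share
this rule, so denominators are consistent end to end.

Coordinates are 0-based half-open internally; GFF3 I/O converts at the
boundary. Promoters are the 1500 bp immediately 5′ of the start codon
(`[atg−1500, atg)` on +, `[atg+1, atg+1501)` on −), clipped to chromosome
bounds with the clipping reported. Gene bodies default to the CDS span;
a `cds_only=False` switch includes intronic cytosines of the genomic
footprint. Both strands are enumerated by default, matching allc-style
per-cytosine call files.

## Methylome summaries

Inputs are per-cytosine call tables (chrom, 1-based position, strand,
context, 0/1 call, optional counts). Files that list only methylated sites
are the norm, so a reference site absent from the file counts as
unmethylated by default; `missing="no_coverage"` instead drops it from the
denominator. When count columns are present without a binary call, the
call is mc/total ≥ 0.5. When a record's context disagrees with the
reference-derived context, the reference wins with a warning (the genome
is the arbiter of sequence context).

The primary per-gene statistic is **mC**, the methylated-site count over
CG+CHG+CHH in the region — the quantity the phenotype screen consumes.
Fractional levels per context are first-class outputs as well, because
count- and level-language are both used for this kind of analysis; the
count is the default because it is well defined even when contexts have
few sites.

## Association statistics

Spearman is the default correlation (rank-based, robust for cohorts of a
few dozen accessions with skewed flowering times); Pearson is available.
For n ≤ 8 the Spearman p-value is exact, by enumerating all n! pairings of
the rank vectors (average ranks for ties) and counting |ρ| at least the
observed. The per-gene screen flags raw p < α (α = 0.05), which is the
faithful screening rule for this analysis style; Benjamini–Hochberg
q-values are reported alongside but deliberately do not drive the default
flags.

Mann–Whitney U is exact for combined n ≤ 12 by enumerating all
C(n₁+n₂, n₁) labelings of the pooled midranks and counting labelings with
|U − n₁n₂/2| at least the observed deviation (a two-sided permutation
test that remains exact under ties); larger samples use the normal
approximation with tie correction.

The 2^−ΔΔCt fold change averages ΔCt = Ct(target) − Ct(reference) over
replicates within each group before differencing — not the mean of
per-replicate fold changes — because the geometric scale of Ct makes the
ΔCt mean the natural estimator. Replicate SDs combine in quadrature and
propagate to a [fold/2^sd, fold·2^sd] range.

## Bisulfite clone calling

At each reference cytosine the clones are tallied as retained (C),
converted (T) or ambiguous (anything else). The retention fraction
excludes ambiguous reads from the denominator, so sequencing errors do not
dilute the signal. A site is called methylated when the fraction reaches
its context threshold — 0.50 for CG, 0.20 for CHG/CHH — compared
**inclusively**, so a 5-of-10 CG site is called; strictness is not
universally specified for this assay and the inclusive rule matches common
clone-sequencing practice. Positions where ambiguous reads reach half the
clones are flagged low-quality and never called. Per-clone QC drops clones
with >10% non-C/T bases at reference-C positions; an optional (default
off) filter drops clones whose non-CG retention exceeds 0.9 as
conversion failures. Clones must be pre-aligned to the reference;
alignment is upstream of this package.

## Codon recoding

Every fully-flanked cytosine of a CDS falls in some CG/CHG/CHH context, so
"minimize methylatable sites" on the coding strand reduces to minimizing
cytosines, which is separable per codon: `min_C` greedily picks, per amino
acid, the synonym with the fewest Cs (fewest C+G in duplex mode, where
reverse-strand cytosines also count). `min_C_dp` instead scores the
context-aware objective — fully-flanked sites in the concatenated
sequence, whose windows couple adjacent codons (a C near a codon's 3′ end
reads into the next codon; a duplex G near the 5′ end reads into the
previous) — by a Viterbi pass over codon choices, with boundary terms for
flank truncation at the CDS ends. The two objectives differ only through
those junction/end effects, but the DP carries a global-optimality
guarantee that the exhaustive-enumeration tests verify.

The start codon is never altered; stop codons are kept unless stop swaps
are enabled (no stop contains C, so the objective never needs them). Ties
between equally cytosine-poor synonyms prefer the highest relative
adaptiveness w, then the lexicographically smallest codon — keeping CAI
drift small, in line with the observation that a cytosine-depleted design
can retain near-original codon adaptation.

CAI is the geometric mean of w = f(codon)/max f(synonyms) over the CDS,
excluding Met, Trp and stops (standard convention: single-codon families
carry no information). It is computed in log space. The bundled
A. thaliana usage table holds representative genome-wide frequencies per
1000 codons and is explicitly a replaceable default (`codon_usage_athaliana.tsv`,
version athaliana-bundled-v1): CAI values are only comparable under a
stated usage table, so exact reproduction of any particular published CAI
requires supplying that study's table.

## Synthetic cohorts

The generator emulates the study design the analysis modules target, with
defaults chosen once as the package's study conditions:

- **Cohort**: 27 accessions, 27 genes, 6 causal; single-exon CDSs of
  100–300 codons on random strands, spaced 1700 bp so promoter windows
  never overlap genes.
- **Methylation**: a latent accession factor u ~ U(0,1) sets every causal
  gene's CG propensity p = 0.05 + 0.55·clip(u + jitter), jitter sd 0.05 —
  late-flowering accessions are coherently hypermethylated across causal
  genes, which is what makes a per-gene screen at n = 27 well powered.
  Null genes draw independent propensities with the same marginal
  distribution, giving an honest type-I-error control check. CHG/CHH and
  promoter sites are sparsely (0.02 / 0.05) and independently methylated,
  mirroring CG dominance of plant gene-body methylation.
- **Phenotype**: flowering = 12.0 + 0.13 × (total causal-gene body mC)
  + N(0, 2²) days; the slope and intercept were set so the default cohort
  spans roughly 19–55 flowering days. Leaf count tracks flowering at 0.5
  leaves/day with unit noise.
- **Expression**: 60 − 1.0 × mC + N(0, 3²), floored at 0 — a linear
  negative coupling for every gene.
- **Demethylation treatment**: per gene, a fraction f ~ U(0.14, 0.56) of
  methylated body sites is removed uniformly at random; the removal count
  is clamped so the realized fraction stays inside [0.14, 0.56] whenever
  the gene's mC makes that possible (a gene with 1–2 methylated sites
  cannot realize a 35% reduction).
- **Clones**: a molecule retains each methylated C; unmethylated Cs
  convert to T with the conversion efficiency (default 1.0) and otherwise
  stay C; sequencing error (default 0.1%) then substitutes bases uniformly,
  exercising the caller's ambiguous-base path.

Everything is driven by one seed and is byte-reproducible. The truth JSON
records the causal set, every propensity, every per-gene mC and the
phenotype, so downstream checks can be computed without re-running the
pipeline.

What the simulator does **not** model: sequence polymorphism between
accessions, read-level coverage and mC-calling error, spatial correlation
of methylation along genes, and any nonlinearity in the
methylation–phenotype map. Tests passing on these cohorts demonstrate the
statistical machinery is correct under the stated generative model, not
that the pipeline is robust to those real-data complications.

## Problem sizes and numerical choices

The replicate-based operating-characteristics estimate uses 500 cohort
replicates over one fixed genome (power and type-I error are cohort-level
properties; regenerating the genome each replicate would only add gene-
panel noise). The clone-calling calibration uses 1000 simulated clone
sets; oracle-agreement checks use 1000 random 50-mers and 1000 random
CDSs. Exhaustive-enumeration comparisons cap CDSs at 8 codons (up to 6⁶
synonymous combinations). Exact permutation statistics switch to
asymptotics above n = 8 (Spearman) and combined n = 12 (Mann–Whitney).
Floating-point tie comparisons in enumeration use 1e-9–1e-12 slack; the
DP's adaptiveness tie-break rounds −log w to 12 decimals to stabilize
ordering.

## Known limitations

- Region-local UNKNOWN classification at region edges (above) differs by
  up to 2 sites per region end from a whole-chromosome classification.
- The clone caller requires pre-aligned clones and does not handle indels.
- The bundled codon-usage table is approximate; CAI values under it are
  internally consistent but not comparable to values computed under other
  tables.
- The recoder optimizes cytosine content only — it ignores mRNA structure,
  GC content, splice signals and restriction sites.
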