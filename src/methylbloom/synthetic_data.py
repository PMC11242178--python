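"""Synthetic study generator with known ground truth.

Emulates the structure of a multi-accession Arabidopsis flowering-time
methylation study: a small genome of protein-coding genes, per-accession
gene-body methylomes in which a subset of "causal" genes carries an
accession-wide CG-methylation state that drives flowering time linearly,
expression negatively coupled to gene-body methylation, a demethylating
(5-azaC-style) perturbation that thins methylated sites per gene by a
uniform 14–56% fraction, and bisulfite clone reads with configurable
conversion efficiency and sequencing error.

What the generator reproduces and what it does not: per-accession
methylation of causal genes is driven by a shared accession-level factor
(late-flowering accessions are hypermethylated across all causal genes at
once), phenotype is linear in the total causal methylated-site count with
Gaussian noise, and CHG/CHH sites are sparsely and independently
methylated, mirroring the CG-dominance of plant gene-body methylation.
There is no sequence variation between accessions, no read-level coverage
model, and no spatial autocorrelation of methylation along a gene — so
passing tests demonstrate correct statistical machinery, not robustness to
those real-data complications.

Every operation takes the config seed (or an explicit ``numpy`` Generator)
and is byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .methylome_summary import MethylomeRecord, write_methylome
from .sequence_context import (
    CG,
    UNKNOWN,
    CytosineSite,
    GeneModel,
    GenomicRegion,
    enumerate_cytosine_sites,
    write_fasta,
)

_SENSE_CODONS = tuple(
    sorted(
        c
        for c in ("".join(t) for t in product("ACGT", repeat=3))
        if c not in ("TAA", "TAG", "TGA")
    )
)
_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a 27-accession cohort whose flowering times span
    roughly 19–55 days, driven by the CG gene-body methylation of 6 causal
    genes out of 27, with a 14–56% per-gene methylation reduction under the
    demethylating treatment and 10 bisulfite clones per sample.
    """

    seed: int = 0
    # cohort
    n_accessions: int = 27
    n_genes: int = 27
    n_causal: int = 6
    # genome
    cds_codons_range: tuple[int, int] = (100, 300)  # codons incl. start/stop
    intergenic: int = 1700       # bp between genes; > promoter length 1500
    genes_per_chrom: int = 50
    promoter_length: int = 1500
    # methylation propensities
    cg_propensity_range: tuple[float, float] = (0.05, 0.60)
    accession_factor_jitter: float = 0.05
    non_cg_propensity: float = 0.02
    promoter_propensity: float = 0.05
    # phenotype: flowering = baseline + effect * sum(causal mC) + noise
    baseline_days: float = 12.0
    effect_days_per_site: float = 0.13
    phenotype_sd: float = 2.0
    leaves_per_day: float = 0.5
    # expression: expr = baseline - slope * mC + noise, floored at 0
    expression_baseline: float = 60.0
    expression_slope: float = 1.0
    expression_sd: float = 3.0
    # bisulfite clones
    conversion_efficiency: float = 1.0
    n_clones: int = 10
    sequencing_error: float = 0.001
    # demethylating treatment
    azaC_reduction_range: tuple[float, float] = (0.14, 0.56)

    def __post_init__(self) -> None:
        if not (0 < self.n_causal <= self.n_genes):
            raise ValueError("need 0 < n_causal <= n_genes")
        for p in (
            *self.cg_propensity_range,
            self.non_cg_propensity,
            self.promoter_propensity,
            self.conversion_efficiency,
            *self.azaC_reduction_range,
        ):
            if not (0 <= p <= 1):
                raise ValueError(f"probability {p} outside [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SimulatedGenome:
    sequences: dict[str, str]
    genes: list[GeneModel]

    def gff3(self) -> str:
        lines = ["##gff-version 3"]
        for chrom, seq in self.sequences.items():
            lines.append(f"##sequence-region {chrom} 1 {len(seq)}")
        for g in self.genes:
            r = g.region
            s, e = r.start + 1, r.end  # to 1-based inclusive
            attrs = f"ID={g.gene_id}"
            lines.append(
                f"{r.chrom}\tmethylbloom\tgene\t{s}\t{e}\t.\t{r.strand}\t.\t{attrs}"
            )
            lines.append(
                f"{r.chrom}\tmethylbloom\tmRNA\t{s}\t{e}\t.\t{r.strand}\t.\t"
                f"ID={g.gene_id}.1;Parent={g.gene_id}"
            )
            for cs, ce in sorted(g.cds_segments):
                lines.append(
                    f"{r.chrom}\tmethylbloom\tCDS\t{cs + 1}\t{ce}\t.\t{r.strand}\t0\t"
                    f"ID={g.gene_id}.1.cds;Parent={g.gene_id}.1"
                )
        return "\n".join(lines) + "\n"

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.sequences, out / "genome.fasta")
        (out / "genes.gff3").write_text(self.gff3())


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    stop = _STOPS[rng.integers(len(_STOPS))]
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + stop


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _revcomp(seq: str) -> str:
    from .sequence_context import reverse_complement

    return reverse_complement(seq)


def generate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedGenome:
    """Random genome: one chromosome per ``genes_per_chrom`` genes.

    Each gene is a single-exon CDS (valid start, no internal stops,
    terminal stop), placed on a random strand with enough intergenic
    spacing that no promoter window overlaps a neighboring gene.
    """
    rng = config.rng() if rng is None else rng
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    gene_idx = 0
    n_chroms = -(-config.n_genes // config.genes_per_chrom)
    lo, hi = config.cds_codons_range
    for c in range(n_chroms):
        chrom = f"chr{c + 1}"
        parts: list[str] = []
        cursor = 0
        on_this = min(config.genes_per_chrom, config.n_genes - gene_idx)
        for _ in range(on_this):
            pad = config.intergenic
            parts.append(_random_seq(rng, pad))
            cursor += pad
            n_codons = int(rng.integers(lo, hi + 1))
            cds = _random_cds(rng, n_codons)
            strand = "+" if rng.random() < 0.5 else "-"
            genomic = cds if strand == "+" else _revcomp(cds)
            start, end = cursor, cursor + len(genomic)
            parts.append(genomic)
            cursor = end
            atg = start if strand == "+" else end - 1
            gene_id = f"gene{gene_idx + 1:03d}"
            genes.append(
                GeneModel(
                    gene_id,
                    GenomicRegion(chrom, start, end, strand),
                    atg,
                    ((start, end),),
                )
            )
            gene_idx += 1
        parts.append(_random_seq(rng, config.intergenic))
        sequences[chrom] = "".join(parts)
    return SimulatedGenome(sequences=sequences, genes=genes)


@dataclass
class _GeneSites:
    """Cached per-gene site arrays for fast per-accession sampling."""

    body_sites: list[CytosineSite]
    body_contexts: np.ndarray       # int codes: 0 CG, 1 CHG, 2 CHH, 3 UNKNOWN
    promoter_sites: list[CytosineSite]


_CTX_CODE = {CG: 0, "CHG": 1, "CHH": 2, UNKNOWN: 3}


def _gene_site_cache(genome: SimulatedGenome, config: SimulationConfig) -> dict[str, _GeneSites]:
    from .sequence_context import promoter_region

    cache: dict[str, _GeneSites] = {}
    for gene in genome.genes:
        chrom_seq = genome.sequences[gene.region.chrom]
        body = enumerate_cytosine_sites(
            chrom_seq[gene.region.start : gene.region.end],
            gene.region.chrom,
            strands="both",
            offset=gene.region.start,
        )
        window = promoter_region(gene, len(chrom_seq), config.promoter_length)
        prom = enumerate_cytosine_sites(
            chrom_seq[window.region.start : window.region.end],
            gene.region.chrom,
            strands="both",
            offset=window.region.start,
        )
        cache[gene.gene_id] = _GeneSites(
            body_sites=body,
            body_contexts=np.array([_CTX_CODE[s.context] for s in body]),
            promoter_sites=prom,
        )
    return cache


@dataclass
class SimulatedStudy:
    """A generated cohort plus its ground truth."""

    genome: SimulatedGenome
    config: SimulationConfig
    accessions: list[str]
    causal_genes: list[str]
    mc_matrix: pd.DataFrame          # accession x gene: total methylated sites, gene body
    mc_cg_matrix: pd.DataFrame       # accession x gene: CG methylated sites only
    phenotype: pd.DataFrame          # accession, flowering_days, leaf_count
    expression: pd.DataFrame         # accession x gene
    methylomes: dict[str, list[MethylomeRecord]] | None
    truth: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.genome.write(out)
        self.phenotype.to_csv(out / "phenotype.csv", index=True, index_label="accession")
        self.expression.to_csv(out / "expression.tsv", sep="\t", index_label="accession")
        if self.methylomes is not None:
            meth_dir = out / "methylomes"
            meth_dir.mkdir(exist_ok=True)
            for accession, records in self.methylomes.items():
                write_methylome(records, meth_dir / f"{accession}.tsv")
        (out / "truth.json").write_text(json.dumps(self.truth, indent=1, sort_keys=True))


def generate_methylomes(
    genome: SimulatedGenome,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    materialize: bool = True,
) -> SimulatedStudy:
    """Per-accession methylomes coupled to a flowering phenotype.

    For each accession *i*, a latent methylation factor u_i ~ U(0,1) sets
    the CG propensity of every causal gene (with per-gene jitter); CG sites
    are then methylated independently with that propensity, CHG/CHH and
    promoter sites with small context-independent propensities. Flowering
    time is baseline + effect x (total causal-gene body mC) + Gaussian
    noise; leaf count tracks flowering; expression of every gene declines
    linearly in its own body mC. With ``materialize=False`` only the
    matrices and truth are produced (no site-level records), which is the
    fast path for replicate simulations.
    """
    rng = config.rng() if rng is None else rng
    cache = _gene_site_cache(genome, config)
    accessions = [f"acc{i + 1:02d}" for i in range(config.n_accessions)]
    gene_ids = [g.gene_id for g in genome.genes]
    causal = gene_ids[: config.n_causal]
    p_lo, p_hi = config.cg_propensity_range

    u = rng.uniform(0.0, 1.0, size=config.n_accessions)  # accession factor
    mc = np.zeros((config.n_accessions, len(gene_ids)), dtype=int)
    mc_cg = np.zeros_like(mc)
    propensities = np.zeros((config.n_accessions, len(gene_ids)))
    methylomes: dict[str, list[MethylomeRecord]] | None = {} if materialize else None

    for j, gene in enumerate(genome.genes):
        sites = cache[gene.gene_id]
        ctx = sites.body_contexts
        is_cg = ctx == 0
        is_non_cg = (ctx == 1) | (ctx == 2)
        for i, accession in enumerate(accessions):
            if gene.gene_id in causal:
                v = float(np.clip(u[i] + rng.normal(0.0, config.accession_factor_jitter), 0, 1))
            else:
                v = float(rng.uniform(0.0, 1.0))
            p = p_lo + (p_hi - p_lo) * v
            propensities[i, j] = p
            draws = rng.random(len(ctx))
            methylated = np.where(
                is_cg, draws < p, np.where(is_non_cg, draws < config.non_cg_propensity, False)
            )
            mc[i, j] = int(methylated.sum())
            mc_cg[i, j] = int(methylated[is_cg].sum())
            prom_flags = rng.random(len(sites.promoter_sites)) < config.promoter_propensity
            if methylomes is not None:
                records = methylomes.setdefault(accession, [])
                for site, m in zip(sites.body_sites, methylated):
                    if m:
                        records.append(
                            MethylomeRecord(
                                site.chrom, site.pos, site.strand, site.context, True
                            )
                        )
                for site, m in zip(sites.promoter_sites, prom_flags):
                    if m and site.context != UNKNOWN:
                        records.append(
                            MethylomeRecord(
                                site.chrom, site.pos, site.strand, site.context, True
                            )
                        )

    if methylomes is not None:
        for records in methylomes.values():
            records.sort(key=lambda r: (r.chrom, r.pos, r.strand))

    causal_idx = [gene_ids.index(g) for g in causal]
    causal_mc = mc[:, causal_idx].sum(axis=1)
    flowering = (
        config.baseline_days
        + config.effect_days_per_site * causal_mc
        + rng.normal(0.0, config.phenotype_sd, size=config.n_accessions)
    )
    leaves = np.maximum(
        0, np.round(config.leaves_per_day * flowering + rng.normal(0, 1, config.n_accessions))
    ).astype(int)
    expression = np.maximum(
        0.0,
        config.expression_baseline
        - config.expression_slope * mc
        + rng.normal(0.0, config.expression_sd, size=mc.shape),
    )

    mc_df = pd.DataFrame(mc, index=accessions, columns=gene_ids)
    truth = {
        "causal_genes": causal,
        "accession_factor": {a: float(x) for a, x in zip(accessions, u)},
        "cg_propensity": {
            a: {g: float(propensities[i, j]) for j, g in enumerate(gene_ids)}
            for i, a in enumerate(accessions)
        },
        "mc": {a: {g: int(mc[i, j]) for j, g in enumerate(gene_ids)} for i, a in enumerate(accessions)},
        "mc_cg": {
            a: {g: int(mc_cg[i, j]) for j, g in enumerate(gene_ids)}
            for i, a in enumerate(accessions)
        },
        "flowering_days": {a: float(f) for a, f in zip(accessions, flowering)},
        "config": {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()
        },
    }
    return SimulatedStudy(
        genome=genome,
        config=config,
        accessions=accessions,
        causal_genes=causal,
        mc_matrix=mc_df,
        mc_cg_matrix=pd.DataFrame(mc_cg, index=accessions, columns=gene_ids),
        phenotype=pd.DataFrame(
            {"flowering_days": flowering, "leaf_count": leaves}, index=accessions
        ),
        expression=pd.DataFrame(expression, index=accessions, columns=gene_ids),
        methylomes=methylomes,
        truth=truth,
    )


def generate_study(config: SimulationConfig, materialize: bool = True) -> SimulatedStudy:
    """Genome plus methylomes in one seeded call."""
    rng = config.rng()
    genome = generate_genome(config, rng)
    return generate_methylomes(genome, config, rng, materialize=materialize)


def apply_azaC(
    records: Sequence[MethylomeRecord],
    genes: Sequence[GeneModel],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[MethylomeRecord], dict[str, float]]:
    """Demethylating-treatment model: per-gene uniform thinning of mC sites.

    For each gene a reduction fraction f ~ U(low, high) is drawn and
    round(f * mC) methylated body sites are removed uniformly at random
    (the removal count is clamped so the realized fraction stays inside the
    configured range whenever the gene has enough methylated sites to allow
    it). Returns the perturbed records and the realized per-gene fraction.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    low, high = config.azaC_reduction_range
    drop: set[int] = set()
    realized: dict[str, float] = {}
    for gene in genes:
        region = gene.region
        meth_idx = [
            k
            for k, r in enumerate(records)
            if r.methylated and r.chrom == region.chrom and region.contains(r.pos)
        ]
        m = len(meth_idx)
        if m == 0:
            realized[gene.gene_id] = 0.0
            continue
        f = rng.uniform(low, high)
        k = int(round(f * m))
        k_lo, k_hi = int(np.ceil(low * m)), int(np.floor(high * m))
        if k_lo <= k_hi:
            k = min(max(k, k_lo), k_hi)
        chosen = rng.choice(meth_idx, size=k, replace=False) if k else np.array([], dtype=int)
        drop.update(int(c) for c in chosen)
        realized[gene.gene_id] = k / m
    kept = [r for k, r in enumerate(records) if k not in drop]
    return kept, realized


def simulate_bisulfite_clones(
    reference: str,
    methylation_probs: Mapping[int, float],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Simulate bisulfite-converted clone sequences of one amplicon.

    Each forward-strand cytosine is methylated (stays C) with its site
    probability; unmethylated cytosines convert to T with probability
    ``conversion_efficiency`` and otherwise stay C (conversion failure).
    Sequencing error then substitutes any base uniformly at the configured
    rate. Every reference C must have a probability.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    reference = reference.upper()
    c_positions = [i for i, b in enumerate(reference) if b == "C"]
    missing = [p for p in c_positions if p not in methylation_probs]
    if missing:
        raise ValueError(f"no methylation probability for C positions {missing[:5]}...")
    clones: list[str] = []
    for _ in range(config.n_clones):
        bases = list(reference)
        for pos in c_positions:
            if rng.random() < methylation_probs[pos]:
                continue  # methylated, protected
            if rng.random() < config.conversion_efficiency:
                bases[pos] = "T"
        if config.sequencing_error > 0:
            err = rng.random(len(bases)) < config.sequencing_error
            for pos in np.flatnonzero(err):
                alternatives = [b for b in "ACGT" if b != bases[pos]]
                bases[pos] = alternatives[rng.integers(3)]
        clones.append("".join(bases))
    return clones


def replicate_screen_flags(
    config: SimulationConfig,
    n_reps: int,
    alpha: float = 0.05,
    method: str = "spearman",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-replicate causal and null significance counts of the screen.

    Holds one genome fixed and redraws the cohort ``n_reps`` times, running
    the methylation–phenotype correlation screen on each replicate's truth
    matrix (the fast path — no site-level records). Returns one row per
    replicate with flagged/total counts for causal and null genes, from
    which screen power and type-I error are estimated.
    """
    from .association import correlation_screen

    rng = config.rng() if rng is None else rng
    genome = generate_genome(config, rng)
    rows = []
    for rep in range(n_reps):
        study = generate_methylomes(genome, config, rng, materialize=False)
        screen = correlation_screen(
            study.mc_matrix, study.phenotype["flowering_days"], method=method, alpha=alpha
        )
        sig = screen["significant"]
        causal = sig.loc[study.causal_genes]
        null = sig.drop(study.causal_genes)
        rows.append(
            {
                "rep": rep,
                "causal_flagged": int(causal.sum()),
                "causal_total": len(causal),
                "null_flagged": int(null.sum()),
                "null_total": len(null),
            }
        )
    return pd.DataFrame(rows)


def write_clone_fasta(reference: str, clones: Iterable[str], path, sample: str = "sample") -> None:
    """Reference-first clone FASTA, the dialect the clone caller reads."""
    records = [(f"{sample}_reference", reference)]
    records += [(f"{sample}_clone{i + 1:02d}", c) for i, c in enumerate(clones)]
    write_fasta(records, path)
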