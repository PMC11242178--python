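"""Per-gene, per-context methylation summaries from site-level call tables.

Consumes allc-style TSVs (one row per methylated-or-covered cytosine) and
summarizes methylated / total cytosine counts per region (gene body or
promoter) and per context, for one accession or a panel of accessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .sequence_context import (
    CG,
    CHG,
    CHH,
    CONTEXTS,
    UNKNOWN,
    CytosineSite,
    GeneModel,
    GenomicRegion,
    PromoterWindow,
    enumerate_cytosine_sites,
    promoter_region,
)

_METHYLOME_COLUMNS = ("chrom", "pos", "strand", "context", "methylated")
_VALID_CONTEXTS = frozenset((*CONTEXTS, UNKNOWN))


class MethylomeParseError(ValueError):
    pass


@dataclass(frozen=True)
class MethylomeRecord:
    """One cytosine call: position (internal 0-based), context, binary state."""

    chrom: str
    pos: int
    strand: str
    context: str
    methylated: bool
    mc_count: int | None = None
    total_count: int | None = None

    def __post_init__(self) -> None:
        if (
            self.mc_count is not None
            and self.total_count is not None
            and self.mc_count > self.total_count
        ):
            raise ValueError(f"mc_count > total_count at {self.chrom}:{self.pos}")


@dataclass
class GeneMethylationSummary:
    """Methylated (m) and total (n) cytosine-site counts per context.

    ``mC`` — the total number of methylated sites over CG+CHG+CHH — is the
    count statistic correlated with flowering phenotypes; ``level(c)`` is
    the fractional alternative m_c / n_c.
    """

    gene_id: str
    region_kind: str
    m: dict[str, int]
    n: dict[str, int]

    @property
    def mC(self) -> int:
        return sum(self.m[c] for c in CONTEXTS)

    def level(self, context: str) -> float | None:
        if self.n[context] == 0:
            return None
        return self.m[context] / self.n[context]

    def statistic(self, name: str) -> float | int | None:
        if name == "mC":
            return self.mC
        if name.startswith("level_"):
            return self.level(name.removeprefix("level_"))
        raise ValueError(f"unknown statistic {name!r}")


def load_methylome(path) -> list[MethylomeRecord]:
    """Read a methylome TSV (1-based positions) into validated records.

    Expected columns: chrom, pos, strand, context, methylated(0/1) and
    optionally mc_count, total_count. Raises MethylomeParseError with the
    offending line number on malformed rows.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    has_counts = "mc_count" in df.columns and "total_count" in df.columns
    required = [c for c in _METHYLOME_COLUMNS if not (c == "methylated" and has_counts)]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MethylomeParseError(f"{path}: missing columns {missing}")
    if "methylated" not in df.columns:
        df["methylated"] = pd.NA
    records: list[MethylomeRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            pos = int(row.pos)
            if pos < 1:
                raise ValueError("position must be >= 1 (1-based)")
            if row.strand not in ("+", "-"):
                raise ValueError(f"bad strand {row.strand!r}")
            if row.context not in _VALID_CONTEXTS:
                raise ValueError(f"unknown context token {row.context!r}")
            mc = int(row.mc_count) if has_counts and pd.notna(row.mc_count) else None
            tot = (
                int(row.total_count) if has_counts and pd.notna(row.total_count) else None
            )
            if pd.isna(row.methylated) and mc is not None and tot is not None:
                # threshold count data to a binary call
                methylated = tot > 0 and mc / tot >= 0.5
            elif str(row.methylated) in ("0", "1"):
                methylated = row.methylated == "1"
            else:
                raise ValueError(f"methylated flag must be 0/1, got {row.methylated!r}")
            records.append(
                MethylomeRecord(
                    chrom=str(row.chrom),
                    pos=pos - 1,
                    strand=row.strand,
                    context=row.context,
                    methylated=methylated,
                    mc_count=mc,
                    total_count=tot,
                )
            )
        except ValueError as exc:
            raise MethylomeParseError(f"{path}:{i}: {exc}") from exc
    records.sort(key=lambda r: (r.chrom, r.pos, r.strand))
    return records


def write_methylome(records: Iterable[MethylomeRecord], path) -> None:
    """Write records back to the TSV dialect (1-based positions)."""
    rows = [
        (r.chrom, r.pos + 1, r.strand, r.context, int(r.methylated))
        for r in records
    ]
    pd.DataFrame(rows, columns=_METHYLOME_COLUMNS).to_csv(path, sep="\t", index=False)


def _index_records(
    records: Iterable[MethylomeRecord],
) -> dict[tuple[str, int, str], MethylomeRecord]:
    return {(r.chrom, r.pos, r.strand): r for r in records}


def summarize_region(
    records: Iterable[MethylomeRecord] | Mapping[tuple[str, int, str], MethylomeRecord],
    region: GenomicRegion,
    reference_sites: Sequence[CytosineSite],
    gene_id: str = "",
    region_kind: str = "body",
    missing: Literal["unmethylated", "no_coverage"] = "unmethylated",
) -> GeneMethylationSummary:
    """Count methylated and total cytosines per context inside ``region``.

    ``reference_sites`` supplies the denominator (every cytosine in the
    region, from the genome sequence). A reference site absent from the
    methylome counts as unmethylated by default — allc-style files list mC
    sites — or is dropped from the denominator under ``missing="no_coverage"``.
    When a record's context disagrees with the reference, the reference wins
    with a warning.
    """
    index = (
        records
        if isinstance(records, Mapping)
        else _index_records(records)
    )
    m = {c: 0 for c in CONTEXTS}
    n = {c: 0 for c in CONTEXTS}
    for site in reference_sites:
        if site.chrom != region.chrom or not region.contains(site.pos):
            continue
        if site.context == UNKNOWN:
            continue
        rec = index.get((site.chrom, site.pos, site.strand))
        if rec is None and missing == "no_coverage":
            continue
        n[site.context] += 1
        if rec is None:
            continue
        if rec.context != site.context and rec.context != UNKNOWN:
            warnings.warn(
                f"context mismatch at {site.chrom}:{site.pos}{site.strand}: "
                f"record says {rec.context}, reference says {site.context}; "
                "reference wins",
                stacklevel=2,
            )
        if rec.methylated:
            m[site.context] += 1
    return GeneMethylationSummary(gene_id=gene_id, region_kind=region_kind, m=m, n=n)


def summarize_gene(
    records,
    gene: GeneModel,
    genome: Mapping[str, str],
    region_kind: Literal["body", "promoter"] = "body",
    strands: str = "both",
    cds_only: bool = True,
    promoter_length: int = 1500,
    missing: Literal["unmethylated", "no_coverage"] = "unmethylated",
) -> GeneMethylationSummary:
    """Summarize one gene's body (CDS footprint) or promoter.

    With ``cds_only`` (default) intronic cytosines are excluded from the
    body summary; otherwise the full genomic footprint counts.
    """
    chrom_seq = genome[gene.region.chrom]
    if region_kind == "promoter":
        window: PromoterWindow = promoter_region(gene, len(chrom_seq), promoter_length)
        regions = [(window.region.start, window.region.end)]
        region = window.region
    elif region_kind == "body":
        regions = sorted(gene.cds_segments) if cds_only else [
            (gene.region.start, gene.region.end)
        ]
        region = gene.region
    else:
        raise ValueError(f"region_kind must be body or promoter, got {region_kind!r}")

    index = records if isinstance(records, Mapping) else _index_records(records)
    total = GeneMethylationSummary(
        gene.gene_id, region_kind, {c: 0 for c in CONTEXTS}, {c: 0 for c in CONTEXTS}
    )
    for start, end in regions:
        sites = enumerate_cytosine_sites(
            chrom_seq[start:end], gene.region.chrom, strands=strands, offset=start
        )
        part = summarize_region(
            index,
            GenomicRegion(gene.region.chrom, start, end, gene.strand),
            sites,
            gene.gene_id,
            region_kind,
            missing,
        )
        for c in CONTEXTS:
            total.m[c] += part.m[c]
            total.n[c] += part.n[c]
    _ = region
    return total


def build_accession_matrix(
    methylomes: Mapping[str, Iterable[MethylomeRecord]],
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    region_kind: Literal["body", "promoter"] = "body",
    statistic: str = "mC",
    **kwargs,
) -> pd.DataFrame:
    """Accession x gene matrix of a chosen methylation statistic.

    Statistic is ``mC`` (methylated-site count) or ``level_CG`` /
    ``level_CHG`` / ``level_CHH``. All accessions share the gene models; a
    missing statistic (zero-denominator level) raises rather than yielding
    NaN.
    """
    data: dict[str, list] = {}
    for accession, records in methylomes.items():
        index = _index_records(records)
        row = []
        for gene in genes:
            summary = summarize_gene(index, gene, genome, region_kind, **kwargs)
            value = summary.statistic(statistic)
            if value is None:
                raise ValueError(
                    f"statistic {statistic} undefined for {gene.gene_id} "
                    f"in accession {accession} (no sites in denominator)"
                )
            row.append(value)
        data[accession] = row
    return pd.DataFrame.from_dict(
        data, orient="index", columns=[g.gene_id for g in genes]
    )


def summary_table(summaries: Iterable[GeneMethylationSummary]) -> pd.DataFrame:
    """Flat per-gene summary table (the TSV export layout)."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "gene_id": s.gene_id,
                "region_kind": s.region_kind,
                "m_CG": s.m[CG],
                "n_CG": s.n[CG],
                "m_CHG": s.m[CHG],
                "n_CHG": s.n[CHG],
                "m_CHH": s.m[CHH],
                "n_CHH": s.n[CHH],
                "mC": s.mC,
            }
        )
    return pd.DataFrame(rows)
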