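"""Methylation calling from cloned bisulfite-PCR amplicon sequences.

Bisulfite treatment deaminates unmethylated cytosines to uracil (read as T
after PCR) while methylated cytosines are protected and stay C. Sanger
sequencing of individual cloned amplicons therefore reads out the
methylation state of single molecules: at each reference cytosine, the
fraction of clones retaining C estimates that site's methylation level.

A site is called methylated when its retention fraction reaches the
per-context threshold — 50% for CG and 20% for CHG and CHH by default,
compared inclusively (a 5-of-10 CG site is called). Call sets from two
samples can be partitioned into shared and sample-specific (novel) sites.

Inputs are pre-aligned: every clone must have the same length as the
unconverted reference. Alignment of raw Sanger traces is upstream of this
module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .sequence_context import (
    CG,
    CHG,
    CHH,
    CONTEXTS,
    UNKNOWN,
    enumerate_cytosine_sites,
)


@dataclass(frozen=True)
class CloneSet:
    """A reference amplicon and its pre-aligned bisulfite clone sequences."""

    reference: str
    clones: tuple[str, ...]
    sample: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "reference", self.reference.upper())
        object.__setattr__(self, "clones", tuple(c.upper() for c in self.clones))
        if not self.clones:
            raise ValueError("need at least one clone")
        for i, clone in enumerate(self.clones):
            if len(clone) != len(self.reference):
                raise ValueError(
                    f"clone {i} length {len(clone)} != reference length "
                    f"{len(self.reference)} (clones must be pre-aligned)"
                )


@dataclass(frozen=True)
class SiteProfile:
    """Per-reference-cytosine clone tallies."""

    pos: int
    context: str
    retained: int      # clones reading C (methylated molecule)
    converted: int     # clones reading T (unmethylated, converted)
    ambiguous: int     # anything else (sequencing error, N)
    low_quality: bool

    @property
    def fraction(self) -> float | None:
        informative = self.retained + self.converted
        if informative == 0:
            return None
        return self.retained / informative


@dataclass
class CloneProfile:
    """Profile of every reference cytosine across the clone set."""

    sample: str
    n_clones: int
    sites: list[SiteProfile]
    excluded_clones: list[int] = field(default_factory=list)

    def site(self, pos: int) -> SiteProfile:
        for s in self.sites:
            if s.pos == pos:
                return s
        raise KeyError(pos)


@dataclass(frozen=True)
class ThresholdSet:
    """Per-context retention-fraction thresholds (inclusive)."""

    t_CG: float = 0.50
    t_CHG: float = 0.20
    t_CHH: float = 0.20

    def __post_init__(self) -> None:
        for name, t in (("t_CG", self.t_CG), ("t_CHG", self.t_CHG), ("t_CHH", self.t_CHH)):
            if not (0 < t <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {t}")

    def for_context(self, context: str) -> float:
        return {CG: self.t_CG, CHG: self.t_CHG, CHH: self.t_CHH}[context]


@dataclass(frozen=True)
class MethylationCall:
    pos: int
    context: str
    fraction: float


@dataclass(frozen=True)
class SiteSetComparison:
    """Disjoint partition of two call sets into shared and novel sites."""

    shared: frozenset[int]
    novel_in_a: frozenset[int]
    novel_in_b: frozenset[int]


def clone_conversion_stats(reference: str, clone: str) -> dict[str, float]:
    """Per-clone QC: retention over non-CG cytosines and bad-base fraction.

    Near-complete retention at non-CG sites (rarely methylated in plants at
    high levels) flags a clone that escaped bisulfite conversion.
    """
    reference = reference.upper()
    clone = clone.upper()
    non_cg_ret = non_cg_tot = bad = c_positions = 0
    contexts = {
        s.pos: s.context
        for s in enumerate_cytosine_sites(reference, strands="+")
    }
    for pos, context in contexts.items():
        c_positions += 1
        base = clone[pos]
        if base not in "CT":
            bad += 1
            continue
        if context in (CHG, CHH):
            non_cg_tot += 1
            if base == "C":
                non_cg_ret += 1
    return {
        "non_cg_retention": non_cg_ret / non_cg_tot if non_cg_tot else 0.0,
        "bad_base_fraction": bad / c_positions if c_positions else 0.0,
    }


def profile_clones(
    clone_set: CloneSet,
    max_bad_base_fraction: float = 0.10,
    low_quality_ambiguous_fraction: float = 0.50,
    filter_unconverted: bool = False,
    unconverted_retention: float = 0.90,
) -> CloneProfile:
    """Tally retained/converted/ambiguous clones at every reference cytosine.

    Clones with more than ``max_bad_base_fraction`` non-C/T bases at
    reference-C positions are excluded (listed in ``excluded_clones``).
    Positions where ambiguous reads reach ``low_quality_ambiguous_fraction``
    of the included clones are flagged low-quality and never called.
    ``filter_unconverted`` additionally drops clones whose non-CG retention
    exceeds ``unconverted_retention`` (conversion-failure QC, off by
    default).
    """
    reference = clone_set.reference
    ref_sites = enumerate_cytosine_sites(reference, strands="+")

    included: list[str] = []
    excluded: list[int] = []
    for i, clone in enumerate(clone_set.clones):
        qc = clone_conversion_stats(reference, clone)
        if qc["bad_base_fraction"] > max_bad_base_fraction:
            excluded.append(i)
            continue
        if filter_unconverted and qc["non_cg_retention"] > unconverted_retention:
            excluded.append(i)
            continue
        included.append(clone)
    if not included:
        raise ValueError("all clones failed QC; nothing to profile")

    sites: list[SiteProfile] = []
    n = len(included)
    for ref_site in ref_sites:
        retained = converted = ambiguous = 0
        for clone in included:
            base = clone[ref_site.pos]
            if base == "C":
                retained += 1
            elif base == "T":
                converted += 1
            else:
                ambiguous += 1
        sites.append(
            SiteProfile(
                pos=ref_site.pos,
                context=ref_site.context,
                retained=retained,
                converted=converted,
                ambiguous=ambiguous,
                low_quality=ambiguous >= low_quality_ambiguous_fraction * n,
            )
        )
    return CloneProfile(
        sample=clone_set.sample, n_clones=n, sites=sites, excluded_clones=excluded
    )


def call_methylated_sites(
    profile: CloneProfile, thresholds: ThresholdSet = ThresholdSet()
) -> list[MethylationCall]:
    """Call a site methylated when retention >= its context threshold.

    UNKNOWN-context sites (insufficient 3' flank) and low-quality positions
    are never called.
    """
    calls: list[MethylationCall] = []
    for site in profile.sites:
        if site.context == UNKNOWN or site.low_quality:
            continue
        fraction = site.fraction
        if fraction is None:
            continue
        if fraction >= thresholds.for_context(site.context):
            calls.append(MethylationCall(site.pos, site.context, fraction))
    return calls


def compare_site_sets(
    calls_a: Iterable[MethylationCall | int],
    calls_b: Iterable[MethylationCall | int],
) -> SiteSetComparison:
    """Partition two call sets (on one coordinate system) by sharedness."""
    pos_a = frozenset(c.pos if isinstance(c, MethylationCall) else int(c) for c in calls_a)
    pos_b = frozenset(c.pos if isinstance(c, MethylationCall) else int(c) for c in calls_b)
    return SiteSetComparison(
        shared=pos_a & pos_b,
        novel_in_a=pos_a - pos_b,
        novel_in_b=pos_b - pos_a,
    )


def context_breakdown(calls: Iterable[MethylationCall]) -> dict[str, int]:
    """Count calls per context; the three counts sum to the total."""
    counts = {c: 0 for c in CONTEXTS}
    for call in calls:
        counts[call.context] += 1
    return counts


def load_clone_fasta(path, reference_path=None, sample: str = "") -> CloneSet:
    """Build a CloneSet from FASTA input.

    Either one file whose first record is the unconverted reference and the
    rest are clones, or a separate single-record reference FASTA plus a
    clones FASTA.
    """
    from .sequence_context import read_fasta

    if reference_path is not None:
        ref_records = read_fasta(reference_path)
        if len(ref_records) != 1:
            raise ValueError("reference FASTA must contain exactly one record")
        reference = next(iter(ref_records.values()))
        clones = tuple(read_fasta(path).values())
    else:
        records = list(read_fasta(path).values())
        if len(records) < 2:
            raise ValueError("combined FASTA needs a reference plus >= 1 clone")
        reference, clones = records[0], tuple(records[1:])
    return CloneSet(reference=reference, clones=clones, sample=sample)


def calls_table(profile: CloneProfile, thresholds: ThresholdSet = ThresholdSet()):
    """Flat per-site table: tallies, fraction and the threshold call."""
    import pandas as pd

    called = {c.pos for c in call_methylated_sites(profile, thresholds)}
    rows = [
        {
            "pos": s.pos,
            "strand": "+",
            "context": s.context,
            "retained": s.retained,
            "converted": s.converted,
            "ambiguous": s.ambiguous,
            "fraction": s.fraction,
            "low_quality": s.low_quality,
            "call": s.pos in called,
        }
        for s in profile.sites
    ]
    return pd.DataFrame(rows)
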