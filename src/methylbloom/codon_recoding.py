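"""Synonymous recoding of a CDS to deplete methylatable cytosines.

Every cytosine in a protein-coding sequence with two downstream bases falls
in one of the CG, CHG or CHH methylation contexts, so the number of
"theoretically methylatable" cytosines in a CDS is simply its count of
fully-flanked Cs (plus, on the duplex reading, the reverse-strand cytosines
that appear as Gs on the coding strand). Codon degeneracy lets many of
those cytosines be removed without touching the protein: for each amino
acid we may pick the synonymous codon with the fewest cytosines.

Two objectives are provided:

``min_C``
    Per-codon greedy choice of the synonym with the fewest cytosines
    (fewest C+G in duplex mode). Because cytosine counting is separable
    over codons, this is globally optimal for the plain cytosine count.

``min_C_dp``
    Dynamic programming over codon choices that scores the context-aware
    objective — methylatable sites whose trinucleotide window spans codon
    junctions, including flank truncation at the CDS ends — and returns a
    guaranteed global minimum of that objective.

Ties between equally cytosine-poor synonyms are broken by the highest
relative adaptiveness w (then lexicographically), so recoding drifts the
codon adaptation index (CAI) as little as possible.  CAI is the geometric
mean of w over the CDS's codons, excluding Met, Trp and stop codons by the
standard convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Mapping

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .sequence_context import CG, CHG, CHH, CONTEXTS, enumerate_cytosine_sites

_STANDARD = unambiguous_dna_by_id[1]
_STOP_CODONS = tuple(sorted(_STANDARD.stop_codons))

#: codon -> amino-acid letter ('*' for stops), standard genetic code
GENETIC_CODE: dict[str, str] = {
    **{c: aa for c, aa in _STANDARD.forward_table.items()},
    **{c: "*" for c in _STOP_CODONS},
}

#: amino-acid letter -> sorted tuple of synonymous codons
SYNONYMS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(GENETIC_CODE.items()):
    SYNONYMS.setdefault(_aa, ())
    SYNONYMS[_aa] += (_codon,)

_EXCLUDED_FROM_CAI = frozenset(["ATG", "TGG", *_STOP_CODONS])


class CodonError(ValueError):
    pass


@dataclass(frozen=True)
class CodonUsageTable:
    """Codon usage frequencies and derived relative adaptiveness w.

    ``w(codon) = freq(codon) / max(freq over the codon's synonyms)``; the
    most frequent synonym of every amino acid has w = 1. Frequencies must
    be positive for every codon of the standard code.
    """

    frequencies: Mapping[str, float]
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = [c for c in GENETIC_CODE if c not in self.frequencies]
        if missing:
            raise CodonError(f"usage table {self.name!r} missing codons: {missing[:5]}...")
        bad = [c for c, f in self.frequencies.items() if not f > 0]
        if bad:
            raise CodonError(f"usage table {self.name!r} has non-positive frequencies: {bad[:5]}")
        w = {}
        for aa, codons in SYNONYMS.items():
            top = max(self.frequencies[c] for c in codons)
            for c in codons:
                w[c] = self.frequencies[c] / top
        object.__setattr__(self, "_w", w)

    def w(self, codon: str) -> float:
        try:
            return self._w[codon]  # type: ignore[attr-defined]
        except KeyError:
            raise CodonError(f"{codon!r} is not a standard codon") from None

    @classmethod
    def from_tsv(cls, path, name: str | None = None) -> "CodonUsageTable":
        """Two-column TSV: codon, frequency (e.g. per 1000 codons)."""
        freqs: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                codon, value = line.split("\t")[:2]
                freqs[codon.upper().replace("U", "T")] = float(value)
        return cls(freqs, name=name or str(path))

    @classmethod
    def arabidopsis(cls) -> "CodonUsageTable":
        """The bundled A. thaliana genome-wide usage table (approximate)."""
        ref = resources.files("methylbloom.data") / "codon_usage_athaliana.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path, name="athaliana-bundled-v1")


@dataclass(frozen=True)
class MethylatableCounts:
    """Per-context counts of theoretically methylatable cytosines."""

    cg: int
    chg: int
    chh: int
    unknown_flank: int

    @property
    def total(self) -> int:
        return self.cg + self.chg + self.chh

    def as_dict(self) -> dict[str, int]:
        return {CG: self.cg, CHG: self.chg, CHH: self.chh}


@dataclass(frozen=True)
class Substitution:
    codon_index: int
    original: str
    replacement: str
    cytosines_removed: int


@dataclass(frozen=True)
class RecodingResult:
    original_cds: str
    recoded_cds: str
    substitutions: tuple[Substitution, ...]
    cytosines_before: int
    cytosines_after: int
    substituted_cytosine_count: int
    methylatable_before: MethylatableCounts
    methylatable_after: MethylatableCounts
    cai_before: float
    cai_after: float


def _split_codons(cds: str) -> list[str]:
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise CodonError(f"CDS length {len(cds)} is not divisible by 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for i, codon in enumerate(codons):
        if codon not in GENETIC_CODE:
            raise CodonError(f"codon {codon!r} at index {i} is not in the standard table")
    return codons


def translate(cds: str) -> str:
    """Standard-code translation; a terminal stop is rendered as '*'.

    Internal stop codons are an error.
    """
    codons = _split_codons(cds)
    protein = "".join(GENETIC_CODE[c] for c in codons)
    if "*" in protein[:-1]:
        raise CodonError(f"internal stop codon at index {protein.index('*')}")
    return protein


def count_theoretical_methylation_sites(
    cds: str, mode: Literal["coding_strand", "duplex"] = "coding_strand"
) -> MethylatableCounts:
    """Count cytosines that could carry methylation, per context.

    ``coding_strand`` counts every fully-flanked C of the CDS itself;
    ``duplex`` adds reverse-strand cytosines (Gs on the coding strand,
    context read on the reverse complement). Cytosines whose context is
    truncated by the CDS end are tallied separately as ``unknown_flank``
    and excluded from the total.
    """
    _split_codons(cds)  # validates length and alphabet
    strands = "+" if mode == "coding_strand" else "both"
    counts = {CG: 0, CHG: 0, CHH: 0}
    unknown = 0
    for site in enumerate_cytosine_sites(cds.upper(), strands=strands):
        if site.context in counts:
            counts[site.context] += 1
        else:
            unknown += 1
    return MethylatableCounts(
        cg=counts[CG], chg=counts[CHG], chh=counts[CHH], unknown_flank=unknown
    )


def _plain_cost(codon: str, mode: str) -> int:
    if mode == "duplex":
        return codon.count("C") + codon.count("G")
    return codon.count("C")


def _fwd_cost(codon: str, next_two: str) -> int:
    # Cs in `codon` with a full 2-base 3' flank inside codon + next_two
    avail = len(codon) + len(next_two)
    return sum(1 for j in range(3) if codon[j] == "C" and j + 2 < avail)


def _rev_cost(codon: str, prev_two: str) -> int:
    # Gs in `codon` (reverse-strand Cs) with a full 2-base 5' flank
    return sum(1 for j in range(3) if codon[j] == "G" and len(prev_two) + j >= 2)


def _choices(
    codons: list[str], usage: CodonUsageTable, allow_stop_swaps: bool
) -> list[list[str]]:
    protein = "".join(GENETIC_CODE[c] for c in codons)
    if "*" in protein[:-1]:
        raise CodonError("internal stop codon")
    options: list[list[str]] = []
    for i, (codon, aa) in enumerate(zip(codons, protein)):
        fixed = i == 0 or (aa == "*" and not allow_stop_swaps)
        syn = [codon] if fixed else list(SYNONYMS[aa])
        for s in syn:
            usage.w(s)  # raises if the table lacks a synonym
        options.append(syn)
    return options


def _pick(
    candidates: list[str], cost: Mapping[str, float], usage: CodonUsageTable
) -> str:
    # lowest cost, then highest w, then lexicographic
    return min(candidates, key=lambda c: (cost[c], -usage.w(c), c))


def _recode_greedy(
    codons: list[str], usage: CodonUsageTable, mode: str, allow_stop_swaps: bool
) -> list[str]:
    out = []
    for i, syn in enumerate(_choices(codons, usage, allow_stop_swaps)):
        costs = {c: _plain_cost(c, mode) for c in syn}
        out.append(_pick(syn, costs, usage))
    return out


def _recode_dp(
    codons: list[str], usage: CodonUsageTable, mode: str, allow_stop_swaps: bool
) -> list[str]:
    """Viterbi DP minimizing context-aware methylatable-site count.

    A cytosine's context window extends two bases 3' (and, on the duplex
    reading, a reverse-strand cytosine's two bases 5'), so the objective
    couples adjacent codons only. States are codon choices; the transition
    out of codon i pays its forward-strand sites (flanked by codon i+1) and,
    in duplex mode, codon i+1's reverse-strand sites (flanked by codon i).
    Ends pay truncated-flank boundary terms. Ties prefer the highest total
    relative adaptiveness, then the lexicographically smallest sequence.
    """
    options = _choices(codons, usage, allow_stop_swaps)
    duplex = mode == "duplex"

    def neg_log_w(c: str) -> float:
        return round(-math.log(usage.w(c)), 12)

    # dp: codon -> (site_count, neg_log_w_sum, sequence_so_far)
    dp: dict[str, tuple[int, float, str]] = {}
    for c in options[0]:
        cost = _rev_cost(c, "") if duplex else 0
        dp[c] = (cost, neg_log_w(c), c)

    for i in range(1, len(options)):
        nxt: dict[str, tuple[int, float, str]] = {}
        for cur in options[i]:
            best: tuple[int, float, str] | None = None
            for prev, (count, nlw, seq) in dp.items():
                step = _fwd_cost(prev, cur[:2])
                if duplex:
                    step += _rev_cost(cur, prev[1:])
                cand = (count + step, round(nlw + neg_log_w(cur), 12), seq + cur)
                if best is None or cand < best:
                    best = cand
            assert best is not None
            nxt[cur] = best
        dp = nxt

    final = min(
        (count + _fwd_cost(cur, ""), nlw, seq) for cur, (count, nlw, seq) in dp.items()
    )
    seq = final[2]
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def context_objective(cds: str, mode: Literal["coding_strand", "duplex"]) -> int:
    """The DP objective: methylatable sites with full flanks inside the CDS."""
    return count_theoretical_methylation_sites(cds, mode).total


def recode_minimize_cytosines(
    cds: str,
    usage: CodonUsageTable | None = None,
    mode: Literal["coding_strand", "duplex"] = "coding_strand",
    objective: Literal["min_C", "min_C_dp"] = "min_C",
    allow_stop_swaps: bool = False,
) -> RecodingResult:
    """Synonymously recode ``cds`` to minimize (methylatable) cytosines.

    The start codon is never altered; the terminal stop is kept unless
    ``allow_stop_swaps``. The protein sequence is preserved exactly.
    """
    if usage is None:
        usage = CodonUsageTable.arabidopsis()
    codons = _split_codons(cds)
    if objective == "min_C":
        recoded = _recode_greedy(codons, usage, mode, allow_stop_swaps)
    elif objective == "min_C_dp":
        recoded = _recode_dp(codons, usage, mode, allow_stop_swaps)
    else:
        raise ValueError(f"unknown objective {objective!r}")

    original = "".join(codons)
    recoded_cds = "".join(recoded)
    if translate(recoded_cds) != translate(original):
        raise AssertionError("recoding altered the protein — this is a bug")

    substitutions = tuple(
        Substitution(
            codon_index=i,
            original=o,
            replacement=r,
            cytosines_removed=sum(
                1 for a, b in zip(o, r) if a == "C" and b != "C"
            ),
        )
        for i, (o, r) in enumerate(zip(codons, recoded))
        if o != r
    )
    return RecodingResult(
        original_cds=original,
        recoded_cds=recoded_cds,
        substitutions=substitutions,
        cytosines_before=original.count("C"),
        cytosines_after=recoded_cds.count("C"),
        substituted_cytosine_count=sum(
            1 for a, b in zip(original, recoded_cds) if a == "C" and b != "C"
        ),
        methylatable_before=count_theoretical_methylation_sites(original, mode),
        methylatable_after=count_theoretical_methylation_sites(recoded_cds, mode),
        cai_before=cai(original, usage),
        cai_after=cai(recoded_cds, usage),
    )


def cai(cds: str, usage: CodonUsageTable | None = None) -> float:
    """Codon adaptation index: geometric mean of w over the CDS's codons.

    Met, Trp and stop codons are excluded (they have no synonymous
    alternative, so w = 1 by construction and they carry no information).
    A CDS with no informative codons returns 1.0.
    """
    if usage is None:
        usage = CodonUsageTable.arabidopsis()
    codons = _split_codons(cds)
    included = [c for c in codons if c not in _EXCLUDED_FROM_CAI]
    if not included:
        return 1.0
    log_sum = sum(math.log(usage.w(c)) for c in included)
    return math.exp(log_sum / len(included))


def substitution_table(result: RecodingResult):
    """Substitution ledger as a DataFrame (the TSV export layout)."""
    import pandas as pd

    rows = [
        {
            "codon_index": s.codon_index,
            "nt_pos": 3 * s.codon_index,
            "original_codon": s.original,
            "new_codon": s.replacement,
            "cytosines_removed": s.cytosines_removed,
        }
        for s in result.substitutions
    ]
    return pd.DataFrame(
        rows,
        columns=["codon_index", "nt_pos", "original_codon", "new_codon", "cytosines_removed"],
    )
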