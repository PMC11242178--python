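"""Cytosine counting, synonymous recoding and CAI."""

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylbloom.codon_recoding import (
    GENETIC_CODE,
    SYNONYMS,
    CodonError,
    CodonUsageTable,
    cai,
    context_objective,
    count_theoretical_methylation_sites,
    recode_minimize_cytosines,
    substitution_table,
    translate,
)
from methylbloom.sequence_context import enumerate_cytosine_sites

# independent codon table for the translation oracle (hand-typed, not
# derived from the implementation's source)
ORACLE_CODE = {}
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_b1, _b2, _b3) in enumerate(product(_BASES, repeat=3)):
    ORACLE_CODE[_b1 + _b2 + _b3] = _AA[_i]

SENSE = sorted(c for c, aa in ORACLE_CODE.items() if aa != "*")


@pytest.fixture(scope="module")
def uniform_usage():
    return CodonUsageTable({c: 1.0 for c in GENETIC_CODE}, name="uniform")


@pytest.fixture(scope="module")
def ath_usage():
    return CodonUsageTable.arabidopsis()


def random_cds(gen, n_codons, with_stop=True):
    body = [SENSE[i] for i in gen.integers(0, len(SENSE), size=n_codons - 2)]
    return "ATG" + "".join(body) + ("TAA" if with_stop else SENSE[0])


class TestTranslate:
    def test_examples(self):
        assert translate("ATGTGGTAA") == "MW*"
        assert translate("CTGCTA") == "LL"

    def test_matches_independent_codon_table(self, rng):
        for _ in range(30):
            cds = random_cds(rng, 20)
            expected = "".join(ORACLE_CODE[cds[i : i + 3]] for i in range(0, len(cds), 3))
            assert translate(cds) == expected

    def test_internal_stop_rejected(self):
        with pytest.raises(CodonError, match="stop"):
            translate("ATGTAATGG")

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(CodonError, match="divisible"):
            translate("ATGC")


class TestCountMethylatableSites:
    def test_single_cg_cytosine(self):
        counts = count_theoretical_methylation_sites("ATGCGATAA")
        assert counts.total == 1 and counts.cg == 1

    def test_no_cytosines(self):
        assert count_theoretical_methylation_sites("ATGTTTTAA").total == 0

    def test_matches_site_enumerator_oracle(self, rng):
        for _ in range(20):
            cds = random_cds(rng, 100)
            counts = count_theoretical_methylation_sites(cds, "coding_strand")
            sites = [
                s
                for s in enumerate_cytosine_sites(cds, strands="+")
                if s.context != "UNKNOWN"
            ]
            assert counts.total == len(sites)
            duplex = count_theoretical_methylation_sites(cds, "duplex")
            both = [
                s for s in enumerate_cytosine_sites(cds) if s.context != "UNKNOWN"
            ]
            assert duplex.total == len(both)

    def test_every_fully_flanked_c_is_counted(self, rng):
        """total = cytosine count minus flank-truncated sites."""
        cds = random_cds(rng, 50)
        counts = count_theoretical_methylation_sites(cds)
        assert counts.total + counts.unknown_flank == cds.count("C")


def exhaustive_minimum(cds, mode):
    """Brute-force minimum of the context-aware objective over all
    synonymous recodings (start and stop codons held fixed)."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    choice_sets = []
    for i, codon in enumerate(codons):
        aa = GENETIC_CODE[codon]
        if i == 0 or aa == "*":
            choice_sets.append([codon])
        else:
            choice_sets.append(list(SYNONYMS[aa]))
    return min(
        context_objective("".join(combo), mode) for combo in product(*choice_sets)
    )


class TestRecoding:
    def test_five_codon_example_reaches_exhaustive_minimum(self, uniform_usage):
        result = recode_minimize_cytosines("ATGCTGTGCTGGTAA", uniform_usage)
        assert result.recoded_cds in ("ATGTTATGTTGGTAA", "ATGTTGTGTTGGTAA")
        assert result.cytosines_before == 2
        assert result.cytosines_after == 0
        assert result.substituted_cytosine_count == 2
        assert len(result.substitutions) == 2

    def test_no_degeneracy_relief_leaves_sequence_unchanged(self, uniform_usage):
        result = recode_minimize_cytosines("ATGTGGTAA", uniform_usage)
        assert result.recoded_cds == result.original_cds
        assert result.substitutions == ()

    @pytest.mark.parametrize("objective", ["min_C", "min_C_dp"])
    @pytest.mark.parametrize("mode", ["coding_strand", "duplex"])
    def test_protein_preserved_and_cytosines_never_increase(
        self, rng, ath_usage, objective, mode
    ):
        for _ in range(15):
            cds = random_cds(rng, 40)
            result = recode_minimize_cytosines(cds, ath_usage, mode, objective)
            assert translate(result.recoded_cds) == translate(cds)
            assert result.cytosines_after <= result.cytosines_before

    @pytest.mark.parametrize("mode", ["coding_strand", "duplex"])
    def test_dp_objective_is_globally_optimal_small_cds(self, rng, ath_usage, mode):
        for _ in range(12):
            n = int(rng.integers(3, 9))
            cds = random_cds(rng, n)
            result = recode_minimize_cytosines(cds, ath_usage, mode, "min_C_dp")
            achieved = context_objective(result.recoded_cds, mode)
            assert achieved == exhaustive_minimum(cds, mode)

    def test_greedy_is_optimal_for_plain_cytosine_count(self, rng, ath_usage):
        """min_C minimizes the separable per-codon C count exactly."""
        for _ in range(10):
            cds = random_cds(rng, 6)
            result = recode_minimize_cytosines(cds, ath_usage, objective="min_C")
            codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
            best = sum(
                min(s.count("C") for s in SYNONYMS[GENETIC_CODE[c]])
                for c in codons[1:-1]
            ) + codons[0].count("C") + codons[-1].count("C")
            assert result.cytosines_after == best

    def test_tie_break_prefers_high_adaptiveness(self, ath_usage):
        # Leu: zero-C synonyms are TTA (12.6/1000) and TTG (20.9/1000)
        result = recode_minimize_cytosines("ATGCTGTAA", ath_usage)
        assert result.recoded_cds == "ATGTTGTAA"

    def test_substitution_ledger_accounts_for_removed_cytosines(self, rng, ath_usage):
        cds = random_cds(rng, 30)
        result = recode_minimize_cytosines(cds, ath_usage)
        assert (
            sum(s.cytosines_removed for s in result.substitutions)
            == result.substituted_cytosine_count
        )
        table = substitution_table(result)
        assert len(table) == len(result.substitutions)

    def test_usage_table_must_cover_synonyms(self):
        partial = dict.fromkeys(GENETIC_CODE, 1.0)
        with pytest.raises(CodonError):
            del partial["CTG"]
            CodonUsageTable(partial)


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_protein_preservation_property(seed):
    gen = np.random.default_rng(seed)
    cds = random_cds(gen, int(gen.integers(3, 25)))
    result = recode_minimize_cytosines(cds, objective="min_C_dp")
    assert translate(result.recoded_cds) == translate(cds)


class TestCai:
    def test_all_optimal_codons_give_one(self, ath_usage):
        # most frequent synonym per amino acid
        best = {aa: max(cs, key=lambda c: ath_usage.frequencies[c]) for aa, cs in SYNONYMS.items()}
        cds = "ATG" + best["A"] + best["L"] + best["G"] + "TAA"
        assert cai(cds, ath_usage) == pytest.approx(1.0)

    def test_two_codon_geometric_mean(self):
        freqs = dict.fromkeys(GENETIC_CODE, 1.0)
        freqs["GCT"] = 4.0  # Ala max; GCC keeps 1.0 -> w = 0.25
        usage = CodonUsageTable(freqs)
        assert cai("GCCGCT", usage) == pytest.approx(0.5)

    def test_matches_log_domain_oracle(self, rng, ath_usage):
        for _ in range(20):
            cds = random_cds(rng, 60)
            codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
            logs = [
                math.log(ath_usage.w(c))
                for c in codons
                if c not in ("ATG", "TGG", "TAA", "TAG", "TGA")
            ]
            oracle = math.exp(sum(logs) / len(logs))
            assert cai(cds, ath_usage) == pytest.approx(oracle, abs=1e-12)

    def test_met_trp_stop_only_cds(self, ath_usage):
        assert cai("ATGTGGTAA", ath_usage) == 1.0

    def test_recoding_reports_cai_drift(self, rng, ath_usage):
        cds = random_cds(rng, 80)
        result = recode_minimize_cytosines(cds, ath_usage)
        assert 0 < result.cai_after <= 1 and 0 < result.cai_before <= 1
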