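"""Methylation–phenotype–expression association statistics.

Correlation of per-gene methylation statistics with flowering time and leaf
number across accessions, a per-gene significance screen, the 2^-ddCt
relative-expression calculation for qPCR data, Mann–Whitney U group
comparisons (exact by enumeration for small samples), and descriptive
range/spread summaries used to quantify how demethylating treatments
compress phenotypic variation.

Small-sample exactness is deliberate: with a handful of accessions or
replicates, asymptotic p-values are unreliable, so Spearman p-values for
n <= 8 and Mann–Whitney p-values for combined n <= 12 are computed by full
permutation/labeling enumeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EXACT_SPEARMAN_MAX_N = 8
EXACT_MWU_MAX_N = 12


class UndefinedCorrelationError(ValueError):
    """A correlation is undefined (zero variance in an input)."""


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    p_value: float
    n: int
    method: str


@dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR replicate: target and reference (e.g. beta-actin) Ct values."""

    sample: str
    target_ct: float
    reference_ct: float
    replicate: int = 0

    def __post_init__(self) -> None:
        for ct in (self.target_ct, self.reference_ct):
            if not (math.isfinite(ct) and ct > 0):
                raise ValueError(f"Ct values must be finite and positive, got {ct}")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.reference_ct


@dataclass(frozen=True)
class FoldChange:
    """2^-ddCt fold change with an SD-propagated range."""

    fold: float
    low: float
    high: float
    ddct: float


def _rankdata(values: Sequence[float]) -> np.ndarray:
    return stats.rankdata(values, method="average")


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["spearman", "pearson"] = "spearman",
) -> CorrelationResult:
    """Correlation coefficient with a two-sided p-value.

    Spearman uses average ranks for ties; for n <= 8 its p-value is exact,
    computed by enumerating all n! pairings of the rank vectors and counting
    those with |rho| at least the observed. Pearson and larger-n Spearman
    use scipy's standard tests.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in an input vector")

    if method == "pearson":
        r, p = stats.pearsonr(x, y)
        return CorrelationResult(float(r), float(p), n, "pearson")
    if method != "spearman":
        raise ValueError(f"unknown method {method!r}")

    rx, ry = _rankdata(x), _rankdata(y)
    r = float(stats.pearsonr(rx, ry)[0])
    if n <= EXACT_SPEARMAN_MAX_N:
        p = _exact_spearman_p(rx, ry, abs(r))
    else:
        p = float(stats.spearmanr(x, y)[1])
    return CorrelationResult(r, p, n, "spearman")


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, abs_r: float) -> float:
    """Two-sided exact p by enumerating all pairings of the rank vectors."""
    n = len(rx)
    sx = rx - rx.mean()
    denom_x = float(np.sqrt((sx**2).sum()))
    sy = ry - ry.mean()
    denom_y = float(np.sqrt((sy**2).sum()))
    count = 0
    total = 0
    tol = 1e-12
    for perm in permutations(range(n)):
        rho = float(np.dot(sx, sy[list(perm)])) / (denom_x * denom_y)
        if abs(rho) >= abs_r - tol:
            count += 1
        total += 1
    return count / total


def correlation_screen(
    matrix: pd.DataFrame,
    phenotype: Sequence[float] | pd.Series,
    method: Literal["spearman", "pearson"] = "spearman",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene correlation of a methylation matrix against a phenotype.

    Rows of ``matrix`` are accessions aligned with ``phenotype``; columns are
    genes. Significance flags use the raw p < alpha screening rule; a
    Benjamini–Hochberg q-value column is emitted alongside for reference but
    does not drive the flags.
    """
    from statsmodels.stats.multitest import multipletests

    pheno = np.asarray(phenotype, dtype=float)
    if len(pheno) != len(matrix):
        raise ValueError("phenotype length must match matrix rows")
    rows = []
    for gene in matrix.columns:
        res = correlate(matrix[gene].to_numpy(), pheno, method)
        rows.append((gene, res.coefficient, res.p_value, res.n))
    out = pd.DataFrame(rows, columns=["gene_id", "r", "p", "n"]).set_index("gene_id")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["p"] < alpha
    out["method"] = method
    return out


def delta_delta_ct(
    treated: Iterable[QpcrMeasurement], control: Iterable[QpcrMeasurement]
) -> FoldChange:
    """Relative expression of treated vs control by the 2^-ddCt method.

    dCt = target Ct - reference Ct is averaged over replicates within each
    group; ddCt = mean dCt(treated) - mean dCt(control); fold = 2^-ddCt.
    Replicate SDs are combined in quadrature and propagated to a
    [fold / 2^sd, fold * 2^sd] range.
    """
    dct_t = np.array([m.delta_ct for m in treated], dtype=float)
    dct_c = np.array([m.delta_ct for m in control], dtype=float)
    if len(dct_t) == 0 or len(dct_c) == 0:
        raise ValueError("each group needs at least one replicate")
    ddct = float(dct_t.mean() - dct_c.mean())
    fold = 2.0**-ddct
    sd = math.sqrt(
        (dct_t.std(ddof=1) ** 2 if len(dct_t) > 1 else 0.0)
        + (dct_c.std(ddof=1) ** 2 if len(dct_c) > 1 else 0.0)
    )
    return FoldChange(fold=fold, low=fold / 2.0**sd, high=fold * 2.0**sd, ddct=ddct)


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Mann–Whitney U with a two-sided p-value.

    For combined n <= 12 the p-value is exact: all C(n_a + n_b, n_a) group
    labelings are enumerated and labelings with |U - n_a n_b / 2| at least
    the observed deviation are counted (ties handled by midranks, so the
    enumeration remains exact under ties). Larger samples use the normal
    approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("each group needs at least one value")
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = _rankdata(pooled)
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2)

    if na + nb <= EXACT_MWU_MAX_N:
        center = na * nb / 2
        observed_dev = abs(u_a - center)
        count = total = 0
        tol = 1e-9
        idx = range(na + nb)
        for group_a in combinations(idx, na):
            rank_sum = ranks[list(group_a)].sum()
            u = rank_sum - na * (na + 1) / 2
            if abs(u - center) >= observed_dev - tol:
                count += 1
            total += 1
        return u_a, count / total

    _, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_a, float(p)


def range_and_spread(values_by_group: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Descriptive min / max / range / variance per group."""
    rows = []
    for name, values in values_by_group.items():
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
        rows.append(
            {
                "group": name,
                "n": arr.size,
                "min": float(arr.min()),
                "max": float(arr.max()),
                "range": float(np.ptp(arr)),
                "variance": float(arr.var(ddof=1)) if arr.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def range_reduction_ratio(
    before: Sequence[float], after: Sequence[float]
) -> float:
    """range(after) / range(before) — below 1 means the spread contracted."""
    rb = float(np.ptp(np.asarray(before, dtype=float)))
    if rb == 0:
        raise ValueError("zero range in the 'before' group")
    return float(np.ptp(np.asarray(after, dtype=float))) / rb
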