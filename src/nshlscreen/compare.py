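"""Allele-count comparison against a reference cohort.

Each variant detected in both cohorts yields a 2x2 table of alternate vs
non-alternate allele counts by cohort, tested with a two-tailed Fisher exact
test and adjusted for multiple comparisons with the Benjamini-Hochberg
step-up procedure (family size = number of co-detected variants). Both
statistics are implemented here from first principles; the two-tailed p-value
follows the conventional point-probability definition (sum of hypergeometric
outcomes no more probable than the observed table), computed in log space so
large allele counts do not underflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

#: Relative tolerance when deciding "at most as probable as observed".
_REL_TOL = 1e-7


class CompareError(ValueError):
    """Raised on invalid tables or p-values."""


@dataclass(frozen=True)
class AlleleComparison:
    """One variant's study-vs-reference allele-count comparison."""

    variant_key: tuple[str, int, str, str]
    study_alt_alleles: int
    study_total_alleles: int
    ref_alt_alleles: int
    ref_total_alleles: int
    p_value: float
    p_adjusted: float
    significant: bool


def _log_hypergeom_pmf(k: np.ndarray, n1: int, n2: int, m: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeometric(row1=n1, row2=n2, col1=m)."""
    k = np.asarray(k, dtype=np.int64)
    return (
        gammaln(n1 + 1)
        - gammaln(k + 1)
        - gammaln(n1 - k + 1)
        + gammaln(n2 + 1)
        - gammaln(m - k + 1)
        - gammaln(n2 - (m - k) + 1)
        - (gammaln(n1 + n2 + 1) - gammaln(m + 1) - gammaln(n1 + n2 - m + 1))
    )


def fisher_exact_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums the point probabilities of every table with the same margins whose
    probability is at most the observed table's (within relative tolerance
    1e-7). Degenerate tables (a zero margin) give p = 1.
    """
    if min(a, b, c, d) < 0:
        raise CompareError("negative cell in 2x2 table")
    n1, n2 = a + b, c + d
    m = a + c
    if n1 == 0 or n2 == 0 or m == 0 or (b + d) == 0:
        return 1.0
    k = np.arange(max(0, m - n2), min(n1, m) + 1)
    logp = _log_hypergeom_pmf(k, n1, n2, m)
    log_obs = float(_log_hypergeom_pmf(np.array([a]), n1, n2, m)[0])
    include = logp <= log_obs + np.log1p(_REL_TOL)
    # sum in linear space relative to the max for stability
    shift = logp.max()
    p = float(np.exp(shift) * np.exp(logp[include] - shift).sum())
    return min(p, 1.0)


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    p_adj(i) = min over j >= i (by sorted rank) of m * p(j) / j, clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise CompareError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted_sorted
    return out.tolist()


def compare_cohorts(
    study_counts: dict[tuple[str, int, str, str], tuple[int, int]],
    reference_counts: dict[tuple[str, int, str, str], tuple[int, int]],
    alpha: float = 0.05,
    skipped_log: list[str] | None = None,
) -> list[AlleleComparison]:
    """Fisher + BH-FDR comparison over variants present in both cohorts.

    Inputs map variant key -> (alt allele count, total allele count). Only the
    intersection of the two keyed sets is compared (the FDR family size is the
    intersection size); variants with a zero total on either side are skipped
    with a log entry.
    """
    shared = sorted(set(study_counts) & set(reference_counts))
    rows: list[tuple[tuple[str, int, str, str], int, int, int, int]] = []
    for key in shared:
        s_alt, s_tot = study_counts[key]
        r_alt, r_tot = reference_counts[key]
        if s_tot <= 0 or r_tot <= 0:
            if skipped_log is not None:
                skipped_log.append(f"{key}: zero total alleles, skipped")
            continue
        if s_alt > s_tot or r_alt > r_tot:
            raise CompareError(f"{key}: alt count exceeds total")
        rows.append((key, s_alt, s_tot, r_alt, r_tot))
    p_values = [
        fisher_exact_two_tailed(s_alt, s_tot - s_alt, r_alt, r_tot - r_alt)
        for _, s_alt, s_tot, r_alt, r_tot in rows
    ]
    adjusted = bh_fdr(p_values)
    return [
        AlleleComparison(
            variant_key=key,
            study_alt_alleles=s_alt,
            study_total_alleles=s_tot,
            ref_alt_alleles=r_alt,
            ref_total_alleles=r_tot,
            p_value=p,
            p_adjusted=p_adj,
            significant=p_adj < alpha,
        )
        for (key, s_alt, s_tot, r_alt, r_tot), p, p_adj in zip(rows, p_values, adjusted)
    ]


def read_reference_counts(
    path,
) -> dict[tuple[str, int, str, str], tuple[int, int]]:
    """Read a reference-cohort allele-count TSV.

    Columns: contig, pos, ref, alt, alt_allele_count, total_alleles.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return {
        (r.contig, int(r.pos), r.ref, r.alt): (
            int(r.alt_allele_count),
            int(r.total_alleles),
        )
        for r in df.itertuples(index=False)
    }
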