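"""Fisher exact test, Benjamini-Hochberg FDR and cohort comparison."""

import math

import numpy as np
import pytest
from scipy import stats

from nshlscreen.compare import (
    CompareError,
    bh_fdr,
    compare_cohorts,
    fisher_exact_two_tailed,
)


def _enumeration_fisher(a, b, c, d):
    """Independent oracle: exact-fraction hypergeometric enumeration."""
    n1, n2, m = a + b, c + d, a + c
    if n1 == 0 or n2 == 0 or m == 0 or b + d == 0:
        return 1.0
    total = math.comb(n1 + n2, m)
    obs = math.comb(n1, a) * math.comb(n2, c)
    acc = 0
    for k in range(max(0, m - n2), min(n1, m) + 1):
        pk = math.comb(n1, k) * math.comb(n2, m - k)
        if pk <= obs * (1 + 1e-7):
            acc += pk
    return acc / total


def test_symmetric_and_degenerate_tables_give_p_one():
    assert fisher_exact_two_tailed(5, 5, 5, 5) == 1.0
    assert fisher_exact_two_tailed(0, 10, 0, 7) == 1.0   # zero alt column
    assert fisher_exact_two_tailed(0, 0, 3, 4) == 1.0    # zero row
    assert fisher_exact_two_tailed(4, 0, 3, 0) == 1.0    # zero non-alt column


def test_negative_cells_rejected():
    with pytest.raises(CompareError):
        fisher_exact_two_tailed(-1, 2, 3, 4)


def test_fisher_matches_enumeration_and_scipy_on_random_tables():
    rng = np.random.default_rng(9)
    for _ in range(200):
        a, b, c, d = (int(rng.integers(0, 31)) for _ in range(4))
        p = fisher_exact_two_tailed(a, b, c, d)
        assert p == pytest.approx(_enumeration_fisher(a, b, c, d), rel=1e-9)
        if min(a + b, c + d) > 0 and (a + c) > 0 and (b + d) > 0:
            scipy_p = stats.fisher_exact([[a, b], [c, d]])[1]
            assert p == pytest.approx(scipy_p, rel=1e-7, abs=1e-12)


def test_fisher_stable_for_large_counts():
    # cohort-scale margins; compare with scipy (which uses the same
    # point-probability definition)
    p = fisher_exact_two_tailed(25, 4169, 80, 2262)
    scipy_p = stats.fisher_exact([[25, 4169], [80, 2262]])[1]
    assert p == pytest.approx(scipy_p, rel=1e-6)
    assert p < 1e-10


def test_fisher_symmetric_under_row_and_column_swaps():
    rng = np.random.default_rng(10)
    for _ in range(50):
        a, b, c, d = (int(rng.integers(0, 25)) for _ in range(4))
        p = fisher_exact_two_tailed(a, b, c, d)
        assert p == pytest.approx(fisher_exact_two_tailed(c, d, a, b), rel=1e-9)
        assert p == pytest.approx(fisher_exact_two_tailed(b, a, d, c), rel=1e-9)


def _bh_definition(ps):
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    out = [0.0] * m
    for rank_pos, i in enumerate(order):
        candidates = [
            m * ps[order[j]] / (j + 1) for j in range(rank_pos, m)
        ]
        out[i] = min(1.0, min(candidates))
    return out


def test_bh_matches_stepup_definition_and_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(11)
    for _ in range(100):
        m = int(rng.integers(1, 21))
        ps = rng.uniform(1e-6, 1.0, m).tolist()
        got = bh_fdr(ps)
        assert got == pytest.approx(_bh_definition(ps), rel=1e-12)
        sm = multipletests(ps, method="fdr_bh")[1]
        assert got == pytest.approx(sm.tolist(), rel=1e-12)


def test_bh_trivial_cases_and_input_validation():
    assert bh_fdr([0.37]) == [0.37]
    assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])
    assert bh_fdr([]) == []
    with pytest.raises(CompareError):
        bh_fdr([0.0, 0.5])
    with pytest.raises(CompareError):
        bh_fdr([1.5])


def test_bh_permutation_equivariant_and_monotone():
    rng = np.random.default_rng(12)
    ps = rng.uniform(1e-4, 1.0, 12).tolist()
    adj = bh_fdr(ps)
    perm = rng.permutation(12)
    adj_perm = bh_fdr([ps[i] for i in perm])
    assert adj_perm == pytest.approx([adj[i] for i in perm])
    # raising one raw p never lowers any adjusted p
    bumped = list(ps)
    bumped[3] = min(1.0, bumped[3] * 2)
    adj_bumped = bh_fdr(bumped)
    assert all(b >= a - 1e-12 for a, b in zip(adj, adj_bumped))


def _key(i):
    return ("chr1", 100 + i, "A", "G")


def test_identical_cohorts_show_no_significant_differences():
    study = {_key(i): (5 + i, 4000) for i in range(10)}
    comps = compare_cohorts(study, dict(study))
    assert len(comps) == 10
    assert all(not c.significant for c in comps)
    assert all(c.p_value == pytest.approx(1.0) for c in comps)


def test_comparison_restricted_to_intersection_and_skips_zero_totals():
    study = {_key(0): (5, 4000), _key(1): (3, 4000), _key(2): (2, 0)}
    reference = {_key(1): (2, 2000), _key(2): (1, 2000), _key(3): (9, 2000)}
    skipped: list[str] = []
    comps = compare_cohorts(study, reference, skipped_log=skipped)
    assert [c.variant_key for c in comps] == [_key(1)]
    assert len(skipped) == 1


def test_flags_match_oracle_composition():
    rng = np.random.default_rng(13)
    study, reference = {}, {}
    for i in range(15):
        study[_key(i)] = (int(rng.integers(0, 40)), 4000)
        reference[_key(i)] = (int(rng.integers(0, 40)), 2000)
    comps = compare_cohorts(study, reference, alpha=0.05)
    ps = [
        _enumeration_fisher(s, 4000 - s, r, 2000 - r)
        for (s, _), (r, _) in (
            (study[c.variant_key], reference[c.variant_key]) for c in comps)
    ]
    adj = _bh_definition(ps)
    for c, p, q in zip(comps, ps, adj):
        assert c.p_value == pytest.approx(p, rel=1e-9)
        assert c.p_adjusted == pytest.approx(q, rel=1e-9)
        assert c.significant == (q < 0.05)
    assert all(c.p_adjusted >= c.p_value - 1e-15 for c in comps)
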