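import numpy as np
import pytest
from scipy import stats

from gcimsvoc.cohort_stats import (ContingencyTable, fisher_exact_2x2,
                                   fisher_freeman_halton, kruskal_wallis,
                                   table1_report, total_margin_probability)
from gcimsvoc.io import Cohort, SampleRecord
from gcimsvoc.datasets import baseline_dichotomous_counts

from conftest import make_chrom


def hypergeometric_oracle_2x2(table):
    """Independent 1-D enumeration of the 2x2 conditional family."""
    t = np.asarray(table)
    r1, r2 = t.sum(axis=1)
    c1 = t[:, 0].sum()
    n = t.sum()
    obs = stats.hypergeom.pmf(t[0, 0], n, r1, c1)
    p = 0.0
    for a in range(max(0, c1 - r2), min(r1, c1) + 1):
        pr = stats.hypergeom.pmf(a, n, r1, c1)
        if pr <= obs * (1 + 1e-7):
            p += pr
    return min(p, 1.0)


def random_table(rng, shape=(2, 2), total_max=40):
    while True:
        t = rng.integers(0, total_max // 2, shape)
        if t.sum() > 0 and t.sum() <= total_max:
            return t


# --------------------------------------------------------------- fisher 2x2

def test_fisher_matches_enumeration_oracle_for_small_totals(rng):
    for _ in range(80):
        t = random_table(rng)
        assert fisher_exact_2x2(t).p_value == pytest.approx(
            hypergeometric_oracle_2x2(t), abs=1e-10), t


@pytest.mark.parametrize("table,expected", [
    ([[2, 11], [5, 2]], 0.022),   # immunosuppressants, 2/13 vs 5/7
    ([[5, 2], [0, 10]], 0.003),   # immunosuppressants, 5/7 vs 0/10
])
def test_fisher_reproduces_printed_subanalysis_pvalues(table, expected):
    assert round(fisher_exact_2x2(table).p_value, 3) == expected


def test_fisher_degenerate_margin_gives_one():
    assert fisher_exact_2x2([[0, 0], [3, 5]]).p_value == 1.0
    assert fisher_exact_2x2([[0, 4], [0, 6]]).p_value == 1.0


def test_fisher_rejects_non_2x2():
    with pytest.raises(ValueError, match="2x2"):
        fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])


# --------------------------------------------------------------- FFH

def test_ffh_equals_fisher_on_2x2_tables(rng):
    for _ in range(30):
        t = random_table(rng, total_max=30)
        assert fisher_freeman_halton(t).p_value == pytest.approx(
            fisher_exact_2x2(t).p_value, abs=1e-9)


@pytest.mark.parametrize("table,expected", [
    ([[2, 11], [5, 2], [0, 10]], 0.002),   # immunosuppressive therapy
    ([[10, 3], [3, 4], [6, 4]], 0.314),    # female sex
    ([[1, 12], [0, 7], [1, 9]], 1.000),    # current smoking
    ([[5, 8], [6, 1], [4, 6]], 0.130),     # proton pump inhibitors
    ([[4, 9], [2, 5], [0, 10]], 0.121),    # antibiotics
])
def test_ffh_reproduces_printed_three_group_pvalues(table, expected):
    assert round(fisher_freeman_halton(table).p_value, 3) == expected


def test_ffh_family_probabilities_sum_to_one(rng):
    for shape in [(2, 2), (3, 2), (3, 3)]:
        t = random_table(rng, shape=shape, total_max=24)
        assert total_margin_probability(t) == pytest.approx(1.0, abs=1e-9)


def test_ffh_pvalue_never_exceeds_one(rng):
    for _ in range(20):
        t = random_table(rng, shape=(3, 2), total_max=30)
        assert 0.0 < fisher_freeman_halton(t).p_value <= 1.0


def test_ffh_budget_exceeded_raises():
    t = [[8, 9, 7], [9, 8, 9], [7, 9, 8]]
    with pytest.raises(RuntimeError, match="budget"):
        fisher_freeman_halton(t, budget=10)


def test_contingency_table_validation():
    with pytest.raises(ValueError):
        ContingencyTable(np.array([[1, -1], [2, 3]]))
    with pytest.raises(ValueError):
        ContingencyTable(np.array([[0, 0], [0, 0]]))
    with pytest.raises(ValueError):
        ContingencyTable(np.array([[1, 2]]))


# --------------------------------------------------------------- KW

def test_kruskal_identical_constants():
    res = kruskal_wallis([[5.0, 5.0, 5.0], [5.0, 5.0]])
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_kruskal_two_groups_tracks_ranksum(rng):
    from gcimsvoc.selection import ranksum_pvalue
    x = rng.normal(0.0, 1.0, 25)
    y = rng.normal(0.8, 1.0, 25)
    kw = kruskal_wallis([x, y]).p_value
    rs = ranksum_pvalue(x, y)
    assert kw == pytest.approx(rs, abs=0.02)


def test_kruskal_three_groups_agrees_with_permutation_oracle(rng):
    groups = [rng.normal(0, 1, 6), rng.normal(0.9, 1, 5),
              rng.normal(0.3, 1, 7)]
    observed = kruskal_wallis(groups)
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    count = 0
    n_perm = 4000
    for _ in range(n_perm):
        rng.shuffle(pooled)
        parts = np.split(pooled, np.cumsum(sizes)[:-1])
        h = stats.kruskal(*parts).statistic
        count += h >= observed.statistic - 1e-12
    mc_p = count / n_perm
    assert observed.p_value == pytest.approx(mc_p, abs=0.05)


def test_kruskal_rejects_empty_group():
    with pytest.raises(ValueError):
        kruskal_wallis([[1.0], []])


# --------------------------------------------------------------- table 1

def cohort_from_counts(counts, continuous=False, order=("CD", "RCD", "HC"),
                       shuffle_seed=None):
    """Build a cohort whose dichotomous covariates realise given counts."""
    rng = np.random.default_rng(0)
    records = []
    chroms = {}
    for g in order:
        n = next(iter(counts.values()))[g][1]
        for i in range(n):
            cov = {}
            for var, per_group in counts.items():
                yes, _ = per_group[g]
                cov[var if var != "sex_female" else "sex"] = (
                    ("female" if i < yes else "male")
                    if var == "sex_female" else i < yes)
            if continuous:
                cov["age"] = float(rng.integers(30, 80))
                cov["bmi"] = float(rng.uniform(19, 33))
                cov["bristol_stool_score"] = float(rng.integers(1, 7))
            sid = f"{g}{i}"
            records.append(SampleRecord(sid, g, cov))
            chroms[sid] = make_chrom([[0.0]], sample_id=sid)
    if shuffle_seed is not None:
        perm = np.random.default_rng(shuffle_seed).permutation(len(records))
        records = [records[i] for i in perm]
    return Cohort(records=records, chromatograms=chroms)


PRINTED_TABLE1 = {
    # variable: (p_all, p_cd_hc, p_rcd_hc, p_cd_rcd)
    "sex": (0.314, 0.650, 0.637, 0.174),
    "smoking": (1.000, 1.000, 1.000, 1.000),
    "ppi": (0.130, 1.000, 0.134, 0.070),
    "antibiotics": (0.121, 0.104, 0.154, 1.000),
    "immunosuppressants": (0.002, 0.486, 0.003, 0.022),
}


def test_table1_reproduces_every_printed_dichotomous_pvalue():
    cohort = cohort_from_counts(baseline_dichotomous_counts())
    with pytest.warns(UserWarning):       # continuous covariates absent
        report = table1_report(cohort, group_order=["CD", "RCD", "HC"])
    for var, (p_all, p_cd_hc, p_rcd_hc, p_cd_rcd) in PRINTED_TABLE1.items():
        entry = report[var]
        assert round(entry["overall"].p_value, 3) == p_all, var
        assert round(entry["pairwise"][("CD", "HC")].p_value, 3) == p_cd_hc
        assert round(entry["pairwise"][("RCD", "HC")].p_value, 3) == p_rcd_hc
        assert round(entry["pairwise"][("CD", "RCD")].p_value, 3) == p_cd_rcd


def test_table1_includes_continuous_variables_when_present():
    cohort = cohort_from_counts(baseline_dichotomous_counts(),
                                continuous=True)
    report = table1_report(cohort, group_order=["CD", "RCD", "HC"])
    assert report["age"]["kind"] == "continuous"
    assert report["age"]["overall"].method == "kruskal_wallis"
    assert "median" in report["age"]["summary"]["CD"]


def test_table1_invariant_to_sample_order():
    a = cohort_from_counts(baseline_dichotomous_counts(), continuous=True)
    b = cohort_from_counts(baseline_dichotomous_counts(), continuous=True,
                           shuffle_seed=99)
    ra = table1_report(a, group_order=["CD", "RCD", "HC"])
    rb = table1_report(b, group_order=["CD", "RCD", "HC"])
    for var in ra:
        assert ra[var]["overall"].p_value == pytest.approx(
            rb[var]["overall"].p_value, abs=1e-12)


def test_table1_single_group_rejected():
    cohort = cohort_from_counts(
        {"smoking": {"CD": (1, 3)}}, order=("CD",))
    with pytest.raises(ValueError, match="two groups"):
        table1_report(cohort)
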