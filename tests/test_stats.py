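"""Paired inference, Holm-Bonferroni step-down, comparison-table assembly."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

import spinevoi as sv
from spinevoi.phantom import CohortSpec, GroupDistribution, generate_cohort
from spinevoi.stats import build_comparison_table, holm_bonferroni, paired_compare


# ---------------------------------------------------------------------------
# paired_compare
# ---------------------------------------------------------------------------

def test_zero_mean_differences_give_t_zero_p_one():
    res = paired_compare([0.0, 1.2, 2.8], [1.0, 1.0, 2.0])  # d = -1, 0.2, 0.8
    assert res.test_used == "paired_t"
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)
    assert res.mean_difference == pytest.approx(0.0, abs=1e-12)


def test_textbook_paired_t_example():
    # differences 1, 2, 3, 4: t = 2.5 / (sqrt(5/3)/2) = 3.873, df 3, p = 0.0305
    res = paired_compare([2, 4, 6, 8], [1, 2, 3, 4])
    assert res.test_used == "paired_t"
    assert res.statistic == pytest.approx(3.8730, abs=1e-3)
    assert res.p_value == pytest.approx(0.03047, abs=2e-4)
    assert res.ci95[0] < res.mean_difference < res.ci95[1]


def test_wilcoxon_exact_p_matches_sign_enumeration():
    """Heavy-tailed n = 6 differences fail the normality gate; the exact
    Wilcoxon p must equal the brute-force enumeration over all 2^6 sign
    assignments of the absolute differences."""
    d = np.array([0.1, -0.2, 0.15, 0.12, 0.18, 50.0])
    res = paired_compare(d, np.zeros(6))
    assert res.test_used == "wilcoxon"
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    dist = np.array([sum(r for s, r in zip(signs, ranks) if s)
                     for signs in product([0, 1], repeat=6)])
    p_enum = min(1.0, 2 * min((dist <= w_obs).mean(), (dist >= w_obs).mean()))
    assert res.p_value == pytest.approx(p_enum, rel=1e-12)


def test_label_swap_negates_difference_and_keeps_p():
    rng = np.random.default_rng(8)
    case = rng.normal(5, 1, 12)
    ctrl = rng.normal(4.5, 1, 12)
    a = paired_compare(case, ctrl)
    b = paired_compare(ctrl, case)
    assert b.mean_difference == pytest.approx(-a.mean_difference)
    assert b.ci95[0] == pytest.approx(-a.ci95[1])
    assert b.ci95[1] == pytest.approx(-a.ci95[0])
    assert b.p_value == pytest.approx(a.p_value, rel=1e-12)
    assert b.test_used == a.test_used


def test_degenerate_and_insufficient_inputs():
    with pytest.raises(sv.DegenerateVarianceError):
        paired_compare([2, 3, 4], [1, 2, 3])  # all differences = 1
    with pytest.raises(sv.InsufficientDataError):
        paired_compare([1, 2], [0, 1])


# ---------------------------------------------------------------------------
# holm_bonferroni
# ---------------------------------------------------------------------------

def test_holm_published_family_of_27():
    """The published 27 comparisons: smallest p = 0.015 exceeds the
    first-step level 0.05/27, which rounds to 0.002; nothing is rejected."""
    ps = sv.reference.published_table().p.to_numpy()
    assert ps.min() == pytest.approx(0.015)
    res = holm_bonferroni(ps, alpha=0.05)
    assert res.m == 27
    assert res.n_rejected == 0
    assert round(res.steps[0].threshold, 3) == 0.002


def test_holm_single_test_reduces_to_alpha():
    assert holm_bonferroni([0.03]).n_rejected == 1
    assert holm_bonferroni([0.07]).n_rejected == 0


def test_holm_hand_stepdown_example():
    res = holm_bonferroni([0.001, 0.02, 0.04])
    assert [round(s.threshold, 4) for s in res.steps] == [0.0167, 0.025, 0.05]
    assert res.n_rejected == 3


def test_holm_stops_at_first_failure():
    # 0.03 fails step 1 (0.0167); 0.001-level later p must not be rejected
    res = holm_bonferroni([0.03, 0.032, 0.031])
    assert res.n_rejected == 0
    rejected_flags = [s.rejected for s in res.steps]
    assert rejected_flags == sorted(rejected_flags, reverse=True)  # prefix


def test_holm_literal_variant_uses_fixed_threshold():
    ps = [0.0015, 0.001, 0.04]
    assert holm_bonferroni(ps, variant="standard").n_rejected == 3
    assert holm_bonferroni(ps, variant="literal_fixed").n_rejected == 2


def test_holm_matches_statsmodels_on_random_p_vectors():
    rng = np.random.default_rng(17)
    for _ in range(20):
        m = int(rng.integers(1, 40))
        ps = rng.beta(0.3, 3.0, size=m)
        ours = holm_bonferroni(ps, ids=list(range(m)))
        ref, _, _, _ = multipletests(ps, alpha=0.05, method="holm")
        assert ours.rejected_ids() == set(np.flatnonzero(ref))


def test_holm_sandwich_between_bonferroni_and_unadjusted():
    rng = np.random.default_rng(23)
    for _ in range(20):
        m = int(rng.integers(2, 30))
        ps = rng.random(m) ** 2
        holm = holm_bonferroni(ps, ids=list(range(m))).rejected_ids()
        bonf = {i for i, p in enumerate(ps) if p < 0.05 / m}
        raw = {i for i, p in enumerate(ps) if p < 0.05}
        assert bonf <= holm <= raw


def test_holm_rejects_invalid_p():
    with pytest.raises(sv.ParameterError):
        holm_bonferroni([0.2, 1.3])
    with pytest.raises(sv.ParameterError):
        holm_bonferroni([])


# ---------------------------------------------------------------------------
# comparison table
# ---------------------------------------------------------------------------

def test_comparison_table_has_27_rows_on_default_cohort():
    _, cohort = generate_cohort(CohortSpec(n_pairs=12, seed=5))
    table, holm = build_comparison_table(cohort)
    assert len(table) == 27
    assert (table.gap_reason == "").all()
    assert holm.m == 27
    assert set(table.test_used) <= {"paired_t", "wilcoxon"}
    # CI always brackets the mean difference
    ok = (table.ci_low <= table.difference) & (table.difference <= table.ci_high)
    assert ok.all()


def test_comparison_table_single_cell():
    spec = CohortSpec(n_pairs=12,
                      distributions={("PET_NaF", "intervertebral_discs", "max"):
                                     GroupDistribution(11.63, 3.29, 9.45, 1.32)},
                      seed=2)
    _, cohort = generate_cohort(spec)
    table, holm = build_comparison_table(cohort)
    assert len(table) == 1 and holm.m == 1


def test_comparison_table_summary_formats():
    _, cohort = generate_cohort(CohortSpec(n_pairs=12, seed=5))
    table, _ = build_comparison_table(cohort)
    normal = table[table.test_used == "paired_t"]
    assert normal.case_summary.str.contains("±").all()
    skew = table[table.test_used == "wilcoxon"]
    if len(skew):
        assert skew.case_summary.str.contains(r"\(").all()


def test_comparison_table_gap_row_for_incomplete_cell():
    _, cohort = generate_cohort(
        CohortSpec(n_pairs=12,
                   distributions={("PET_NaF", "intervertebral_discs", "max"):
                                  GroupDistribution(1, 1, 1, 1)}, seed=2))
    broken = cohort[~((cohort.group == "control") & (cohort.pair_id != "P01"))]
    table, holm = build_comparison_table(broken)
    assert len(table) == 1
    assert table.gap_reason.iloc[0] != ""
    assert holm.m == 0
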