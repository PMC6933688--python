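"""Accuracy statistics: IQS, error taxonomy, correlations, scans, comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import herdimpute as hi
from herdimpute import metrics
from herdimpute.lsimpute import IMPUTED, OBSERVED, ImputationResult

from conftest import make_matrix
from oracles import kappa_from_table, random_contingency_table


# ---------------------------------------------------------------------------
# error taxonomy
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "truth,imputed,expected",
    [
        (0, 0, "correct"),
        (0, 1, "false_het"),  # AA imputed as AB
        (2, 1, "false_het"),
        (1, 0, "false_hom"),  # AB imputed as AA
        (1, 2, "false_hom"),
        (0, 2, "discordant"),  # opposite homozygotes
        (2, 0, "discordant"),
    ],
)
def test_error_taxonomy(truth, imputed, expected):
    assert hi.classify_errors(truth, imputed) == expected


def test_classify_rejects_missing():
    with pytest.raises(ValueError):
        hi.classify_errors(np.array([0, -1]), np.array([1, 1]))


# ---------------------------------------------------------------------------
# IQS
# ---------------------------------------------------------------------------

def test_iqs_perfect_agreement_is_one():
    assert hi.iqs([0, 1, 2, 1], [0, 1, 2, 1]) == pytest.approx(1.0)


def test_iqs_constant_imputation_scores_zero_despite_high_concordance():
    truth = np.array([0] * 46 + [1] * 3)
    imputed = np.zeros(49, dtype=int)
    table = metrics.contingency_table(truth, imputed)
    assert metrics.concordance_from_table(table) == pytest.approx(46 / 49)
    assert hi.iqs(truth, imputed) == pytest.approx(0.0)


def test_iqs_hand_computed_table():
    table = np.array([[6, 0, 0], [1, 2, 0], [0, 0, 1]])
    # P0 = 0.9, Pc = (6*7 + 3*2 + 1*1)/100 = 0.49 -> 0.41/0.51
    assert metrics.iqs_from_table(table) == pytest.approx(0.41 / 0.51)


def test_iqs_both_sides_constant():
    assert hi.iqs([0, 0, 0], [0, 0, 0]) == pytest.approx(1.0)
    assert hi.iqs([0, 0, 0], [2, 2, 2]) == pytest.approx(0.0)


def test_iqs_can_be_negative():
    # systematic disagreement worse than chance
    assert hi.iqs([0, 0, 2, 2], [2, 2, 0, 0]) < 0


def test_iqs_matches_kappa_oracle_on_random_tables():
    rng = np.random.default_rng(12)
    for _ in range(1000):
        table = random_contingency_table(rng)
        assert metrics.iqs_from_table(table) == pytest.approx(
            kappa_from_table(table), abs=1e-12
        )


def test_iqs_matches_sklearn_kappa():
    from sklearn.metrics import cohen_kappa_score

    rng = np.random.default_rng(7)
    for _ in range(50):
        t = rng.integers(0, 3, 40)
        i = rng.integers(0, 3, 40)
        if len(set(t)) < 2 or len(set(i)) < 2:
            continue
        assert hi.iqs(t, i) == pytest.approx(
            cohen_kappa_score(t, i, labels=[0, 1, 2]), abs=1e-12
        )


@settings(derandomize=True, deadline=None, max_examples=300)
@given(cells=st.lists(st.integers(0, 30), min_size=9, max_size=9))
def test_iqs_never_exceeds_concordance(cells):
    table = np.array(cells).reshape(3, 3)
    if table.sum() == 0:
        return
    iqs_v = metrics.iqs_from_table(table)
    assert iqs_v <= metrics.concordance_from_table(table) + 1e-12


def test_fixed_site_behavior_exhaustive_small_tables():
    """Single-constant tables score 0; both-constant-equal score 1 (N <= 20)."""
    for n in range(1, 21):
        for g in range(3):
            for c0 in range(n + 1):
                for c1 in range(n + 1 - c0):
                    c2 = n - c0 - c1
                    table = np.zeros((3, 3), dtype=int)
                    table[g] = [c0, c1, c2]  # truth constant at class g
                    cols = [c0, c1, c2]
                    if cols.count(0) == 2:  # imputed constant too
                        h = cols.index(n)
                        expected = 1.0 if h == g else 0.0
                    else:
                        expected = 0.0
                    assert metrics.iqs_from_table(table) == pytest.approx(expected)
                    assert metrics.iqs_from_table(table.T) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Pearson r
# ---------------------------------------------------------------------------

def test_pearson_identical_vectors():
    assert hi.pearson_r([0, 1, 2, 0], [0, 1, 2, 0]) == pytest.approx(1.0)
    assert hi.pearson_r(
        [0, 1, 2, 0], [0, 1, 2, 0], centering="maf-centered", maf=[0.1] * 4
    ) == pytest.approx(1.0)


def test_pearson_hand_value():
    assert hi.pearson_r([0, 1, 2, 1], [0, 1, 1, 1]) == pytest.approx(1.0 / np.sqrt(1.5))


def test_pearson_zero_variance_is_sentinel():
    assert np.isnan(hi.pearson_r([0, 0, 0], [0, 1, 0]))


def test_pearson_centered_requires_maf():
    with pytest.raises(ValueError):
        hi.pearson_r([0, 1], [1, 0], centering="maf-centered")


# ---------------------------------------------------------------------------
# per-variant / per-individual reports
# ---------------------------------------------------------------------------

def _result_from(best, provenance=None, chrom=None):
    best = np.asarray(best, dtype=np.int8)
    n, m = best.shape
    mm = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": (np.arange(m) + 1) * 100,
            "id": [f"m{j}" for j in range(m)],
            "ref": ["A"] * m,
            "alt": ["C"] * m,
        }
    )
    prov = (
        np.full(best.shape, IMPUTED, dtype=np.uint8)
        if provenance is None
        else provenance
    )
    return ImputationResult(
        dosage=best.astype(float),
        best_guess=best,
        provenance=prov,
        marker_map=mm,
        sample_ids=[f"s{i}" for i in range(n)],
    )


def test_perfect_imputation_scores_perfectly():
    truth = make_matrix([[0, 1, 2], [1, 1, 0], [2, 0, 1]])
    res = _result_from(truth.calls)
    va = hi.per_variant_accuracy(truth, res, maf=truth.maf())
    assert (va["iqs"] == 1.0).all()
    assert (va["n_errors"] == 0).all()
    ia = hi.per_individual_accuracy(truth, res, maf=truth.maf())
    assert (ia["total_errors"] == 0).all()


def test_single_injected_error_is_conserved():
    truth = make_matrix([[1, 1, 2], [1, 0, 0], [0, 2, 1]])
    best = truth.calls.copy()
    best[0, 0] = 0  # AB imputed as AA: false homozygote
    res = _result_from(best)
    va = hi.per_variant_accuracy(truth, res, maf=truth.maf())
    assert va.loc[va["marker_id"] == "m0", "n_false_hom"].item() == 1
    assert va["n_errors"].sum() == 1
    ia = hi.per_individual_accuracy(truth, res, maf=truth.maf())
    assert ia.loc[ia["sample_id"] == "s0", "total_errors"].item() == 1
    assert ia["total_errors"].sum() == va["n_errors"].sum()


def test_observed_entries_are_not_scored():
    truth = make_matrix([[0, 1], [2, 1]])
    best = np.array([[2, 1], [0, 1]], dtype=np.int8)  # wrong only at observed col
    prov = np.array([[OBSERVED, IMPUTED], [OBSERVED, IMPUTED]], dtype=np.uint8)
    res = _result_from(best, provenance=prov)
    va = hi.per_variant_accuracy(truth, res, maf=truth.maf())
    assert va["marker_id"].tolist() == ["m1"]
    assert va["n_errors"].sum() == 0


def test_maf_bins_half_open_with_fixed_bin():
    bins = metrics.assign_maf_bins(np.array([0.0, 0.01, 0.05, 0.0501, 0.5]))
    assert bins.tolist() == [
        "fixed", "(0.00,0.05]", "(0.00,0.05]", "(0.05,0.10]", "(0.45,0.50]"
    ]


def test_error_conservation_on_study_run(study_sweep):
    for run in study_sweep.values():
        va, ia = run["va"], run["ia"]
        assert (
            va[["n_false_het", "n_false_hom", "n_discordant"]].sum(axis=1)
            == va["n_errors"]
        ).all()
        assert va["n_errors"].sum() == ia["total_errors"].sum()
        assert (
            ia[["n_false_het", "n_false_hom", "n_discordant"]].sum(axis=1)
            == ia["total_errors"]
        ).all()


def test_raw_and_centered_individual_r_agree(study_sweep):
    ia = study_sweep["SNP50"]["ia"]
    rho = stats.spearmanr(ia["r_raw"], ia["r_centered"]).statistic
    assert rho > 0.99


def test_binned_iqs_rises_from_rare_to_common(study_sweep):
    """Mean IQS is lowest in the rarest bin and higher at common MAF."""
    b = study_sweep["SNP50"]["binned"].set_index("maf_bin")
    assert b.loc["(0.00,0.05]", "iqs"] < b.loc["(0.20,0.25]", "iqs"]
    assert b.loc["(0.00,0.05]", "iqs"] < b.loc["(0.45,0.50]", "iqs"]


# ---------------------------------------------------------------------------
# region scan
# ---------------------------------------------------------------------------

def _va_frame(iqs_values, errors=None, chrom="1"):
    m = len(iqs_values)
    return pd.DataFrame(
        {
            "marker_id": [f"m{j}" for j in range(m)],
            "chrom": [chrom] * m,
            "pos": (np.arange(m) + 1) * 100,
            "maf": [0.3] * m,
            "iqs": iqs_values,
            "n_errors": errors if errors is not None else [0] * m,
        }
    )


def test_region_scan_clean_input_flags_nothing():
    assert hi.region_scan(_va_frame([1.0] * 200)).empty


def test_region_scan_flags_window_above_fraction():
    vals = [1.0] * 200
    vals[50:65] = [0.0] * 15  # 15/50 = 0.3 > 0.2 in the second window
    flagged = hi.region_scan(_va_frame(vals))
    assert len(flagged) == 1
    assert flagged.iloc[0]["n_breaching"] == 15


def test_region_scan_error_threshold_also_breaches():
    errs = [0] * 100
    errs[10:25] = [11] * 15
    flagged = hi.region_scan(_va_frame([1.0] * 100, errors=errs))
    assert len(flagged) == 1


# ---------------------------------------------------------------------------
# panel comparison
# ---------------------------------------------------------------------------

def test_compare_identical_panels_is_null():
    va = _va_frame([0.9] * 30)
    comp = hi.compare_panels(va, va.copy())
    assert comp.mean_diff == 0
    assert comp.n_improved == comp.n_worsened == 0
    assert comp.n_unchanged == 30


def test_compare_shifted_half_improves():
    a = _va_frame([0.5] * 40)
    b = a.copy()
    b.loc[:19, "iqs"] += 0.1
    comp = hi.compare_panels(a, b)
    assert comp.n_improved == 20 and comp.n_worsened == 0
    assert comp.t_stat > 0
    assert comp.mean_gain_improved == pytest.approx(0.1)


def test_paired_t_matches_scipy_on_hand_data():
    x = np.array([0.91, 0.85, 0.97, 0.80, 0.88, 0.93, 0.79, 0.90, 0.84, 0.95])
    y = x + np.array([0.02, -0.01, 0.00, 0.05, 0.01, 0.02, 0.04, -0.02, 0.03, 0.01])
    a, b = _va_frame(x), _va_frame(y)
    comp = hi.compare_panels(a, b)
    t_ref, p_ref = stats.ttest_rel(y, x)
    assert comp.t_stat == pytest.approx(float(t_ref), abs=1e-10)
    assert comp.t_pvalue == pytest.approx(float(p_ref), abs=1e-12)


def test_compare_requires_matching_markers():
    a, b = _va_frame([0.9] * 5), _va_frame([0.9] * 6)
    with pytest.raises(ValueError):
        hi.compare_panels(a, b)
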