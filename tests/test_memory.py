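"""Recognition scoring, exclusion, analysis-table construction and follow-ups."""

import numpy as np
import pandas as pd
import pytest

from pemem.memory import (binned_pe_analysis, bonferroni, build_analysis_table,
                          derive_trial_pe, dprime_from_counts,
                          dprime_from_rates, fit_mixed_logistic,
                          permutation_exclusion, score_recognition,
                          simple_slopes, _quartile_bins, _validate_random_terms)


def _rec(subject, old_resp, new_resp):
    n_old, n_new = len(old_resp), len(new_resp)
    return pd.DataFrame(dict(
        subject=subject,
        object_id=[f"o{i}" for i in range(n_old + n_new)],
        status=["old"] * n_old + ["new"] * n_new,
        response=list(old_resp) + list(new_resp),
    ))


def test_hit_rate_arithmetic():
    rec = _rec("s", [1] * 30 + [0] * 10, [0] * 20)
    out = score_recognition(rec)
    assert out.loc[0, "hit_rate"] == pytest.approx(0.75)
    assert out.loc[0, "hits"] == 30 and out.loc[0, "misses"] == 10


def test_dprime_zero_when_rates_equal():
    assert dprime_from_rates(0.6, 0.6) == pytest.approx(0.0)


def test_dprime_inverse_normal_oracle():
    assert dprime_from_rates(0.84, 0.16) == pytest.approx(1.99, abs=0.01)


def test_dprime_counts_finite_at_extremes():
    assert np.isfinite(dprime_from_counts(40, 0, 0, 40))


def test_scoring_requires_both_statuses():
    rec = _rec("s", [1, 0], [])
    with pytest.raises(ValueError, match="old and new"):
        score_recognition(rec)


def test_perfect_discriminator_included():
    rec = _rec("s", [1] * 40, [0] * 40)
    flags = permutation_exclusion(rec, n_perm=500, seed=0)
    assert flags.loc[0, "included"]


def test_constant_responder_excluded():
    rec = _rec("s", [1] * 40, [1] * 40)
    flags = permutation_exclusion(rec, n_perm=500, seed=0)
    assert not flags.loc[0, "included"]
    assert flags.loc[0, "dprime"] == pytest.approx(0.0)


def test_permutation_requires_positive_n_perm():
    with pytest.raises(ValueError):
        permutation_exclusion(_rec("s", [1], [0]), n_perm=0)


def test_quartile_bins_balanced():
    bins = _quartile_bins(np.random.default_rng(0).uniform(size=21))
    sizes = np.bincount(bins)[1:]
    assert sizes.max() - sizes.min() <= 1
    assert set(bins) == {1, 2, 3, 4}


@pytest.mark.parametrize("p,k,expected", [(0.01, 4, 0.04), (0.5, 4, 1.0)])
def test_bonferroni_correction(p, k, expected):
    assert bonferroni(p, k) == pytest.approx(expected)


def test_analysis_table_row_counts(small_study, exp1_study):
    """EXP2 contributes all 100 uniques; EXP1 only the immediate half (72)."""
    t2 = build_analysis_table(small_study.trials, small_study.recognition)
    assert t2.groupby("subject").size().eq(100).all()
    t1 = build_analysis_table(exp1_study.trials, exp1_study.recognition)
    assert t1.groupby("subject").size().eq(72).all()
    for t in (t1, t2):
        assert set(t["po"].unique()) <= {0.5, -0.5}
        assert not t["object_id"].str.startswith("F").any()


def test_analysis_table_join_is_complete(small_study):
    table = build_analysis_table(small_study.trials, small_study.recognition)
    enc = small_study.trials.query("phase == 'ENCODING' and is_filler == 0")
    expected = set(map(tuple, enc[["subject", "object_id"]].to_numpy()))
    got = set(map(tuple, table[["subject", "object_id"]].to_numpy()))
    assert got == expected  # every non-filler item exactly once


def test_analysis_table_reports_unmatched_items(small_study):
    broken = small_study.trials[small_study.trials["object_id"] != "U0_0"]
    with pytest.raises(ValueError, match="without encoding trials"):
        build_analysis_table(broken, small_study.recognition)


def test_derived_pe_uses_fitted_learning_rate(small_study):
    params = small_study.true_params[["subject", "alpha", "beta"]]
    traj = derive_trial_pe(small_study.trials, params)
    assert len(traj) == len(small_study.trials)
    assert traj["pe_unsigned"].between(0, 1).all()
    assert traj["pe_signed"].between(-1, 1).all()


def test_between_subject_covariate_rejected_as_random_slope(small_study):
    table = build_analysis_table(
        small_study.trials, small_study.recognition,
        small_study.true_params[["subject", "alpha", "beta"]],
    )
    with pytest.raises(ValueError, match="between-subject"):
        _validate_random_terms(table, "hit ~ pe + (1 + alpha | subject)")


def test_mixed_logistic_needs_multiple_subjects(small_study):
    table = build_analysis_table(small_study.trials, small_study.recognition)
    with pytest.raises(ValueError, match="at least 2 subjects"):
        fit_mixed_logistic(table[table["subject"] == 0])


def test_mixed_logistic_odds_ratios_consistent(small_study):
    table = build_analysis_table(small_study.trials, small_study.recognition)
    res = fit_mixed_logistic(table)
    assert np.allclose(res.fixed["odds_ratio"],
                       np.exp(res.fixed["estimate"]), atol=1e-3)
    assert set(res.random["term"]) == {"(Intercept)", "pe", "po", "pe:po"}
    # interaction is generative (1.5) and should dominate the main effects
    assert res.coef("pe:po")["estimate"] > 0


def test_simple_slopes_opposite_signs_under_interaction(small_study):
    table = build_analysis_table(small_study.trials, small_study.recognition)
    slopes = simple_slopes(table)
    assert slopes["correct"].coef("pe")["estimate"] > 0
    assert slopes["incorrect"].coef("pe")["estimate"] < 0


def test_signed_pe_slope_positive_under_interaction(small_study):
    """With a positive PE x PO interaction, signed PE predicts memory
    positively (better-than-expected outcomes help, worse ones hurt)."""
    table = build_analysis_table(small_study.trials, small_study.recognition)
    from pemem.memory import signed_pe_analysis
    res = signed_pe_analysis(table)
    row = res.coef("spe")
    assert row["estimate"] > 0
    assert row["odds_ratio"] == pytest.approx(np.exp(row["estimate"]), abs=1e-6)
    with pytest.raises(ValueError, match="pe_signed"):
        signed_pe_analysis(table.drop(columns=["pe_signed"]))


def test_binned_pe_analysis_structure(small_study):
    table = build_analysis_table(small_study.trials, small_study.recognition)
    out = binned_pe_analysis(table)
    assert out.n_dropped_subjects == 0
    assert set(out.bin_hit_rates["pe_bin"]) == {1, 2, 3, 4}
    assert len(out.contrasts) == 3
    assert (out.contrasts["p_corrected"] <= 1.0).all()
    assert (out.contrasts["p_corrected"] >=
            out.contrasts["p"] - 1e-12).all()
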