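"""Equivalence testing, ICC, group comparisons, significance colors."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tibmorph.stats import (EquivalenceConfig, anova_tukey, bonferroni_adjust,
                            depth_profile_comparison, games_howell, icc,
                            model_vs_raters_equivalence, significance_color,
                            tost_paired)


# --------------------------------------------------------------------------
# TOST
# --------------------------------------------------------------------------

def test_tiny_differences_are_equivalent():
    d = np.array([0.001, -0.002, 0.000, 0.001, -0.001])
    res = tost_paired(d, np.zeros_like(d), bound_mm=0.05)
    # closed-form check: p = max of the two one-sided t CDF tails
    n, mean, sd = len(d), d.mean(), d.std(ddof=1)
    se = sd / np.sqrt(n)
    expected = max(sps.t.sf((mean + 0.05) / se, n - 1),
                   sps.t.cdf((mean - 0.05) / se, n - 1))
    assert res["p_tost"] == pytest.approx(expected, rel=1e-12)
    assert res["equivalent"] and res["p_tost"] < 0.001


def test_mean_exactly_at_bound_gives_half():
    x = np.array([0.05, 0.04, 0.06, 0.05, 0.05]) + 0.0
    y = np.zeros(5)
    res = tost_paired(x, y, bound_mm=x.mean() - 0.0)
    assert res["p_upper"] == pytest.approx(0.5)
    assert not res["equivalent"]


def test_large_difference_never_equivalent(rng):
    x = rng.normal(1.0, 0.01, 10)
    res = tost_paired(x, np.zeros(10), bound_mm=0.05)
    assert res["p_tost"] > 0.999


def test_tost_symmetry_and_bound_monotonicity(rng):
    x = rng.normal(0.01, 0.02, 8)
    y = rng.normal(0.0, 0.02, 8)
    a = tost_paired(x, y, 0.05)
    b = tost_paired(y, x, 0.05)
    assert a["p_tost"] == pytest.approx(b["p_tost"], rel=1e-12)
    wide = tost_paired(x, y, 0.10)
    assert wide["p_tost"] <= a["p_tost"] + 1e-15


def test_tost_matches_pingouin(rng):
    import pingouin as pg

    x = rng.normal(0.51, 0.02, 12)
    y = rng.normal(0.50, 0.02, 12)
    ours = tost_paired(x, y, bound_mm=0.05)
    theirs = float(pg.tost(x, y, bound=0.05, paired=True)["pval"].iloc[0])
    assert ours["p_tost"] == pytest.approx(theirs, rel=1e-6)


def test_degenerate_variance_inside_bounds():
    x = np.full(5, 0.30)
    y = np.full(5, 0.31)
    res = tost_paired(x, y, bound_mm=0.05)
    assert res["equivalent"] and res["p_tost"] == 0.0
    assert "degenerate" in res["note"]


def test_small_n_rejected():
    with pytest.raises(ValueError, match="n >= 3"):
        tost_paired([0.1, 0.2], [0.1, 0.2])


def test_bonferroni_adjustment():
    assert bonferroni_adjust([0.01] * 5)[0] == pytest.approx(0.05)
    assert bonferroni_adjust([0.4, 0.5, 0.6])[0] == pytest.approx(1.0)
    assert bonferroni_adjust([0.123])[0] == pytest.approx(0.123)


# --------------------------------------------------------------------------
# model-vs-raters verdict
# --------------------------------------------------------------------------

def _landmark_table(model_offsets, n_bones=6, seed=0):
    rng = np.random.default_rng(seed)
    truth = rng.uniform(0.8, 1.0, n_bones)
    rows = []
    for b in range(n_bones):
        for src in ("r1", "r2", "r3"):
            rows.append({"bone_id": b, "source": src, "landmark": "Z_ps",
                         "value_mm": truth[b] + rng.normal(0, 0.003)})
        rows.append({"bone_id": b, "source": "model", "landmark": "Z_ps",
                     "value_mm": truth[b] + model_offsets.get(b, 0.0)})
    return pd.DataFrame(rows)


def test_model_identical_to_raters_agrees_with_all():
    table = _landmark_table({})
    res = model_vs_raters_equivalence(table)
    assert res["model_pass"].all()
    assert res["model_agreements"].iloc[0] == 3


def test_equivalence_needs_only_two_of_three_raters(rng):
    # model systematically 0.2 mm off from rater 1 only
    truth = rng.uniform(0.8, 1.0, 6)
    rows = []
    for b in range(6):
        rows += [{"bone_id": b, "source": "r1", "landmark": "Z_ps",
                  "value_mm": truth[b] - 0.2},
                 {"bone_id": b, "source": "r2", "landmark": "Z_ps",
                  "value_mm": truth[b] + rng.normal(0, 0.002)},
                 {"bone_id": b, "source": "r3", "landmark": "Z_ps",
                  "value_mm": truth[b] + rng.normal(0, 0.002)},
                 {"bone_id": b, "source": "model", "landmark": "Z_ps",
                  "value_mm": truth[b]}]
    res = model_vs_raters_equivalence(pd.DataFrame(rows))
    assert res["model_agreements"].iloc[0] == 2
    assert res["model_pass"].all()


def test_unbiased_model_passes_almost_always():
    # raters and model with sd 0.01 mm around truth, n=5 bones: the verdict
    # should pass in at least 95% of repetitions
    rng = np.random.default_rng(42)
    passes = 0
    reps = 200
    for _ in range(reps):
        truth = rng.uniform(0.8, 1.0, 5)
        rows = []
        for b in range(5):
            for src in ("r1", "r2", "r3", "model"):
                rows.append({"bone_id": b, "source": src, "landmark": "Z",
                             "value_mm": truth[b] + rng.normal(0, 0.01)})
        res = model_vs_raters_equivalence(pd.DataFrame(rows))
        passes += bool(res["model_pass"].all())
    assert passes / reps >= 0.95


def test_fewer_than_two_raters_rejected():
    table = pd.DataFrame([
        {"bone_id": 0, "source": "model", "landmark": "Z", "value_mm": 1.0},
        {"bone_id": 0, "source": "r1", "landmark": "Z", "value_mm": 1.0},
    ])
    with pytest.raises(ValueError, match="two raters"):
        model_vs_raters_equivalence(table)


# --------------------------------------------------------------------------
# ICC
# --------------------------------------------------------------------------

def test_identical_raters_give_icc_one(rng):
    col = rng.normal(0, 1, 10)
    m = np.stack([col, col, col], axis=1)
    assert icc(m) == pytest.approx(1.0, abs=1e-9)


def test_icc_matches_hand_mean_squares():
    # 6 subjects x 3 raters; ICC(2,1) from the variance decomposition
    m = np.array([[9, 2, 5], [6, 1, 3], [8, 4, 6],
                  [7, 1, 2], [10, 5, 6], [6, 2, 4]], dtype=float)
    n, k = m.shape
    grand = m.mean()
    msr = k * ((m.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((m.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((m - m.mean(axis=1, keepdims=True)
            - m.mean(axis=0, keepdims=True) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    assert icc(m) == pytest.approx(expected, abs=1e-9)


def test_independent_noise_gives_icc_near_zero():
    rng = np.random.default_rng(7)
    m = rng.normal(0, 1, (200, 3))
    assert abs(icc(m)) <= 0.1


def test_constant_matrix_rejected():
    with pytest.raises(ValueError, match="variance"):
        icc(np.full((5, 3), 2.0))


# --------------------------------------------------------------------------
# ANOVA / Tukey / Games-Howell
# --------------------------------------------------------------------------

def test_identical_constant_groups_give_f_zero_no_posthoc():
    res = anova_tukey({"a": [5, 5, 5], "b": [5, 5, 5], "c": [5, 5, 5]})
    assert res["F"] == 0.0
    assert res["pairwise"] is None


def test_f_statistic_matches_hand_sum_of_squares():
    groups = {"a": [4.0, 5.0, 6.0], "b": [7.0, 8.0, 9.0], "c": [1.0, 2.0, 3.0]}
    res = anova_tukey(groups)
    vals = np.concatenate(list(groups.values()))
    grand = vals.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups.values())
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups.values())
    F = (ssb / 2) / (ssw / 6)
    assert res["F"] == pytest.approx(F, rel=1e-12)
    assert res["pairwise"] is not None  # significant → post hoc emitted


def test_posthoc_gated_on_omnibus(rng):
    groups = {g: rng.normal(0, 1, 6) for g in "abc"}
    res = anova_tukey(groups)
    if res["p_omnibus"] > 0.05:
        assert res["pairwise"] is None


def test_games_howell_equals_tukey_under_equal_variance():
    # two groups with identical n and sample variance: Welch df = pooled df
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    b = a + 5.0
    gh = games_howell({"a": a, "b": b})
    tk = anova_tukey({"a": a, "b": b})
    assert tk["pairwise"] is not None
    assert gh[("a", "b")] == pytest.approx(tk["pairwise"][("a", "b")],
                                           abs=1e-6)


def test_identical_groups_give_p_near_one(rng):
    base = rng.normal(0, 1, 8)
    gh = games_howell({"a": base, "b": base + rng.normal(0, 1e-6, 8)})
    assert gh[("a", "b")] > 0.99


def test_zero_variance_pair_rejected():
    with pytest.raises(ValueError, match="zero variance"):
        games_howell({"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]})


# --------------------------------------------------------------------------
# significance colors and depth comparison
# --------------------------------------------------------------------------

@pytest.mark.parametrize("p,color", [
    (0.2, "blue"), (0.0501, "blue"),
    (0.05, "light_blue"), (0.0100001, "light_blue"),
    (0.010, "orange"), (0.00999, "orange"), (0.0011, "orange"),
    (0.001, "red"), (0.0001, "red"),
])
def test_color_band_boundaries(p, color):
    assert significance_color(p) == color


def test_color_mapping_total_on_unit_interval(rng):
    for p in rng.random(100):
        assert significance_color(p) in {"blue", "light_blue", "orange", "red"}


def _profiles(rng, shift_from_bin=None, n_bones=5, n_bins=50, delta=30.0):
    out = []
    for _ in range(n_bones):
        base = 20 + rng.normal(0, 1.0, n_bins)
        if shift_from_bin is not None:
            base[shift_from_bin:] += delta
        out.append(pd.DataFrame({
            "z_start_mm": np.arange(n_bins) * 0.02,
            "bar_tar_pct": base,
            "n_med_voxels": 1000,
        }))
    return out


def test_identical_groups_make_all_bins_blue(rng):
    shared = _profiles(rng)
    groups = {"g1": shared, "g2": [df.copy() for df in shared]}
    res = depth_profile_comparison(groups)
    assert (res["color"] == "blue").all()


def test_step_effect_detected_at_change_point(rng):
    groups = {"ctrl": _profiles(rng), "dose": _profiles(rng, shift_from_bin=25)}
    res = depth_profile_comparison(groups)
    res = res.set_index("bin_index")
    early = res.loc[:22, "color"]
    late = res.loc[27:, "color"]
    assert (late == "red").all()
    assert (early == "blue").mean() > 0.8


def test_grid_mismatch_rejected(rng):
    a = _profiles(rng)
    b = _profiles(rng, n_bins=40)
    with pytest.raises(ValueError, match="grid"):
        depth_profile_comparison({"a": a, "b": b})
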