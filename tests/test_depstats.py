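import itertools

import numpy as np
import pandas as pd
import pytest

from dermafiber.depstats import (complete_cases, dc_test,
                                 dependency_matrix, distance_correlation,
                                 pairwise_dependencies, region_comparison,
                                 validate_feature_table)
from dermafiber.synthetic_data import gen_cohort


def dc_bruteforce(x, y):
    """Literal four-loop double-centering oracle."""
    n = len(x)
    a = np.array([[abs(x[i] - x[j]) for j in range(n)] for i in range(n)])
    b = np.array([[abs(y[i] - y[j]) for j in range(n)] for i in range(n)])
    A = np.empty((n, n))
    B = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            A[i, j] = a[i, j] - a[i].mean() - a[:, j].mean() + a.mean()
            B[i, j] = b[i, j] - b[i].mean() - b[:, j].mean() + b.mean()
    dcov2 = (A * B).mean()
    return np.sqrt(dcov2 / np.sqrt((A * A).mean() * (B * B).mean()))


def test_matches_bruteforce_oracle(rng):
    for n in (4, 7, 12):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        assert distance_correlation(x, y) == pytest.approx(
            dc_bruteforce(x, y), abs=1e-10)


def test_self_and_affine_dependence(rng):
    x = rng.normal(size=30)
    assert distance_correlation(x, x) == pytest.approx(1.0, abs=1e-12)
    assert distance_correlation(x, 2.5 - 3.1 * x) == pytest.approx(1.0, abs=1e-10)


def test_invariance_translation_scaling(rng):
    x = rng.normal(size=25)
    y = rng.gamma(2.0, size=25)
    base = distance_correlation(x, y)
    assert distance_correlation(x + 10, y * 4) == pytest.approx(base, abs=1e-12)


def test_constant_vector_flagged_zero(rng):
    with pytest.warns(UserWarning, match="constant"):
        assert distance_correlation(np.ones(10), rng.normal(size=10)) == 0.0


def test_input_validation(rng):
    with pytest.raises(ValueError):
        distance_correlation([1, 2, 3], [1, 2, 3])  # n < 4
    with pytest.raises(ValueError):
        distance_correlation([1, 2, 3, 4], [1, 2, 3])
    with pytest.raises(ValueError):
        distance_correlation([1, 2, 3, np.nan], [1, 2, 3, 4])


def test_dc_test_maximal_dependence(rng):
    x = rng.normal(size=40)
    res = dc_test(x, x, n_resamples=400, seed=5)
    assert res.dc == pytest.approx(1.0, abs=1e-12)
    assert res.p_value == pytest.approx(1 / 401, abs=1e-12)
    assert res.significant


def test_dc_test_reproducible(rng):
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    r1 = dc_test(x, y, n_resamples=100, seed=11)
    r2 = dc_test(x, y, n_resamples=100, seed=11)
    assert r1.p_value == r2.p_value


def test_dc_test_detects_quadratic_dependence(rng):
    hits = 0
    for _ in range(20):
        x = rng.normal(size=60)
        y = x**2 + 0.2 * rng.normal(size=60)
        res = dc_test(x, y, n_resamples=200, seed=int(rng.integers(2**31)))
        hits += res.p_value < 0.05
    assert hits >= 18  # >= 90% power on a link Pearson r would miss


def test_type_one_error_calibrated(rng):
    rejections = 0
    reps = 500
    for _ in range(reps):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        res = dc_test(x, y, n_resamples=200, seed=int(rng.integers(2**31)))
        rejections += res.significant
    assert 0.03 <= rejections / reps <= 0.07


def test_null_p_values_roughly_uniform(rng):
    ps = []
    for _ in range(200):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        ps.append(dc_test(x, y, n_resamples=99,
                          seed=int(rng.integers(2**31))).p_value)
    # p lives on the grid {1/100, ..., 1}; compare empirical quartile masses
    ps = np.asarray(ps)
    for q in (0.25, 0.5, 0.75):
        assert abs((ps <= q).mean() - q) < 0.11


def test_complete_cases_missingness_pattern():
    table, truth = gen_cohort(24, seed=8)
    features = [c for c in table.columns if c != "sample_id"]
    kept = complete_cases(table, features)
    assert len(table) == 24
    assert len(kept) == 19  # 3 rows missing E1, 2 missing the elastin block


def test_complete_cases_identity_and_errors():
    df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
    pd.testing.assert_frame_equal(complete_cases(df, ["a", "b"]), df)
    df.loc[:, "a"] = np.nan
    with pytest.raises(ValueError, match="empty"):
        complete_cases(df, ["a"])
    with pytest.raises(KeyError):
        complete_cases(df, ["zzz"])


def test_pairwise_duplicated_column_and_pair_count(rng):
    cols = {f"f{i}": rng.normal(size=20) for i in range(13)}
    cols["f1"] = cols["f0"].copy()  # exact duplicate
    table = pd.DataFrame(cols)
    results = pairwise_dependencies(table, n_resamples=60, seed=4)
    assert len(results) == 78  # C(13, 2)
    dup = next(r for r in results if {r.feature_x, r.feature_y} == {"f0", "f1"})
    assert dup.dc == pytest.approx(1.0, abs=1e-12)
    assert dup.significant
    mat = dependency_matrix(results)
    assert mat.shape == (13, 13)
    assert mat.loc["f0", "f1"] == pytest.approx(1.0)


def test_pairwise_finds_planted_links(rng):
    table, truth = gen_cohort(
        24,
        [("E2", "age", lambda a: 45 - 0.4 * a, 0.8),
         ("OI3D_CO", "D_CO", lambda d: 0.05 + 0.3 * d, 0.01)],
        seed=15, apply_missingness=False)
    feats = ["E2", "age", "OI3D_CO", "D_CO", "T_EL", "eps_mid"]
    results = pairwise_dependencies(table, feats, n_resamples=300, seed=2)
    by_pair = {frozenset((r.feature_x, r.feature_y)): r for r in results}
    assert by_pair[frozenset(("E2", "age"))].significant
    assert by_pair[frozenset(("OI3D_CO", "D_CO"))].significant
    null_pairs = [r for r in results
                  if frozenset((r.feature_x, r.feature_y)) not in
                  (frozenset(("E2", "age")), frozenset(("OI3D_CO", "D_CO")))]
    assert sum(r.significant for r in null_pairs) <= len(null_pairs) // 3


def test_validate_feature_table():
    bad = pd.DataFrame({"main_theta_CO": [120.0], "age": [80.0]})
    with pytest.raises(ValueError, match="folded"):
        validate_feature_table(bad)
    ok = pd.DataFrame({"main_theta_CO": [45.0], "age": [80.0]})
    validate_feature_table(ok)


def test_region_comparison_identical_groups():
    res = region_comparison({"toe": [0.2, 0.2, 0.2], "heel": [0.2, 0.2, 0.2],
                             "linear": [0.2, 0.2, 0.2]})
    assert res["p"] > 0.99 or np.isnan(res["p"])


def test_region_comparison_separated_group():
    res = region_comparison({
        "toe": [0.10, 0.11, 0.10, 0.105], "heel": [0.10, 0.105, 0.11, 0.1],
        "linear": [0.50, 0.51, 0.49, 0.50]})
    assert res["p"] < 1e-3
    tuk = {frozenset((t["group1"], t["group2"])): t for t in res["tukey"]}
    assert tuk[frozenset(("toe", "linear"))]["stars"] == "***"
    assert tuk[frozenset(("toe", "heel"))]["stars"] == "ns"


def test_region_comparison_matches_textbook_anova():
    groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0], "c": [6.0, 7.0, 8.0]}
    res = region_comparison(groups)
    # closed-form one-way ANOVA: F = (SSB/(k-1)) / (SSW/(N-k))
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    ssb = sum(3 * (np.mean(v) - grand) ** 2 for v in groups.values())
    ssw = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values())
    f_expected = (ssb / 2) / (ssw / 6)
    assert res["F"] == pytest.approx(f_expected, rel=1e-10)


def test_region_comparison_validates_groups():
    with pytest.raises(ValueError):
        region_comparison({"toe": [0.1, 0.2]})
    with pytest.raises(ValueError):
        region_comparison({"toe": [0.1, 0.2], "heel": [0.3]})
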