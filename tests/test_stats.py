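"""Rank tests, partial correlations, normalization and grouped comparisons."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import ctoevol as ce
from ctoevol import stats as cstats


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def exact_ranksum_p(x, y):
    """Independent enumeration oracle: two-sided p as the probability of a
    rank sum at least as extreme (rank-sum distribution is symmetric
    without ties)."""
    pooled = sorted(x) + sorted(y)
    n = len(x)
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    w_obs = sum(ranks[v] for v in x)
    e_w = n * (len(pooled) + 1) / 2
    total = extreme = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), n):
        total += 1
        if abs(sum(combo) - e_w) >= abs(w_obs - e_w) - 1e-12:
            extreme += 1
    return extreme / total


def test_wilcoxon_exact_small_example():
    stat, p = ce.wilcoxon_rank_sum([1, 2], [3, 4])
    assert p == pytest.approx(1 / 3)
    assert p == pytest.approx(exact_ranksum_p([1, 2], [3, 4]))


def test_wilcoxon_same_multiset_gives_p_one():
    _, p = ce.wilcoxon_rank_sum([1.0, 1.0, 1.0], [1.0, 1.0])
    assert p == 1.0


def test_wilcoxon_matches_enumeration_for_moderate_sizes():
    rng = np.random.default_rng(0)
    for n, m in [(3, 4), (4, 4), (2, 6), (5, 5)]:
        x = rng.permutation(n + m)[:n].tolist()
        y = [v for v in range(n + m) if v not in x]
        _, p = ce.wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(exact_ranksum_p(x, y), abs=1e-12)


def test_wilcoxon_large_sample_type1_error_is_nominal():
    rng = np.random.default_rng(12)
    n_reps, alpha = 400, 0.05
    rejections = 0
    for _ in range(n_reps):
        x = rng.standard_normal(60)
        y = rng.standard_normal(60)
        _, p = ce.wilcoxon_rank_sum(x, y)
        rejections += p < alpha
    rate = rejections / n_reps
    half = 2.576 * math.sqrt(alpha * (1 - alpha) / n_reps)
    assert abs(rate - alpha) < half


# ---------------------------------------------------------------------------
# correlations


def test_spearman_examples():
    rho, _ = ce.spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])
    assert rho == pytest.approx(1.0)
    rho, _ = ce.spearman_rho([1, 2, 3, 4], [40, 30, 20, 10])
    assert rho == pytest.approx(-1.0)
    # hand computation: d^2 = (0,1,1,1,1) -> sum 4; rho = 1 - 6*4/(5*24) = 0.8
    rho, _ = ce.spearman_rho([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
    assert rho == pytest.approx(0.8)
    with pytest.raises(ValueError, match="zero variance"):
        ce.spearman_rho([1, 1, 1], [1, 2, 3])


def test_partial_spearman_reduces_to_marginal_when_z_is_constant_rank():
    rng = np.random.default_rng(1)
    x = rng.normal(size=60)
    y = x + rng.normal(size=60)
    # z built orthogonal to the ranks of both x and y in correlation terms
    z = rng.permutation(60).astype(float)
    rho_m, _ = ce.spearman_rho(x, y)
    rho_p, _ = ce.partial_spearman(x, y, z)
    assert rho_p == pytest.approx(rho_m, abs=0.12)


def test_partial_spearman_degenerate_covariate():
    x = np.arange(10.0)
    y = np.arange(10.0)[::-1]
    with pytest.raises(ValueError, match="partial undefined"):
        ce.partial_spearman(x, y, y.copy())


def test_partial_spearman_matches_independent_reference():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(2)
    x, y, z = rng.normal(size=(3, 50))
    y = y + 0.5 * x + 0.3 * z
    rho, p = ce.partial_spearman(x, y, z)
    ref = pg.partial_corr(
        pd.DataFrame({"x": x, "y": y, "z": z}), "x", "y", "z", method="spearman"
    )
    assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
    assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)


def test_partial_spearman_removes_location_driven_association():
    """When rate depends only on a covariate and gene type is clustered on
    that covariate, the marginal correlation is positive but the partial
    correlation given the covariate vanishes."""
    rng = np.random.default_rng(3)
    n, reps, inside = 200, 30, 0
    for _ in range(reps):
        distance = rng.uniform(0, 1, size=n)
        gene_type = (distance < 0.25).astype(float)  # types cluster at low distance
        rate = 2.0 - distance + 0.3 * rng.standard_normal(n)
        rho_m, _ = ce.spearman_rho(gene_type, rate)
        rho_p, _ = ce.partial_spearman(gene_type, rate, distance)
        se = 1 / math.sqrt(n - 3)
        if abs(rho_p) < 3 * se:
            inside += 1
        assert rho_m > 0
    assert inside >= reps - 2  # ~3 SE coverage


# ---------------------------------------------------------------------------
# expression handling


def test_quantile_normalize_hand_example():
    t = pd.DataFrame({"c1": [1.0, 2.0, 3.0], "c2": [4.0, 5.0, 6.0]})
    out = ce.quantile_normalize(t)
    expected = [2.5, 3.5, 4.5]
    assert out["c1"].tolist() == expected
    assert out["c2"].tolist() == expected


def test_quantile_normalize_properties():
    rng = np.random.default_rng(4)
    t = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
    out = ce.quantile_normalize(t)
    ref = np.sort(out["a"].to_numpy())
    for col in "bcd":
        assert np.allclose(np.sort(out[col].to_numpy()), ref)
    # identical columns are a fixed point
    t2 = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
    assert np.allclose(ce.quantile_normalize(t2).to_numpy(), t2.to_numpy())
    # order within each column is preserved
    assert (out["a"].rank() == t["a"].rank()).all()
    with pytest.raises(ValueError, match="missing"):
        ce.quantile_normalize(pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 2.0]}))


def test_quantile_normalize_ties_share_reference_mean():
    t = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
    out = ce.quantile_normalize(t)
    assert out["a"].iloc[0] == out["a"].iloc[1]


def test_quantile_normalize_matches_limma_reference_values():
    """Frozen oracle: limma::normalizeQuantiles on the same 4x3 matrix
    (ties receive the mean of their reference slots)."""
    t = pd.DataFrame(
        {"c1": [2.0, 4.0, 6.0, 8.0], "c2": [1.0, 1.0, 5.0, 7.0], "c3": [3.0, 2.0, 2.0, 9.0]}
    )
    out = ce.quantile_normalize(t)
    expected = np.array(
        [
            [5 / 3, 2.0, 14 / 3],
            [7 / 3, 2.0, 2.0],
            [14 / 3, 14 / 3, 2.0],
            [8.0, 8.0, 8.0],
        ]
    )
    assert np.allclose(out.to_numpy(), expected, atol=1e-9)


def test_standardize_expression():
    out = ce.standardize_expression([1.0, 2.0, 3.0])
    assert np.allclose(out, [-1.0, 0.0, 1.0])
    assert np.median(out) == pytest.approx(0.0, abs=1e-12)
    assert out.var(ddof=1) == pytest.approx(1.0, abs=1e-12)
    again = ce.standardize_expression(out)
    assert np.allclose(again, out, atol=1e-12)
    with pytest.raises(ValueError, match="zero variance"):
        ce.standardize_expression([2.0, 2.0, 2.0])


def test_stratify_top_quantile():
    s = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
    highly, non = ce.stratify_top_quantile(s)
    assert (len(highly), len(non)) == (2, 8)
    assert highly == {"g8", "g9"}
    # boundary ties all go to highly
    tied = pd.Series([1.0] * 97 + [5.0, 5.0, 5.0], index=[f"g{i}" for i in range(100)])
    hi, _ = ce.stratify_top_quantile(tied)
    assert {"g97", "g98", "g99"} <= hi
    allsame = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
    hi, lo = ce.stratify_top_quantile(allsame)
    assert hi == {"a", "b", "c"} and lo == set()


# ---------------------------------------------------------------------------
# grouped comparisons


def _rates_frame(rng, n_cog, n_sog, ds_factor=1.0):
    ds_sog = rng.lognormal(0.0, 0.3, size=n_sog)
    ds_cog = rng.lognormal(0.0, 0.3, size=n_cog) * ds_factor
    df = pd.DataFrame(
        {
            "dN": np.concatenate([ds_cog, ds_sog]) * 0.05,
            "dS": np.concatenate([ds_cog, ds_sog]),
            "omega": rng.lognormal(-3.0, 0.2, size=n_cog + n_sog),
            "orientation_call": ["COG"] * n_cog + ["SOG"] * n_sog,
        },
        index=[f"og{i}" for i in range(n_cog + n_sog)],
    )
    return df


def test_grouped_comparison_null_is_mostly_nonsignificant():
    rng = np.random.default_rng(5)
    sig = 0
    reps = 40
    for _ in range(reps):
        df = _rates_frame(rng, 50, 50)
        (report,) = ce.grouped_rate_comparison(df)
        sig += report.p_ds is not None and report.p_ds < 0.05
    assert sig <= 7  # ~5% of 40 with generous slack


def test_grouped_comparison_detects_doubled_ds_and_assigns_stars():
    rng = np.random.default_rng(6)
    df = _rates_frame(rng, 100, 100, ds_factor=2.0)
    (report,) = ce.grouped_rate_comparison(df)
    assert report.p_ds < 0.05
    assert cstats.stars(report.p_ds) in {"*", "**", "***"}
    assert report.median_ds_cog > report.median_ds_sog


def test_grouped_comparison_handles_empty_stratum():
    rng = np.random.default_rng(7)
    df = _rates_frame(rng, 0, 20)
    (report,) = ce.grouped_rate_comparison(df)
    assert report.n_cog == 0
    assert report.p_ds is None
    assert cstats.stars(report.p_ds) == "NA"


def test_star_thresholds():
    assert cstats.stars(0.2) == "-"
    assert cstats.stars(0.02) == "*"
    assert cstats.stars(0.0005) == "**"  # < 0.01 but not < 0.0001
    assert cstats.stars(0.00005) == "***"  # below the 1e-4 threshold


def test_bh_flag_is_off_by_default_and_monotone_when_on():
    rng = np.random.default_rng(8)
    df = _rates_frame(rng, 30, 30)
    strata = pd.Series(["s1"] * 30 + ["s2"] * 30, index=df.index)
    raw = ce.grouped_rate_comparison(df, strata)
    adj = ce.grouped_rate_comparison(df, strata, bh_correct=True)
    for r, a in zip(raw, adj):
        for key in ("p_dn", "p_ds", "p_omega"):
            if getattr(r, key) is not None:
                assert getattr(a, key) >= getattr(r, key) - 1e-12
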