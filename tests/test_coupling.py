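"""Amplitude-asymmetry coupling, accuracy correlations, and AIC model
selection."""

import numpy as np
import pandas as pd
import pytest

from hemiasym.asymmetry import AsymmetryResult, compute_asymmetry
from hemiasym.coupling import (
    InsufficientDataError,
    accuracy_correlations,
    bin_subjects,
    binned_correlation,
    compare_polynomial_fits,
    selected_degree,
    vertexwise_amp_asym_map,
)
from hemiasym.networks import NetworkSummary, aggregate_by_network
from hemiasym.simulate import SimulationConfig, generate_cohort


def _result(delta, amplitude):
    n_sub, n_ep, _ = delta.shape
    return AsymmetryResult(
        delta=np.asarray(delta, float), amplitude=np.asarray(amplitude, float),
        mask=np.zeros(delta.shape, bool),
        subject_ids=[f"s{i}" for i in range(n_sub)],
        epoch_names=[f"e{j}" for j in range(n_ep)])


def _summary(amplitude, delta, networks=("LAN",), epochs=("story",)):
    amp = np.asarray(amplitude, float).reshape(-1, 1, 1)
    amp = np.broadcast_to(amp, (amp.shape[0], len(epochs), len(networks))).copy()
    dl = np.asarray(delta, float).reshape(-1, 1, 1)
    dl = np.broadcast_to(dl, amp.shape).copy()
    return NetworkSummary(
        delta_mean=dl, amplitude_mean=amp, left_mean=amp, right_mean=amp,
        subject_ids=[f"s{i}" for i in range(amp.shape[0])],
        epoch_names=list(epochs), network_names=list(networks))


# -- vertex-wise map --------------------------------------------------------

def test_identical_measures_give_unit_correlation(rng):
    amp = rng.uniform(1, 2, (10, 3, 4))
    res = _result(amp.copy(), amp)
    np.testing.assert_allclose(vertexwise_amp_asym_map(res), 1.0)


def test_epoch_average_of_mixed_correlations(rng):
    n = 50
    x = rng.standard_normal(n)
    delta = np.empty((n, 2, 1))
    amplitude = np.empty((n, 2, 1))
    amplitude[:, 0, 0] = x
    delta[:, 0, 0] = x                      # r = 1
    amplitude[:, 1, 0] = rng.standard_normal(n)
    delta[:, 1, 0] = 3.0                    # zero variance -> excluded
    res = _result(delta, amplitude)
    np.testing.assert_allclose(vertexwise_amp_asym_map(res), 1.0)

    delta[:, 1, 0] = x                      # r = 1 vs independent amp: ~0
    y = rng.standard_normal(n)
    y = y - np.polyval(np.polyfit(x, y, 1), x)  # orthogonalize exactly
    amplitude[:, 1, 0] = y
    res = _result(delta, amplitude)
    np.testing.assert_allclose(vertexwise_amp_asym_map(res)[0], 0.5,
                               atol=1e-10)


def test_independent_measures_near_zero(rng):
    res = _result(rng.standard_normal((100, 5, 8)),
                  rng.standard_normal((100, 5, 8)) + 5)
    m = vertexwise_amp_asym_map(res)
    # each vertex averages 5 independent r's with SE ~ 1/sqrt(5*100)
    assert np.abs(m.mean()) < 3 / np.sqrt(5 * 100 * 8)


def test_too_few_subjects_raises():
    with pytest.raises(InsufficientDataError):
        vertexwise_amp_asym_map(_result(np.zeros((2, 1, 1)),
                                        np.ones((2, 1, 1))))


# -- binning ----------------------------------------------------------------

def test_bin_exact_multiple(rng):
    summary = _summary(rng.uniform(0, 1, 30), rng.uniform(-1, 1, 30))
    groups = bin_subjects(summary, group_size=10)
    assert groups.n_dropped == 0
    stats_df = groups.group_stats
    assert sorted(stats_df["group"]) == [0, 1, 2]
    # group mean amplitudes non-decreasing (sort invariant)
    assert stats_df.sort_values("group")["amplitude"].is_monotonic_increasing


def test_bin_remainder_dropped(rng):
    summary = _summary(rng.uniform(0, 1, 25), rng.uniform(-1, 1, 25))
    groups = bin_subjects(summary, group_size=10)
    assert groups.n_dropped == 5
    assert groups.group_stats["group"].nunique() == 2
    assigned = groups.assignments
    assert (assigned["group"] == -1).sum() == 5


def test_bin_groups_rank_contiguous(rng):
    amp = rng.uniform(0, 1, 30)
    summary = _summary(amp, rng.uniform(-1, 1, 30))
    groups = bin_subjects(summary, group_size=10)
    a = groups.assignments
    order = np.argsort(amp)
    ranks = np.empty(30, int)
    ranks[order] = np.arange(30)
    expected = ranks // 10
    np.testing.assert_array_equal(a["group"].to_numpy(), expected)


def test_bin_parameter_errors(rng):
    summary = _summary(rng.uniform(0, 1, 30), rng.uniform(-1, 1, 30))
    with pytest.raises(ValueError):
        bin_subjects(summary, group_size=1)
    small = _summary(rng.uniform(0, 1, 5), rng.uniform(-1, 1, 5))
    with pytest.raises(InsufficientDataError):
        bin_subjects(small, group_size=10)


# -- binned correlation -----------------------------------------------------

def test_deterministic_coupling_gives_unit_r(rng):
    amp = rng.uniform(1, 2, 40)
    summary = _summary(amp, 0.1 + 0.3 * amp)   # delta linear in amplitude
    corr = binned_correlation(bin_subjects(summary, group_size=10))
    assert corr.r.iloc[0, 0] == pytest.approx(1.0)


def test_negating_delta_flips_r(rng):
    amp = rng.uniform(1, 2, 40)
    delta = 0.2 * amp + rng.normal(0, 0.05, 40)
    pos = binned_correlation(bin_subjects(_summary(amp, delta), 10))
    neg = binned_correlation(bin_subjects(_summary(amp, -delta), 10))
    assert neg.r.iloc[0, 0] == pytest.approx(-pos.r.iloc[0, 0])


def test_fewer_than_three_groups_raises(rng):
    summary = _summary(rng.uniform(0, 1, 25), rng.uniform(-1, 1, 25))
    with pytest.raises(InsufficientDataError):
        binned_correlation(bin_subjects(summary, group_size=10))


def test_coupling_monotone_in_planted_coefficient():
    """Group-binned amplitude-asymmetry correlation grows with the
    planted coupling coefficient at matched seeds."""
    base = SimulationConfig(n_subjects=120, n_vertices=48, seed=5)
    rs = []
    for c in (0.0, 0.5, 1.0):
        config = base.replace(coupling=base.coupling * 0 + c,
                              true_delta=base.true_delta * 0)
        dataset, _, truth = generate_cohort(config)
        summary = aggregate_by_network(compute_asymmetry(dataset),
                                       truth.partition())
        corr = binned_correlation(bin_subjects(summary, group_size=10))
        rs.append(np.nanmean(corr.r.to_numpy()))
    assert rs[0] < rs[1] < rs[2]
    assert abs(rs[0]) < 0.35 and rs[2] > 0.8


# -- accuracy correlations --------------------------------------------------

def test_exact_linear_accuracy_gives_unit_r(rng):
    amp = rng.uniform(1, 2, 40)
    summary = _summary(amp, rng.uniform(-1, 1, 40))
    table = pd.DataFrame({"acc_story": 50 + 10 * amp},
                         index=summary.subject_ids)
    corr = accuracy_correlations(summary, table, measure="amplitude")
    assert corr.r.loc["LAN", "story"] == pytest.approx(1.0)


def test_bonferroni_family_size(rng):
    networks = [f"N{k}" for k in range(9)]
    epochs = ["faces", "shapes", "reward", "punish", "story", "math",
              "rel", "match", "social", "random", "0bk", "2bk"]
    n = 30
    summary = _summary(rng.uniform(1, 2, n), rng.uniform(-1, 1, n),
                       networks=networks, epochs=epochs)
    # add variation per cell so correlations are defined
    summary.delta_mean += rng.normal(0, 0.1, summary.delta_mean.shape)
    summary.amplitude_mean += rng.normal(0, 0.1,
                                         summary.amplitude_mean.shape)
    table = pd.DataFrame(
        {f"acc_{e}": rng.uniform(60, 90, n) for e in epochs},
        index=summary.subject_ids)
    corr = accuracy_correlations(summary, table, measure="delta",
                                 alpha=0.05, control="bonferroni")
    assert corr.r.shape == (9, 12)
    # per-cell threshold alpha / 108: only p below it count as significant
    sig = corr.significant.to_numpy()
    p = corr.p.to_numpy()
    assert np.array_equal(sig, p < 0.05 / 108)


def test_missing_accuracy_dropped_pairwise(rng):
    amp = rng.uniform(1, 2, 20)
    summary = _summary(amp, rng.uniform(-1, 1, 20))
    acc = 50 + 10 * amp
    acc[:5] = np.nan
    table = pd.DataFrame({"acc_story": acc}, index=summary.subject_ids)
    corr = accuracy_correlations(summary, table, measure="amplitude")
    assert corr.n.loc["LAN", "story"] == 15
    assert corr.r.loc["LAN", "story"] == pytest.approx(1.0)


# -- polynomial AIC ---------------------------------------------------------

def test_aic_matches_closed_form():
    x = np.arange(10.0)
    y = np.array([1.1, 2.3, 2.9, 4.2, 4.8, 6.1, 7.2, 7.9, 9.1, 10.2])
    table = compare_polynomial_fits(x, y, max_degree=3)
    for _, row in table.iterrows():
        deg, k = int(row["degree"]), int(row["k"])
        coef = np.polyfit(x, y, deg)
        rss = float(np.sum((y - np.polyval(coef, x)) ** 2))
        aic = 10 * np.log(rss / 10) + 2 * k
        assert row["aic"] == pytest.approx(aic)
        assert k == deg + 2
    assert selected_degree(table) == 1
    lin = table.loc[table["degree"] == 1, "aic"].iloc[0]
    np.testing.assert_allclose(table["delta_aic"], table["aic"] - lin)


def test_linear_data_selects_degree_one(rng):
    hits = 0
    for seed in range(30):
        r = np.random.default_rng(seed)
        x = r.uniform(-2, 2, 100)
        y = 2 * x + r.normal(0, 0.1, 100)
        hits += selected_degree(compare_polynomial_fits(x, y)) == 1
    assert hits >= 28


def test_cubic_data_selects_degree_three(rng):
    hits = 0
    for seed in range(30):
        r = np.random.default_rng(seed)
        x = r.uniform(-2, 2, 100)
        y = x ** 3 + r.normal(0, 0.1, 100)
        hits += selected_degree(compare_polynomial_fits(x, y)) == 3
    assert hits >= 28


def test_polynomial_fit_errors():
    with pytest.raises(InsufficientDataError):
        compare_polynomial_fits(np.arange(4.0), np.arange(4.0))
    with pytest.raises(ValueError, match="constant"):
        compare_polynomial_fits(np.ones(10), np.arange(10.0))


def test_pearson_matches_covariance_oracle(rng):
    """All Pearson machinery agrees with the direct covariance formula."""
    from hemiasym.coupling import _pearson_columns

    x = rng.standard_normal((50, 7))
    y = rng.standard_normal((50, 7))
    r = _pearson_columns(x, y)
    for j in range(7):
        xc = x[:, j] - x[:, j].mean()
        yc = y[:, j] - y[:, j].mean()
        oracle = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert r[j] == pytest.approx(oracle, abs=1e-12)
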