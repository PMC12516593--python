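import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.distance import jensenshannon
from scipy.stats import entropy as scipy_entropy

from conftest import make_game
from fuseki.corpus import TimeBin
from fuseki.diversity import (VariantDistribution, bootstrap_series,
                              hill_diversity, hill_from_freqs, jsd, jsd_value,
                              label_is_complete, shannon_diversity,
                              tally_variants, variant_label)


def dist(*freqs, labels=None):
    labels = labels or [f"v{i}" for i in range(len(freqs))]
    return VariantDistribution(labels, np.array(freqs), n_games=100)


# ---------------------------------------------------------------------------
# labels and tallies


def test_variant_label_examples():
    g = make_game([(16, 16), (4, 16), (3, 3)])
    assert variant_label(g, 2) == "Q16,D16"
    assert variant_label(g, 1) == "Q16"
    short = make_game([(16, 16)])
    assert variant_label(short, 2) == "Q16,-"
    assert not label_is_complete(variant_label(short, 2))


def test_variant_label_rejects_empty_game():
    with pytest.raises(ValueError):
        variant_label(make_game([]), 2)


def test_tally_frequencies():
    games = [make_game([(16, 16), (4, 16)]),
             make_game([(16, 16), (4, 16)]),
             make_game([(16, 16), (4, 4)]),
             make_game([(16, 17), (4, 4)])]
    d = tally_variants(games, depth=2)
    assert d.n_games == 4
    assert d.as_dict() == {"Q16,D16": 0.5, "Q16,D4": 0.25, "Q17,D4": 0.25}


def test_tally_excludes_and_reports_incomplete():
    games = [make_game([(16, 16), (4, 16)]), make_game([(16, 16)])]
    d = tally_variants(games, depth=2)
    assert d.n_games == 1 and d.n_incomplete == 1


def test_tally_of_union_is_count_weighted_mixture():
    a = [make_game([(16, 16), (4, 16)])] * 3
    b = [make_game([(16, 16), (4, 4)])] * 1
    da, db, dab = (tally_variants(x) for x in (a, b, a + b))
    for label in dab.labels:
        expected = (3 * da.as_dict().get(label, 0)
                    + 1 * db.as_dict().get(label, 0)) / 4
        assert dab.as_dict()[label] == pytest.approx(expected)


def test_tally_with_no_complete_games_raises():
    with pytest.raises(ValueError):
        tally_variants([make_game([(16, 16)])], depth=2)


# ---------------------------------------------------------------------------
# Hill numbers


def test_hill_uniform_returns_variant_count():
    assert hill_diversity(dist(.25, .25, .25, .25), 1).value == pytest.approx(4.0)


def test_hill_point_mass_is_one():
    assert hill_diversity(dist(1.0), 1).value == pytest.approx(1.0)


def test_hill_closed_forms():
    d = dist(0.5, 0.25, 0.25)
    assert hill_diversity(d, 1).value == pytest.approx(2 ** 1.5)
    assert hill_diversity(d, 2).value == pytest.approx(8 / 3)
    assert hill_diversity(d, 0).value == 3


def test_hill_matches_scipy_entropy(rng):
    for _ in range(20):
        p = rng.dirichlet(np.ones(rng.integers(2, 12)))
        d = dist(*p)
        assert shannon_diversity(d) == pytest.approx(
            math.exp(scipy_entropy(p)))


@given(st.lists(st.floats(0.01, 10), min_size=1, max_size=20))
def test_hill_monotone_nonincreasing_in_q(weights):
    p = np.array(weights) / sum(weights)
    values = [hill_from_freqs(p, q) for q in (0, 0.5, 1, 2, 5)]
    for a, b in zip(values, values[1:]):
        assert a >= b - 1e-9
    assert values[-1] >= 1 - 1e-12
    assert values[0] == len(p)


@given(st.lists(st.floats(0.01, 10), min_size=1, max_size=20),
       st.floats(0, 4))
def test_hill_invariant_to_relabeling_and_zero_padding(weights, q):
    p = np.array(weights) / sum(weights)
    base = hill_from_freqs(p, q)
    assert hill_from_freqs(p[::-1], q) == pytest.approx(base)
    assert hill_from_freqs(np.concatenate([p, [0, 0]]), q) == pytest.approx(base)


# ---------------------------------------------------------------------------
# Jensen–Shannon divergence


def test_jsd_identity_is_exactly_zero(rng):
    for _ in range(20):
        p = rng.dirichlet(np.ones(rng.integers(1, 10)))
        d = dist(*p)
        assert jsd_value(d, d) == 0.0


def test_jsd_disjoint_supports_is_one_bit():
    p = dist(1.0, labels=["A"])
    q = dist(1.0, labels=["B"])
    assert jsd_value(p, q, log_base=2) == pytest.approx(1.0)


def test_jsd_symmetric_and_bounded(rng):
    for _ in range(20):
        labels = [f"v{i}" for i in range(6)]
        p = dist(*rng.dirichlet(np.ones(6)), labels=labels)
        q = dist(*rng.dirichlet(np.ones(6)), labels=labels)
        ab, ba = jsd_value(p, q), jsd_value(q, p)
        assert ab == pytest.approx(ba)
        assert 0 <= ab <= 1


def test_jsd_matches_scipy_on_shared_support(rng):
    labels = [f"v{i}" for i in range(8)]
    for _ in range(10):
        a, b = rng.dirichlet(np.ones(8)), rng.dirichlet(np.ones(8))
        ours = jsd_value(dist(*a, labels=labels), dist(*b, labels=labels))
        assert ours == pytest.approx(jensenshannon(a, b, base=2) ** 2)


def test_jsd_zero_pads_disjoint_labels():
    p = dist(0.5, 0.5, labels=["A", "B"])
    q = dist(0.5, 0.5, labels=["B", "C"])
    pair = jsd(p, q)
    assert pair.labels == ["A", "B", "C"]
    assert pair.m.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# bootstrap series


def one_variant_corpus():
    g = make_game([(16, 16), (4, 16)])
    return {
        TimeBin(1990, 1990): [g] * 5,
        TimeBin(1991, 1991): [g] * 9,
        TimeBin(1992, 1992): [g] * 3,
    }


def test_bootstrap_of_point_mass_is_exact():
    series = bootstrap_series(one_variant_corpus(), "shannon_diversity",
                              n_draw=20, n_iter=10, seed=1)
    assert np.allclose(series.stat_mean, 1.0)
    jsd_series = bootstrap_series(one_variant_corpus(), "jsd_vs_previous",
                                  n_draw=20, n_iter=10, seed=1)
    assert np.isnan(jsd_series.stat_mean[0])           # no previous bin
    assert np.allclose(jsd_series.stat_mean[1:], 0.0)


def test_bootstrap_deterministic_for_fixed_seed(synthetic_small):
    from fuseki.canonical import canonicalize_game
    from fuseki.corpus import GameRecord, group_by_bin

    records, _ = synthetic_small
    canon = [GameRecord(**{**g.__dict__,
                           "moves": canonicalize_game(g.moves)[0]})
             for g in records[:500]]
    by_bin = group_by_bin(canon)
    a = bootstrap_series(by_bin, "shannon_diversity", n_draw=50, n_iter=20,
                         seed=42)
    b = bootstrap_series(by_bin, "shannon_diversity", n_draw=50, n_iter=20,
                         seed=42)
    np.testing.assert_array_equal(a.stat_mean, b.stat_mean)
    c = bootstrap_series(by_bin, "shannon_diversity", n_draw=50, n_iter=20,
                         seed=43)
    assert not np.array_equal(a.stat_mean, c.stat_mean)


def test_bootstrap_mean_matches_direct_monte_carlo_oracle(rng):
    """Uniform 4-variant bin: the bootstrap mean of 1D must agree with a
    large direct Monte-Carlo estimate of the subsampled expectation."""
    variants = [[(16, 16), (4, 16)], [(16, 16), (4, 4)],
                [(16, 17), (4, 4)], [(17, 17), (4, 17)]]
    games = [make_game(v) for v in variants for _ in range(100)]
    series = bootstrap_series({TimeBin(2000, 2000): games},
                              "shannon_diversity",
                              n_draw=100, n_iter=400, seed=5)
    # oracle: multinomial(100, uniform-4) -> exp(H'), 10^5 replicates
    counts = rng.multinomial(100, [0.25] * 4, size=100_000)
    freqs = counts / 100
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(freqs > 0, np.log(np.where(freqs > 0, freqs, 1)), 0.0)
    oracle = np.exp(-(freqs * logs).sum(axis=1))
    se = np.sqrt(oracle.var() / 400 + oracle.var() / 100_000)
    assert 1 < series.stat_mean[0] <= 4
    assert abs(series.stat_mean[0] - oracle.mean()) < 3 * se


def test_bootstrap_without_replacement_recovers_plugin_value():
    games = ([make_game([(16, 16), (4, 16)])] * 6
             + [make_game([(16, 16), (4, 4)])] * 2)
    series = bootstrap_series({TimeBin(2000, 2000): games},
                              "shannon_diversity", n_draw=8, n_iter=5,
                              seed=0, replace=False)
    plug_in = shannon_diversity(tally_variants(games))
    assert series.stat_mean[0] == pytest.approx(plug_in)


def test_empty_bin_emits_missing_value_with_warning():
    bins = one_variant_corpus()
    bins[TimeBin(1993, 1993)] = [make_game([(16, 16)])]   # incomplete only
    with pytest.warns(UserWarning):
        series = bootstrap_series(bins, "shannon_diversity", n_draw=10,
                                  n_iter=5, seed=0)
    assert np.isnan(series.stat_mean[-1])
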