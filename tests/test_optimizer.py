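import numpy as np
import pandas as pd
import pytest

from caselect.behavior import StateSequence
from caselect.optimizer import (
    TemplateSet,
    _PairCache,
    accuracy,
    bootstrap_validate,
    combined_robustness,
    find_templates,
    first_and_second,
    holdout_cv,
    level_robustness,
    level_robustness_table,
    normalized_rate_difference,
    rank_settings,
    select_optimal,
    split_counts,
)
from caselect.settings import enumerate_settings

SETTINGS = enumerate_settings()[0]


def _states(n_oa, n_ca):
    is_oa = np.zeros(n_oa + n_ca, dtype=bool)
    is_oa[:n_oa] = True
    return StateSequence(is_oa, np.ones(n_oa + n_ca, bool), "head", 20.0)


def test_template_identification_from_raw_rates():
    states = _states(1000, 1000)
    ev = [
        np.arange(100),          # 100 OA events, 2 CA events -> d ~ 0.96
        np.arange(980, 1002),    # mixed
        np.concatenate([np.arange(30), 1000 + np.arange(30)]),  # equal -> NS
        np.concatenate([np.arange(60), 1000 + np.arange(40)]),  # d = 0.2
        np.array([], dtype=int),  # silent: never a template
    ]
    ev[0] = np.concatenate([np.arange(100), np.array([1000, 1001])])
    d = normalized_rate_difference(ev, states)
    assert d[0] == pytest.approx(98 / 102)
    assert d[2] == 0.0
    assert d[3] == pytest.approx(0.2)
    assert np.isnan(d[4])
    t = find_templates(ev, states)
    assert 0 in t.oa_ids
    assert 2 in t.ns_ids
    assert 3 not in np.concatenate([t.oa_ids, t.ca_ids, t.ns_ids])
    assert 4 not in np.concatenate([t.oa_ids, t.ca_ids, t.ns_ids])


def _templates():
    return TemplateSet(np.arange(7), 7 + np.arange(13), 20 + np.arange(13))


def test_accuracy_direct_count():
    t = _templates()
    codes = t.truth_codes.copy()
    labels = np.zeros(40, dtype=np.int8)
    labels[t.all_ids] = codes
    acc, per = accuracy(labels, t)
    assert acc == 100.0
    labels[t.all_ids[0]] = -1  # two template errors
    labels[t.all_ids[1]] = 0
    acc, per = accuracy(labels, t)
    assert round(acc, 2) == 93.94
    with pytest.raises(ValueError):
        accuracy(labels, TemplateSet(*[np.array([], int)] * 3))


def test_accuracy_of_random_labels_near_chance(rng):
    t = _templates()
    n_iter, accs = 200, []
    for _ in range(n_iter):
        labels = rng.integers(-1, 2, 40).astype(np.int8)
        accs.append(accuracy(labels, t)[0])
    assert np.mean(accs) == pytest.approx(100 / 3, abs=2.5)


def test_level_robustness_toy_matrix_brute_force():
    s = SETTINGS[:3]
    vals = np.array([[1.0, 0.6, 0.8], [0.6, 1.0, 0.4], [0.8, 0.4, 1.0]])
    # all three settings share behavioral=head? check actual membership
    lvl = s[0].levels[0]
    members = [i for i, x in enumerate(s) if lvl in x.levels]
    pairs = [(i, j) for i in members for j in members if i < j]
    expected = np.mean([vals[i, j] for i, j in pairs])
    assert level_robustness(vals, s, lvl) == pytest.approx(expected)
    const = np.full((3, 3), 0.7)
    assert level_robustness(const, s, lvl) == pytest.approx(0.7)
    with pytest.raises(ValueError):
        level_robustness(vals, s, "behavioral=nosuch")


def test_level_robustness_invariant_to_setting_order(rng):
    s = SETTINGS[:6]
    vals = rng.random((6, 6))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 1)
    lvl = "shuffle=randperm"
    base = level_robustness(vals, s, lvl)
    perm = rng.permutation(6)
    assert level_robustness(vals[np.ix_(perm, perm)], [s[i] for i in perm], lvl) == pytest.approx(base)


def test_combined_robustness_mean_of_levels():
    s = SETTINGS[0]
    table = dict(zip(s.levels, [0.9, 0.8, 0.7, 0.9, 0.8]))
    assert combined_robustness(s, table) == pytest.approx(82.0)
    table = dict(zip(s.levels, [0.8] * 5))
    assert combined_robustness(s, table) == pytest.approx(80.0)
    vals = [0.3, 0.5, 0.9, 0.6, 0.7]
    table = dict(zip(s.levels, vals))
    cr = combined_robustness(s, table)
    assert 100 * min(vals) <= cr <= 100 * max(vals)


def _scores(accs, robs):
    return pd.DataFrame(
        {
            "setting_id": np.arange(1, len(accs) + 1),
            "accuracy": accs,
            "combined_robustness": robs,
        }
    )


def test_ranking_and_optimal_selection():
    df = rank_settings(_scores([100, 100, 90, 100], [80, 85, 99, 70]))
    assert df.iloc[0].setting_id == 2  # accuracy first, then robustness
    assert df.iloc[0]["rank"] == 1
    opt = select_optimal(df, robustness_percentile=50.0)
    assert opt.setting_id.tolist() == [2]
    # ties share a rank
    df = rank_settings(_scores([100, 100], [80, 80]))
    assert df["rank"].tolist() == [1, 1]
    # nothing reaches accuracy 100 -> empty optimal set, ranking intact
    df = rank_settings(_scores([90, 80], [99, 99]))
    assert select_optimal(df).empty
    assert df["rank"].tolist() == [1, 2]


def test_stratified_split_counts_match_study_arithmetic():
    got = split_counts([7, 13, 13, 659], 0.6)
    assert got == [(4, 3), (8, 5), (8, 5), (395, 264)]
    train_templates = sum(tr for tr, _ in got[:3])
    assert train_templates == 20


def test_pair_cache_uniform_weights_reproduce_full_sample_scores(rng):
    # the resampling fast path must agree with the direct definitions when
    # every neuron has weight 1
    S, N = 16, 80  # first 16 settings contain every constituent level twice+
    labels = rng.integers(-1, 2, (S, N)).astype(np.int8)
    settings = SETTINGS[:S]
    cache = _PairCache.build(labels, settings, None)
    w = np.ones((N, 1), dtype=np.float32)
    cons = cache.consistency_values(w)[:, 0]
    vals = np.ones((S, S))
    for p, (i, j) in enumerate(cache.pair_idx):
        vals[i, j] = vals[j, i] = np.mean(labels[i] == labels[j])
        assert cons[p] == pytest.approx(vals[i, j])
    table = level_robustness_table(vals, settings)
    rob = cache.combined_robustness(cache.consistency_values(w))[:, 0]
    for i, s in enumerate(settings):
        assert rob[i] == pytest.approx(combined_robustness(s, table))


def test_bootstrap_validate_accounting(rng):
    S, N = 5, 60
    labels = rng.integers(-1, 2, (S, N)).astype(np.int8)
    t = TemplateSet(np.arange(3), 3 + np.arange(4), 7 + np.arange(4))
    out = bootstrap_validate(labels, SETTINGS[:S], t, n_iter=25, seed=0)
    assert out["first_counts"].sum() == 25
    assert out["second_counts"].sum() == 25


def test_holdout_degenerate_split_gives_rho_one(rng):
    S, N = 8, 100
    labels = rng.integers(-1, 2, (S, N)).astype(np.int8)
    t = TemplateSet(np.arange(4), 4 + np.arange(5), 9 + np.arange(5))
    out = holdout_cv(labels, SETTINGS[:S], t, n_iter=3, train_frac=1.0, seed=0)
    assert out["median_rho"] == pytest.approx(1.0)
    assert np.allclose(out["rho"], 1.0)


def test_holdout_random_labels_rho_near_zero(rng):
    # with i.i.d. random labels every setting is statistically equivalent, so
    # train/test rankings are driven by independent noise
    S, N = 12, 400
    labels = rng.integers(-1, 2, (S, N)).astype(np.int8)
    t = TemplateSet(np.arange(6), 6 + np.arange(8), 14 + np.arange(8))
    out = holdout_cv(labels, SETTINGS[:S], t, n_iter=30, seed=1)
    assert abs(out["median_rho"]) < 0.4


def test_holdout_rejects_tiny_strata(rng):
    labels = rng.integers(-1, 2, (3, 10)).astype(np.int8)
    t = TemplateSet(np.array([0]), np.array([1, 2]), np.array([3, 4]))
    with pytest.raises(ValueError, match="stratum too small"):
        holdout_cv(labels, SETTINGS[:3], t, n_iter=2, seed=0)


def test_tie_break_is_deterministic():
    df = _scores([100, 100, 100], [90.0, 90.0, 80.0])
    first, second = first_and_second(df)
    assert (first, second) == (1, 2)
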