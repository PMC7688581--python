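import logging

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morphcomp.evaluation import (
    LRT_CRITICAL_05,
    CompetenceEvaluation,
    TrialTable,
    deviance_accuracy,
    effect_accuracy,
    evaluate_all,
    fit_mixed,
    group_contrast,
    preprocess_trials,
    residual_accuracy,
)
from morphcomp.synth import JudgmentSimConfig, simulate_judgments
from conftest import make_clean_metadata


def _raw_trials(ratings_by_participant):
    rows = []
    for p, ratings in ratings_by_participant.items():
        for i, r in enumerate(ratings):
            rows.append((p, 1, i + 1, f"w{i}", r))
    return pd.DataFrame(
        rows, columns=["participant", "list", "position", "word", "rating"]
    )


# -- preprocessing -----------------------------------------------------------


def test_preprocess_exclusions_and_zscoring():
    trials = _raw_trials(
        {"p1": [1, 2, 3, 4], "p2": [4, 4, 4, 4], "p3": [7, 6, 5, np.nan]}
    )
    meta = pd.DataFrame(
        {
            "participant": ["p1", "p2", "p3"],
            "native_language": ["English", "English", "French"],
            "birthplace": ["USA", "USA", "USA"],
        }
    )
    tt = preprocess_trials(trials, meta)
    assert tt.n_participants == 2
    assert tt.n_excluded_participants == 1
    assert len(tt) == 8  # p3's four trials removed entirely with them
    z1 = tt.frame.loc[tt.frame["participant"] == "p1", "z_rating"]
    assert z1.mean() == pytest.approx(0, abs=1e-9)
    assert z1.std(ddof=1) == pytest.approx(1, abs=1e-9)
    # zero-variance participant: z = 0
    assert (tt.frame.loc[tt.frame["participant"] == "p2", "z_rating"] == 0).all()


def test_preprocess_drops_incomplete_trials():
    trials = _raw_trials({"p1": [1, 2, np.nan, 4], "p2": [2, 2, 3, 3]})
    tt = preprocess_trials(trials, make_clean_metadata(trials["participant"]))
    assert len(tt) == 7
    assert tt.n_incomplete_dropped == 1


def test_preprocess_rejects_out_of_scale_ratings():
    trials = _raw_trials({"p1": [1, 2, 9, 4]})
    with pytest.raises(ValueError, match="1-7"):
        preprocess_trials(trials, make_clean_metadata(trials["participant"]))


# -- contrasts ---------------------------------------------------------------


def test_group_contrast_hand_oracle():
    c = group_contrast([1, 2, 3], [2, 3, 4])
    assert c.d == pytest.approx(-1.0)
    assert c.t == pytest.approx(-np.sqrt(1.5))
    # t and d are mutually consistent for equal group sizes: t = d sqrt(n/2)
    assert c.t == pytest.approx(c.d * np.sqrt(3 / 2))


def test_group_contrast_identical_groups():
    c = group_contrast([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert c.t == pytest.approx(0.0)
    assert c.d == pytest.approx(0.0)
    assert c.p == pytest.approx(1.0)


def test_group_contrast_consistency_at_study_scale():
    """d = 0.28 with 300 words per group implies t ~ 3.4."""
    rng = np.random.default_rng(0)
    a = rng.normal(0.28, 1.0, 300)
    b = rng.normal(0.0, 1.0, 300)
    c = group_contrast(a, b)
    assert c.t == pytest.approx(c.d * np.sqrt(300 / 2), rel=1e-12)


def test_group_contrast_rejects_tiny_groups():
    with pytest.raises(ValueError):
        group_contrast([1.0], [2.0, 3.0])


def test_effect_accuracy():
    assert effect_accuracy(0.28, 0.22) == pytest.approx(0.06)
    assert effect_accuracy(0.28, 0.94) == pytest.approx(0.66)
    assert effect_accuracy(0.5, 0.5) == 0.0
    with pytest.raises(ValueError):
        effect_accuracy(float("nan"), 0.1)


# -- mixed-model metrics -----------------------------------------------------


def _simulated_trial_table(seed, n_words=60, n_participants=12, beta=0.4,
                           sds=(0.3, 0.2, 0.1), score=None):
    """Continuous-response trials from the generating latent model,
    bypassing Likert discretization (the estimator's own regime)."""
    rng = np.random.default_rng(seed)
    words = [f"w{i:03d}" for i in range(n_words)]
    if score is None:
        score = dict(zip(words, rng.normal(0, 1, n_words)))
    per_list = n_words // 2
    rows = []
    us = rng.normal(0, sds[0], n_participants)
    uw = dict(zip(words, rng.normal(0, sds[1], n_words)))
    uo = rng.normal(0, sds[2], per_list)
    for pi in range(n_participants):
        chunk = words[:per_list] if pi % 2 == 0 else words[per_list:]
        for pos, w in enumerate(chunk):
            y = beta * score[w] + us[pi] + uw[w] + uo[pos] + rng.normal(0, 1)
            rows.append((f"p{pi}", pi % 2, pos + 1, w, 4, y))
    frame = pd.DataFrame(
        rows, columns=["participant", "list", "position", "word", "rating", "z_rating"]
    )
    return TrialTable(frame, n_participants, 0, 0), score


def test_fit_mixed_recovers_slope():
    hits = 0
    for rep in range(10):
        trials, score = _simulated_trial_table(200 + rep)
        fit = fit_mixed(trials, score)
        est, se = fit.result.params["slor"], fit.result.bse["slor"]
        hits += abs(est - 0.4) <= 2 * se
    assert hits >= 9


def test_fit_mixed_requires_complete_scores():
    trials, score = _simulated_trial_table(1)
    score.pop("w000")
    with pytest.raises(ValueError, match="lack scores"):
        fit_mixed(trials, score)


def test_deviance_accuracy_identical_fits():
    trials, score = _simulated_trial_table(2)
    base = fit_mixed(trials)
    da, p = deviance_accuracy(base, base)
    assert da == 0.0
    assert p == pytest.approx(1.0)


def test_deviance_accuracy_pvalue_matches_chi2():
    trials, score = _simulated_trial_table(3)
    base = fit_mixed(trials)
    target = fit_mixed(trials, score)
    da, p = deviance_accuracy(base, target)
    assert da >= 0
    assert p == pytest.approx(float(stats.chi2.sf(da, 1)), rel=1e-12)


def test_null_slor_rarely_clears_threshold():
    """A pure-noise score column should not beat the chi-squared bar."""
    hits = 0
    for rep in range(20):
        trials, _ = _simulated_trial_table(300 + rep, beta=0.0)
        rng = np.random.default_rng(900 + rep)
        noise = {w: rng.normal() for w in trials.frame["word"].unique()}
        da, _ = deviance_accuracy(fit_mixed(trials), fit_mixed(trials, noise))
        hits += da < LRT_CRITICAL_05
    assert hits >= 18


def test_lrt_critical_value():
    assert LRT_CRITICAL_05 == pytest.approx(3.84, abs=0.005)


# -- residual accuracy -------------------------------------------------------


class _FakeResult:
    def __init__(self, resid):
        self.resid = np.asarray(resid, dtype=float)
        self.deviance = 0.0
        self.converged = True


def _fake_fit(words, resid):
    from morphcomp.evaluation import FitResult

    return FitResult(_FakeResult(resid), np.asarray(words), "fake", False)


def _stim_meta(words, kinds, outers):
    return pd.DataFrame({"word": words, "kind": kinds, "outer": outers})


def test_residual_accuracy_zero_when_identical():
    words = ["w1", "w1", "w2", "w2"]
    base = _fake_fit(words, [0.5, -0.1, 0.2, 0.4])
    meta = _stim_meta(["w1", "w2"], ["linear", "nested"], ["al", "un"])
    rep = residual_accuracy(base, base, meta)
    assert rep.total == pytest.approx(0.0)
    assert (rep.per_word == 0).all()


def test_residual_accuracy_upper_bound():
    words = ["w1", "w1", "w2", "w2"]
    base = _fake_fit(words, [0.5, 0.3, -0.2, -0.4])
    target = _fake_fit(words, [0.1, -0.1, 0.3, -0.3])  # word means exactly 0
    meta = _stim_meta(["w1", "w2"], ["linear", "nested"], ["al", "un"])
    rep = residual_accuracy(base, target, meta)
    expected = abs(0.4) + abs(-0.3)
    assert rep.total == pytest.approx(expected)
    assert rep.per_kind["linear"] == pytest.approx(0.4)
    assert rep.per_kind["nested"] == pytest.approx(0.3)


def test_residual_accuracy_sign_convention():
    words = ["w1", "w2"]
    base = _fake_fit(words, [0.5, 0.1])
    target = _fake_fit(words, [0.1, 0.5])
    meta = _stim_meta(words, ["linear", "linear"], ["al", "ly"])
    rep = residual_accuracy(base, target, meta)
    assert rep.per_word["w1"] > 0  # improved
    assert rep.per_word["w2"] < 0  # worsened


def test_residual_accuracy_word_mismatch():
    base = _fake_fit(["w1"], [0.1])
    target = _fake_fit(["w2"], [0.1])
    meta = _stim_meta(["w1", "w2"], ["linear", "linear"], ["al", "al"])
    with pytest.raises(ValueError, match="different word sets"):
        residual_accuracy(base, target, meta)


# -- full evaluation ---------------------------------------------------------


def test_evaluate_all_schema(demo_scores, demo_stim_frame):
    words = sorted(demo_stim_frame["word"])
    piv = demo_scores.pivot(index="word", columns="model", values="slor")
    cfg = JudgmentSimConfig(n_participants=12, n_lists=4, beta=0.5, seed=77)
    raw = simulate_judgments(words, dict(piv["pcfg"]), cfg)
    trials = preprocess_trials(raw, make_clean_metadata(raw["participant"]))
    results = evaluate_all(demo_scores, trials, demo_stim_frame)
    assert set(results.table["model"]) == set(demo_scores["model"].unique())
    assert len(results.table) == 5
    for col in ["slor_linear", "slor_nested", "t", "p", "d", "ea", "da", "da_p", "ra"]:
        assert results.table[col].notna().all()
    assert results.pairwise_da.shape[0] == 10
    assert set(results.ra) == set(results.table["model"])
    # human raw means live on the 1-7 scale
    assert 1 <= results.human_raw_means[0] <= 7
    text = results.summary()
    assert "Human" in text and "pcfg" in text
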