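import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphcomp.models import (
    BOS,
    EOS,
    SmoothingConfig,
    load_models,
    save_models,
    token_weight,
    tokenize,
    train_bigram,
    train_hmm,
    train_pcfg,
    train_unigram,
)
from morphcomp.trees import MorphTree, parse_struclab, parse_tree_string

from oracles import hmm_brute_force, pcfg_brute_force, random_hmm, random_pcfg

ALPHA = SmoothingConfig(0.1)


# -- tokenization ------------------------------------------------------------


def test_tokenize_characters():
    assert tokenize("teach", "character") == ("t", "e", "a", "c", "h")


def test_tokenize_morphemes_from_tree():
    t = parse_struclab("((teach)[V],(er)[N|V.])[N]")
    assert tokenize(t, "morpheme") == ("teach", "er")
    t2 = parse_tree_string("(A un (A (V predict) able))")
    assert tokenize(t2, "morpheme") == ("un", "predict", "able")


def test_tokenize_requires_segmentation_for_morphemes():
    with pytest.raises(ValueError):
        tokenize("teacher", "morpheme")
    with pytest.raises(ValueError):
        tokenize("", "character")
    with pytest.raises(ValueError):
        tokenize("teach", "pixels")


# -- bigram model ------------------------------------------------------------


def test_bigram_hand_arithmetic():
    """Single word 'ab', weight 1: V = {a, b, EOS, UNK}, so
    P(a|BOS) = (1 + 0.1) / (1 + 0.1 * 4)."""
    m = train_bigram([(("a", "b"), 1.0)], ALPHA)
    assert math.isclose(math.exp(m.log_transition(BOS, "a")), 1.1 / 1.4)
    # unseen transition: count 0 over context total 1
    assert math.isclose(math.exp(m.log_transition("b", "a")), 0.1 / 1.4)
    expected = (
        math.log(1.1 / 1.4)  # BOS -> a
        + math.log(1.1 / 1.4)  # a -> b
        + math.log(1.1 / 1.4)  # b -> EOS
    )
    assert math.isclose(m.logprob(("a", "b")), expected)


def test_bigram_unknown_units_finite():
    m = train_bigram([(("a", "b"), 2.0)], ALPHA)
    assert math.isfinite(m.logprob(("a", "z")))
    assert math.isfinite(m.logprob(("q", "q", "q")))


def test_bigram_unsmoothed_zero_is_flagged_infinite():
    m = train_bigram([(("a", "b"), 1.0)], SmoothingConfig(0.0))
    assert m.logprob(("b", "a")) == float("-inf")


def test_bigram_extension_decreases_probability():
    m = train_bigram([(("a", "b"), 3.0), (("b", "a"), 1.0)], ALPHA)
    assert m.logprob(("a", "b", "a")) < m.logprob(("a", "b"))


def test_bigram_rows_normalize(demo_models):
    models, _ = demo_models
    for name in ("character", "syllable", "morpheme"):
        m = models[name]
        for ctx in [BOS, *m.vocab[:20]]:
            total = sum(math.exp(m.log_transition(ctx, s)) for s in m.successors())
            assert abs(total - 1.0) < 1e-9


def test_bigram_markov_decomposition():
    m = train_bigram([(("a", "b", "c"), 1.0), (("b", "c"), 2.0)], ALPHA)
    seq = ("a", "b", "c")
    units = [BOS, *seq, EOS]
    assert math.isclose(
        m.logprob(seq),
        sum(m.log_transition(x, y) for x, y in zip(units, units[1:])),
    )


def test_weight_scale_invariance():
    """MLE transition ratios are invariant to rescaling all weights."""
    seqs = [(("a", "b"), 1.0), (("b",), 3.0)]
    doubled = [(s, 2 * w) for s, w in seqs]
    m1, m2 = (
        train_bigram(seqs, SmoothingConfig(0.0)),
        train_bigram(doubled, SmoothingConfig(0.0)),
    )
    assert math.isclose(m1.logprob(("a", "b")), m2.logprob(("a", "b")))


def test_empty_training_rejected():
    for trainer in (train_bigram, train_unigram, train_hmm, train_pcfg):
        with pytest.raises(ValueError):
            trainer([], ALPHA)


def test_token_weight_floor():
    assert token_weight(0) == 1.0
    assert token_weight(7) == 7.0


# -- unigram -----------------------------------------------------------------


def test_unigram_hand_arithmetic():
    """3-type corpus: p(m) = (c + 0.1) / (N + 0.1 * (|V| + 1))."""
    m = train_unigram([(("a",), 2.0), (("b",), 1.0), (("c",), 1.0)], ALPHA)
    assert math.isclose(math.exp(m.log_prob("a")), 2.1 / (4 + 0.1 * 4))
    assert math.isclose(math.exp(m.log_prob("zzz")), 0.1 / (4 + 0.1 * 4))
    assert math.isclose(
        m.logprob(("a", "b")), m.log_prob("a") + m.log_prob("b")
    )
    total = sum(math.exp(m.log_prob(u)) for u in ["a", "b", "c", "zzz"])
    assert abs(total - 1.0) < 1e-9


# -- HMM ---------------------------------------------------------------------


def test_hmm_hand_arithmetic():
    seq = [("a", "X"), ("b", "Y")]
    m = train_hmm([(seq, 1.0)], ALPHA)
    # transition vocabulary = {X, Y, EOS}
    assert math.isclose(math.exp(m.log_transition("X", "Y")), 1.1 / 1.3)
    assert m.trans_counts["X"]["Y"] / sum(m.trans_counts["X"].values()) == 1.0


def test_hmm_transition_rows_normalize(demo_models):
    models, _ = demo_models
    h = models["hmm"]
    for ctx in [BOS, *h.tags]:
        total = sum(
            math.exp(h.log_transition(ctx, t)) for t in [*h.tags, EOS]
        )
        assert abs(total - 1.0) < 1e-9


def test_hmm_weight_doubling_invariance():
    seqs = [([("a", "X"), ("b", "Y")], 1.0), ([("b", "X")], 2.0)]
    m1 = train_hmm(seqs, SmoothingConfig(0.0))
    m2 = train_hmm([(s, 2 * w) for s, w in seqs], SmoothingConfig(0.0))
    assert math.isclose(m1.logprob(["a", "b"]), m2.logprob(["a", "b"]))


@settings(max_examples=60, deadline=None)
@given(st.integers(0, 10_000), st.integers(1, 3))
def test_hmm_forward_equals_enumeration(seed, length):
    rng = np.random.default_rng(seed)
    m = random_hmm(rng)
    seq = [["a", "b", "c", "zzz"][rng.integers(4)] for _ in range(length)]
    assert math.isclose(m.logprob(seq), hmm_brute_force(m, seq), rel_tol=1e-10)


def test_hmm_single_morpheme_closed_form():
    m = random_hmm(np.random.default_rng(0), n_tags=2)
    total = sum(
        math.exp(
            m.log_transition(BOS, t)
            + m.log_emission(t, "a")
            + m.log_transition(t, EOS)
        )
        for t in m.tags
    )
    assert math.isclose(m.logprob(["a"]), math.log(total), rel_tol=1e-12)


def test_hmm_unknown_morpheme_finite():
    m = random_hmm(np.random.default_rng(1))
    assert math.isfinite(m.logprob(["never-seen"]))


def test_single_tag_hmm_reduces_to_unigram():
    """With one tag the forward sum collapses to emission products times
    constant tag-transition terms, and emissions match the unigram."""
    words = [(("a", "b"), 2.0), (("b", "c"), 1.0), (("a",), 3.0)]
    tagged = [([(m, "T") for m in seq], w) for seq, w in words]
    hmm = train_hmm(tagged, ALPHA)
    uni = train_unigram(words, ALPHA)
    for seq in [["a"], ["a", "b"], ["c", "b", "a"], ["zzz"]]:
        const = hmm.log_transition(BOS, "T") + hmm.log_transition("T", EOS)
        const += (len(seq) - 1) * hmm.log_transition("T", "T")
        assert math.isclose(hmm.logprob(seq), uni.logprob(seq) + const, rel_tol=1e-12)


# -- PCFG --------------------------------------------------------------------


def test_pcfg_single_rule_mle():
    t = parse_struclab("((teach)[V],(er)[N|V.])[N]")
    m = train_pcfg([(t, 2.0)], ALPHA)
    assert m.rule_prob("N", (("NT", "V"), ("AFF", "er")), smoothed=False) == 1.0


def test_pcfg_single_parse_is_rule_product():
    t = parse_tree_string("(N (A happy) ness)")
    m = train_pcfg([(t, 2.0)], ALPHA)
    expected = (
        m.log_start_prob("N")
        + m.log_rule_prob("N", (("NT", "A"), ("AFF", "ness")))
        + m.log_rule_prob("A", (("ROOT", "happy"),))
    )
    assert math.isclose(m.logprob(["happy", "ness"]), expected, rel_tol=1e-12)


def test_pcfg_rule_distributions_normalize(demo_models):
    models, _ = demo_models
    p = models["pcfg"]
    for lhs, d in p.rule_counts.items():
        total = sum(math.exp(p.log_rule_prob(lhs, rhs)) for rhs in d)
        total += math.exp(p.log_rule_prob(lhs, (("ROOT", "<unk>"),)))
        assert abs(total - 1.0) < 1e-9
    start_total = sum(math.exp(p.log_start_prob(c)) for c in p.categories)
    assert abs(start_total - 1.0) < 1e-9


def test_pcfg_structural_ambiguity_sums_over_parses():
    """[un [x able]] and [[un x] able] both parse; the chart must sum."""
    t1 = parse_tree_string("(A un (A (V x) able))")
    t2 = parse_tree_string("(A (V un (V x)) able)")
    m = train_pcfg([(t1, 2.0), (t2, 1.0)], ALPHA)
    seq = ["un", "x", "able"]
    assert math.isclose(m.logprob(seq), pcfg_brute_force(m, seq), rel_tol=1e-10)


def test_pcfg_linear_and_nested_both_finite(demo_models, demo_stimuli):
    models, _ = demo_models
    p = models["pcfg"]
    lin = next(s for s in demo_stimuli if s.kind == "linear")
    nst = next(s for s in demo_stimuli if s.kind == "nested")
    assert math.isfinite(p.logprob(lin.morphemes))
    assert math.isfinite(p.logprob(nst.morphemes))


def test_pcfg_no_parse_is_minus_inf():
    t = parse_tree_string("(N (A happy) ness)")
    m = train_pcfg([(t, 1.0)], ALPHA)
    assert m.logprob(["ness", "happy", "ness"]) == float("-inf")
    assert not m.parseable(["ness", "happy", "ness"])


def test_pcfg_unary_chain_geometric_closure():
    """A unary self-loop X -> X sums a geometric series exactly."""
    loop = MorphTree("X", (MorphTree("X", ("a",)),))
    m = train_pcfg([(loop, 1.0)], ALPHA)
    p_u = math.exp(m.log_rule_prob("X", (("NT", "X"),)))
    p_a = math.exp(m.log_rule_prob("X", (("ROOT", "a"),)))
    inside = m.inside(["a"])["X"]
    assert math.isclose(inside, p_a / (1 - p_u), rel_tol=1e-12)


@settings(max_examples=60, deadline=None)
@given(st.integers(0, 10_000), st.integers(1, 3))
def test_pcfg_inside_equals_enumeration(seed, length):
    rng = np.random.default_rng(seed)
    m = random_pcfg(rng)
    symbols = ["a", "b", "p", "q", "zzz"]
    seq = [symbols[rng.integers(len(symbols))] for _ in range(length)]
    ours, brute = m.logprob(seq), pcfg_brute_force(m, seq)
    if math.isinf(brute):
        assert math.isinf(ours)
    else:
        assert math.isclose(ours, brute, rel_tol=1e-10)


# -- serialization -----------------------------------------------------------


def test_model_serialization_round_trip(tmp_path, demo_models, demo_stimuli):
    models, unigram = demo_models
    path = tmp_path / "models.json"
    save_models(models, unigram, path)
    loaded, uni2 = load_models(path)
    stim = demo_stimuli[0]
    for name in models:
        m1, m2 = models[name], loaded[name]
        units = stim.morphemes if name in ("morpheme", "hmm", "pcfg") else tokenize(
            stim.surface, m1.unit_kind
        )
        assert math.isclose(m1.logprob(units), m2.logprob(units), rel_tol=1e-12)
    assert math.isclose(
        unigram.logprob(stim.morphemes), uni2.logprob(stim.morphemes), rel_tol=1e-12
    )
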