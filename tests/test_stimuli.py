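import numpy as np
import pandas as pd
import pytest

from morphcomp.lexicon import LexicalEntry, Lexicon
from morphcomp.stimuli import (
    DEFAULT_JUNCTION_RULES,
    StimulusGenerationError,
    StructureTemplate,
    build_lists,
    candidate_stems,
    extract_templates,
    generate_stimuli,
    orthographic_adjust,
)
from morphcomp.trees import Shape, classify_shape, parse_struclab, tree_to_struclab


def _entry(struclab, freq=50, flags=frozenset()):
    tree = parse_struclab(struclab)
    leaves = tree.leaves()
    status = "C" if len(leaves) > 1 else ("M" if tree.is_root_node else "Z")
    return LexicalEntry("".join(leaves), freq, status, struclab, tree, flags)


def _linear(root, inner, outer, cats=("A", "N", "V"), freq=50):
    o, m, r = cats
    return _entry(
        f"((({root})[{r}],({inner})[{m}|{r}.])[{m}],({outer})[{o}|{m}.])[{o}]", freq
    )


def _nested(root, inner, prefix, cats=("A", "A", "V"), freq=50):
    o, m, r = cats
    return _entry(
        f"(({prefix})[{o}|.{m}],(({root})[{r}],({inner})[{m}|{r}.])[{m}])[{o}]", freq
    )


def _bimorph(root, suffix, cats=("N", "V"), freq=50):
    m, r = cats
    return _entry(f"(({root})[{r}],({suffix})[{m}|{r}.])[{m}]", freq)


ROOTS = [f"r{i:02d}" for i in range(40)]


def test_extract_templates_accepts_best_combination():
    """Seven ion+al types, threshold 5, productive 'al' -> one template."""
    entries = [_linear(ROOTS[i], "ion", "al", cats=("A", "N", "V")) for i in range(7)]
    entries += [_linear(ROOTS[i + 10], "or", "al", cats=("A", "N", "V")) for i in range(3)]
    lex = Lexicon(entries)
    tpls = extract_templates(lex, "linear", 5, frozenset({"al"}))
    assert len(tpls) == 1
    t = tpls[0]
    assert (t.outer, t.inner, t.cats, t.type_freq) == ("al", "ion", ("A", "N", "V"), 7)
    assert t.describe() == "[A [N [V Root] ion] al]"


def test_extract_templates_threshold_rejection():
    entries = [_linear(ROOTS[i], "ion", "al") for i in range(4)]
    lex = Lexicon(entries)
    assert extract_templates(lex, "linear", 5, frozenset({"al"})) == []


def test_extract_templates_nested():
    entries = [_nested(ROOTS[i], "able", "un") for i in range(2)]
    lex = Lexicon(entries)
    tpls = extract_templates(lex, "nested", 2, frozenset({"un"}))
    assert len(tpls) == 1
    assert tpls[0].describe() == "[A un [A [V Root] able]]"


def test_extract_templates_requires_productive_affix():
    entries = [_linear(ROOTS[i], "ion", "al") for i in range(7)]
    lex = Lexicon(entries)
    assert extract_templates(lex, "linear", 5, frozenset({"ness"})) == []


def test_extract_templates_skips_flagged_entries():
    entries = [_linear(ROOTS[i], "ion", "al") for i in range(4)]
    entries += [
        _entry(
            "(((r98)[V],(ion)[N|V.])[N],(al)[A|N.])[A]", flags=frozenset({"StrucOpac"})
        )
    ]
    lex = Lexicon(entries)
    assert extract_templates(lex, "linear", 5, frozenset({"al"})) == []


def test_extract_templates_order_independent():
    rng = np.random.default_rng(0)
    entries = [_linear(ROOTS[i], "ion", "al") for i in range(6)] + [
        _linear(ROOTS[i + 20], "or", "al") for i in range(6)
    ]
    lex1 = Lexicon(entries)
    lex2 = Lexicon([entries[i] for i in rng.permutation(len(entries))])
    t1 = extract_templates(lex1, "linear", 5, frozenset({"al"}))
    t2 = extract_templates(lex2, "linear", 5, frozenset({"al"}))
    assert t1 == t2
    # tie at 6 vs 6: lexicographic tie-break picks 'ion' over 'or'
    assert t1[0].inner == "ion"


def test_candidate_stems_matching_rules():
    tpl = StructureTemplate("linear", "al", "ion", ("A", "N", "V"), 7)
    computation = _bimorph("compute", "ion", cats=("N", "V"), freq=25)
    low_freq = _bimorph("relate", "ion", cats=("N", "V"), freq=19)
    wrong_suffix = _bimorph("accident", "al", cats=("A", "N"), freq=100)
    lex = Lexicon([computation, low_freq, wrong_suffix])
    stems = candidate_stems(lex, tpl, min_token_freq=20)
    assert [e.surface for e in stems] == ["computeion"]


@pytest.mark.parametrize(
    "stem,affix,side,expected",
    [
        ("digital", "ly", "suffix", "digitally"),
        ("observe", "able", "suffix", "observable"),  # e-deletion
        ("happy", "ness", "suffix", "happiness"),  # y -> i
        ("happy", "ish", "suffix", "happyish"),  # y kept before i
        ("predictable", "un", "prefix", "unpredictable"),
        ("bake", "er", "suffix", "baker"),
    ],
)
def test_orthographic_adjust(stem, affix, side, expected):
    assert orthographic_adjust(stem, affix, side) == expected


def test_orthographic_rules_are_data():
    assert orthographic_adjust("observe", "able", "suffix", rules=()) == "observeable"


# -- generation --------------------------------------------------------------


def _check_stimuli(stimuli, lex, n_per_kind):
    kinds = {"linear": 0, "nested": 0}
    roots = set()
    for s in stimuli:
        kinds[s.kind] += 1
        assert not lex.attested(s.surface)
        assert s.root not in roots
        roots.add(s.root)
        assert classify_shape(s.tree).value == f"trimorphemic_{s.kind}"
        # surface is the orthographically adjusted leaf concatenation
        side = "suffix" if s.kind == "linear" else "prefix"
        outer = s.morphemes[-1] if s.kind == "linear" else s.morphemes[0]
        assert orthographic_adjust(s.stem_surface, outer, side) == s.surface
    assert kinds == {"linear": n_per_kind, "nested": n_per_kind}


def test_generate_stimuli_properties(demo_lexicon, demo_templates, demo_stimuli):
    _check_stimuli(demo_stimuli, demo_lexicon, 60)


def test_generate_stimuli_deterministic(demo_lexicon, demo_templates):
    lin, nst = demo_templates
    a = generate_stimuli(demo_lexicon, lin, nst, n_per_kind=10, seed=3)
    b = generate_stimuli(demo_lexicon, lin, nst, n_per_kind=10, seed=3)
    assert a == b


def test_generate_stimuli_respects_blocklist(demo_lexicon, demo_templates):
    lin, nst = demo_templates
    first = generate_stimuli(demo_lexicon, lin, nst, n_per_kind=5, seed=3)[0]
    redo = generate_stimuli(
        demo_lexicon, lin, nst, n_per_kind=5, seed=3, blocklist=frozenset({first.surface})
    )
    assert first.surface not in {s.surface for s in redo}


def test_generate_stimuli_quota_failure_reports_shortfall():
    entries = [_linear(ROOTS[i], "ion", "al") for i in range(6)]
    entries += [_nested(ROOTS[i + 10], "able", "un") for i in range(2)]
    entries += [_bimorph(ROOTS[i + 20], "ion", cats=("N", "V")) for i in range(3)]
    entries += [_bimorph(ROOTS[i + 25], "able", cats=("A", "V")) for i in range(3)]
    lex = Lexicon(entries)
    lin = extract_templates(lex, "linear", 5, frozenset({"al"}))
    nst = extract_templates(lex, "nested", 2, frozenset({"un"}))
    with pytest.raises(StimulusGenerationError, match="quota unreachable"):
        generate_stimuli(lex, lin, nst, n_per_kind=10, seed=0)


def test_generate_exhausts_small_pool_exactly():
    """With an exhaustible pool the output is exactly the acceptable set."""
    entries = [_linear(ROOTS[i], "ion", "al") for i in range(6)]
    entries += [_nested(ROOTS[i + 10], "able", "un") for i in range(2)]
    lin_stems = [_bimorph(ROOTS[i + 20], "ion", cats=("N", "V")) for i in range(4)]
    nst_stems = [_bimorph(ROOTS[i + 30], "able", cats=("A", "V")) for i in range(4)]
    lex = Lexicon(entries + lin_stems + nst_stems)
    lin = extract_templates(lex, "linear", 5, frozenset({"al"}))
    nst = extract_templates(lex, "nested", 2, frozenset({"un"}))
    out = generate_stimuli(lex, lin, nst, n_per_kind=4, seed=1)
    expected = {e.surface + "al" for e in lin_stems} | {
        "un" + e.surface for e in nst_stems
    }
    assert {s.surface for s in out} == expected


# -- lists -------------------------------------------------------------------


def test_build_lists_design(demo_stimuli):
    design = build_lists(demo_stimuli, n_lists=6, seed=0)
    assert design["list"].nunique() == 12
    per_list = design.groupby("list")["word"].count()
    assert (per_list == 20).all()
    kinds = {s.surface: s.kind for s in demo_stimuli}
    for k, grp in design.groupby("list"):
        counts = grp["word"].map(kinds).value_counts()
        assert counts["linear"] == 10 and counts["nested"] == 10
    # reversal contract
    for k in range(1, 7):
        fwd = design[design["list"] == k].sort_values("position")["word"].tolist()
        rev = design[design["list"] == k + 6].sort_values("position")["word"].tolist()
        assert rev == fwd[::-1]
    # partition contract over the original six lists
    words = design[design["list"] <= 6]["word"]
    assert len(words) == len(demo_stimuli)
    assert set(words) == {s.surface for s in demo_stimuli}


def test_build_lists_rejects_indivisible(demo_stimuli):
    with pytest.raises(ValueError):
        build_lists(demo_stimuli[:110], n_lists=6, seed=0)
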