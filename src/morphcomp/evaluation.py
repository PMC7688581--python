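"""Evaluating model SLOR scores against Likert acceptability judgments.

Pipeline: preprocess trials (participant exclusion, incomplete-trial
removal, per-participant z-scoring), fit a baseline linear mixed model
of the z-scored ratings with by-subject, by-word and by-order random
intercepts, then for each computational model a target fit that adds
the model's SLOR as a fixed effect.  Three metrics compare models to
humans:

* effect accuracy  EA = |d_human - d_model|, the absolute difference in
  Cohen's d for the linear-vs-nested contrast;
* deviance accuracy  DA = D_base - D_target, the likelihood-ratio drop
  in ML deviance when SLOR enters the model (chi-squared, df = 1);
* residual accuracy  RA = sum_w |eps_base(w)| - |eps_target(w)| over
  per-word mean conditional residuals, which localizes the improvement
  by word, affix and structure kind.

The top-level entry point is :class:`CompetenceEvaluation` (a model
object over trials + score table) whose :meth:`~CompetenceEvaluation.fit`
returns a :class:`CompetenceResults` with a Table-style summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .mixedlm import CrossedLMM, CrossedLMMResults

logger = logging.getLogger(__name__)

__all__ = [
    "TrialTable",
    "preprocess_trials",
    "ContrastResult",
    "group_contrast",
    "effect_accuracy",
    "FitResult",
    "fit_mixed",
    "deviance_accuracy",
    "residual_accuracy",
    "RAReport",
    "CompetenceEvaluation",
    "CompetenceResults",
    "evaluate_all",
    "LRT_CRITICAL_05",
]

#: critical chi-squared value at p = .05, df = 1 (the DA significance bar)
LRT_CRITICAL_05: float = float(stats.chi2.ppf(0.95, df=1))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


@dataclass
class TrialTable:
    """Preprocessed trials with per-participant z-scored ratings."""

    frame: pd.DataFrame  # participant, list, position, word, rating, z_rating
    n_participants: int
    n_excluded_participants: int
    n_incomplete_dropped: int

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def words(self) -> List[str]:
        return sorted(self.frame["word"].unique())


def default_exclusion(meta_row: pd.Series) -> bool:
    """Exclude participants who are not native English speakers or not
    born in the USA."""
    return meta_row["native_language"] != "English" or meta_row["birthplace"] != "USA"


def preprocess_trials(
    trials: pd.DataFrame,
    metadata: pd.DataFrame,
    exclusion: Callable[[pd.Series], bool] = default_exclusion,
) -> TrialTable:
    """Apply participant exclusions, drop incomplete trials, z-score.

    Trials of excluded participants are removed first, then trials with
    a missing rating; the remaining ratings are z-scored within each
    participant (a participant with zero rating variance gets z = 0,
    with a warning).
    """
    required = {"participant", "word", "rating"}
    if not required <= set(trials.columns):
        raise ValueError(f"trials must have columns {sorted(required)}")
    excluded = {
        row["participant"] for _, row in metadata.iterrows() if exclusion(row)
    }
    kept = trials[~trials["participant"].isin(excluded)].copy()
    complete = kept["rating"].notna()
    n_incomplete = int((~complete).sum())
    kept = kept[complete].copy()
    bad = ~kept["rating"].astype(float).isin(range(1, 8))
    if bad.any():
        raise ValueError(f"{int(bad.sum())} ratings outside the 1-7 scale")

    def _z(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            logger.warning("participant with zero rating variance; z set to 0")
            return pd.Series(np.zeros(len(x)), index=x.index)
        return (x - x.mean()) / sd

    kept["z_rating"] = kept.groupby("participant")["rating"].transform(_z)
    return TrialTable(
        frame=kept.reset_index(drop=True),
        n_participants=kept["participant"].nunique(),
        n_excluded_participants=len(excluded),
        n_incomplete_dropped=n_incomplete,
    )


# ---------------------------------------------------------------------------
# Contrasts and effect accuracy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContrastResult:
    mean1: float
    mean2: float
    t: float
    p: float
    d: float
    n1: int
    n2: int


def group_contrast(values1: Sequence[float], values2: Sequence[float]) -> ContrastResult:
    """Pooled-variance two-sample t test and Cohen's d (pooled SD with
    Bessel-corrected group variances) for two groups of per-word values."""
    a = np.asarray(values1, dtype=float)
    b = np.asarray(values2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    pooled = np.sqrt(
        ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
        / (len(a) + len(b) - 2)
    )
    d = (a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
    return ContrastResult(
        float(a.mean()), float(b.mean()), float(t), float(p), float(d), len(a), len(b)
    )


def effect_accuracy(d_human: float, d_model: float) -> float:
    """Absolute difference in Cohen's d between humans and a model."""
    if not (np.isfinite(d_human) and np.isfinite(d_model)):
        raise ValueError("effect sizes must be finite")
    return abs(d_human - d_model)


# ---------------------------------------------------------------------------
# Mixed-model fits and deviance / residual accuracy
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """A mixed-model fit plus the word labels needed for per-word residuals."""

    result: CrossedLMMResults
    words: np.ndarray
    formula: str
    has_score: bool

    @property
    def deviance(self) -> float:
        return self.result.deviance

    @property
    def converged(self) -> bool:
        return self.result.converged

    def per_word_resid(self) -> pd.Series:
        """Mean conditional residual per word."""
        return pd.Series(self.result.resid).groupby(pd.Series(self.words)).mean()


def fit_mixed(
    trials: TrialTable, score: Optional[Mapping[str, float]] = None
) -> FitResult:
    """Fit the z-rating mixed model, optionally with a SLOR fixed effect.

    Random structure: crossed by-subject, by-word and by-order (within-
    list presentation position) intercepts; estimation is plain ML so
    deviances are comparable across nested fits.
    """
    df = trials.frame
    groups = {
        "subject": df["participant"].to_numpy(),
        "word": df["word"].to_numpy(),
        "order": df["position"].to_numpy(),
    }
    if score is not None:
        missing = set(df["word"]) - set(score)
        if missing:
            raise ValueError(f"{len(missing)} words lack scores (e.g. {sorted(missing)[:3]})")
        x = df["word"].map(score).to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(df)), x])
        names = ["Intercept", "slor"]
        formula = "z_rating ~ 1 + slor + (1|subject) + (1|word) + (1|order)"
    else:
        X = np.ones((len(df), 1))
        names = ["Intercept"]
        formula = "z_rating ~ 1 + (1|subject) + (1|word) + (1|order)"
    model = CrossedLMM(df["z_rating"].to_numpy(), X, groups, exog_names=names)
    res = model.fit()
    if not res.converged:
        logger.warning("mixed-model fit flagged as non-converged: %s", formula)
    return FitResult(res, df["word"].to_numpy(), formula, score is not None)


def deviance_accuracy(
    base: FitResult, target: FitResult, tol: float = 1e-4
) -> Tuple[float, float]:
    """DA = D_base - D_target with its likelihood-ratio p-value
    (chi-squared, df = 1: the fits differ by the single SLOR slope)."""
    if not (base.converged and target.converged):
        raise ValueError("refusing deviance comparison on non-converged fits")
    da = base.deviance - target.deviance
    if da < -tol:
        logger.warning(
            "negative deviance drop (%.3g): target fit may not have converged", da
        )
    p = float(stats.chi2.sf(max(da, 0.0), df=1))
    return float(da), p


@dataclass
class RAReport:
    """Residual-accuracy decomposition."""

    per_word: pd.Series  # word -> |eps_base| - |eps_target|
    total: float
    per_affix: pd.Series  # outer affix -> summed contribution
    per_kind: pd.Series  # structure kind -> mean over its affixes

    def __post_init__(self) -> None:
        assert np.isclose(self.total, self.per_word.sum())


def residual_accuracy(
    base: FitResult, target: FitResult, stimuli: pd.DataFrame
) -> RAReport:
    """Per-word reduction in absolute mean conditional residuals.

    ``stimuli`` must map each word to its outer affix and structure
    kind (columns word, outer, kind).  The per-kind figure averages the
    per-affix sums within each kind.
    """
    rb = base.per_word_resid()
    rt = target.per_word_resid()
    if set(rb.index) != set(rt.index):
        raise ValueError("base and target fits cover different word sets")
    delta = rb.abs() - rt.abs().reindex(rb.index)
    meta = stimuli.set_index("word")
    missing = set(delta.index) - set(meta.index)
    if missing:
        raise ValueError(f"{len(missing)} fitted words missing from stimulus table")
    outer = meta["outer"].reindex(delta.index)
    kind = meta["kind"].reindex(delta.index)
    per_affix = delta.groupby(outer).sum()
    affix_kind = kind.groupby(outer).first()
    per_kind = per_affix.groupby(affix_kind).mean()
    return RAReport(
        per_word=delta,
        total=float(delta.sum()),
        per_affix=per_affix,
        per_kind=per_kind,
    )


# ---------------------------------------------------------------------------
# Full evaluation
# ---------------------------------------------------------------------------


@dataclass
class CompetenceResults:
    """Per-model accuracy metrics against the human judgments."""

    human: ContrastResult  # contrast over per-word mean z-ratings
    human_raw_means: Tuple[float, float]  # raw 1-7 scale, (linear, nested)
    table: pd.DataFrame  # one row per model with all metric columns
    ra: Dict[str, RAReport]
    pairwise_da: pd.DataFrame
    baseline_deviance: float

    def summary(self) -> str:
        lines = [
            "Model evaluation against acceptability judgments",
            "=" * 78,
            f"Human: linear {self.human_raw_means[0]:.2f}, "
            f"nested {self.human_raw_means[1]:.2f} (raw scale); "
            f"t = {self.human.t:.2f}, p = {self.human.p:.3g}, d = {self.human.d:.2f}",
            "-" * 78,
            f"{'Model':<10}{'Linear':>9}{'Nested':>9}{'t':>8}{'p':>10}"
            f"{'d':>7}{'EA':>7}{'DA':>8}{'DA p':>10}{'RA':>8}",
        ]
        for _, r in self.table.iterrows():
            lines.append(
                f"{r['model']:<10}{r['slor_linear']:>9.2f}{r['slor_nested']:>9.2f}"
                f"{r['t']:>8.2f}{r['p']:>10.3g}{r['d']:>7.2f}{r['ea']:>7.2f}"
                f"{r['da']:>8.2f}{r['da_p']:>10.3g}{r['ra']:>8.3f}"
            )
        lines.append("-" * 78)
        lines.append(
            f"Baseline deviance {self.baseline_deviance:.2f}; DA significant "
            f"above the chi-squared(1) 0.95 critical value {LRT_CRITICAL_05:.2f}"
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "human": {
                "raw_mean_linear": self.human_raw_means[0],
                "raw_mean_nested": self.human_raw_means[1],
                "t": self.human.t,
                "p": self.human.p,
                "d": self.human.d,
            },
            "models": self.table.to_dict(orient="records"),
            "pairwise_da": self.pairwise_da.to_dict(orient="records"),
            "baseline_deviance": self.baseline_deviance,
            "ra": {
                m: {
                    "total": rep.total,
                    "per_kind": rep.per_kind.to_dict(),
                    "per_affix": rep.per_affix.to_dict(),
                }
                for m, rep in self.ra.items()
            },
        }


class CompetenceEvaluation:
    """Model object tying trials, SLOR score table and stimulus metadata.

    Parameters
    ----------
    trials : TrialTable
        Preprocessed judgments.
    scores : DataFrame
        Long score table with columns word, model, slor (and optionally
        ok; flagged rows are dropped with a logged count).
    stimuli : DataFrame
        Stimulus metadata with columns word, kind, outer.
    """

    def __init__(self, trials: TrialTable, scores: pd.DataFrame, stimuli: pd.DataFrame):
        self.trials = trials
        self.scores = scores
        self.stimuli = stimuli
        need = {"word", "model", "slor"}
        if not need <= set(scores.columns):
            raise ValueError(f"scores must have columns {sorted(need)}")
        if not {"word", "kind", "outer"} <= set(stimuli.columns):
            raise ValueError("stimuli must have columns word, kind, outer")

    def fit(self) -> CompetenceResults:
        trials = self.trials
        stim = self.stimuli
        words = trials.words
        kind_of = stim.set_index("word")["kind"]
        lin = [w for w in words if kind_of.get(w) == "linear"]
        nst = [w for w in words if kind_of.get(w) == "nested"]

        frame = trials.frame
        word_z = frame.groupby("word")["z_rating"].mean()
        word_raw = frame.groupby("word")["rating"].mean()
        human = group_contrast(word_z[lin], word_z[nst])
        human_raw = (float(word_raw[lin].mean()), float(word_raw[nst].mean()))

        base = fit_mixed(trials, None)
        rows = []
        ra_reports: Dict[str, RAReport] = {}
        target_dev: Dict[str, float] = {}
        for name, grp in self.scores.groupby("model", sort=False):
            ok = grp["ok"] if "ok" in grp.columns else pd.Series(True, index=grp.index)
            dropped = int((~ok).sum())
            if dropped:
                logger.warning("%s: dropping %d unscorable words", name, dropped)
            smap = dict(zip(grp.loc[ok, "word"], grp.loc[ok, "slor"]))
            scored_words = [w for w in words if w in smap]
            if len(scored_words) < len(words):
                sub = TrialTable(
                    frame[frame["word"].isin(smap)].reset_index(drop=True),
                    trials.n_participants,
                    trials.n_excluded_participants,
                    trials.n_incomplete_dropped,
                )
                this_base = fit_mixed(sub, None)
                this_trials = sub
            else:
                this_base, this_trials = base, trials
            target = fit_mixed(this_trials, smap)
            da, da_p = deviance_accuracy(this_base, target)
            target_dev[name] = target.deviance
            contrast = group_contrast(
                [smap[w] for w in lin if w in smap],
                [smap[w] for w in nst if w in smap],
            )
            ra = residual_accuracy(this_base, target, stim)
            ra_reports[name] = ra
            rows.append(
                {
                    "model": name,
                    "slor_linear": contrast.mean1,
                    "slor_nested": contrast.mean2,
                    "t": contrast.t,
                    "p": contrast.p,
                    "d": contrast.d,
                    "ea": effect_accuracy(human.d, contrast.d),
                    "da": da,
                    "da_p": da_p,
                    "ra": ra.total,
                }
            )
        names = list(target_dev)
        pair_rows = []
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                dd = target_dev[b] - target_dev[a]
                better, worse = (a, b) if dd > 0 else (b, a)
                pair_rows.append(
                    {
                        "better": better,
                        "worse": worse,
                        "deviance_diff": abs(dd),
                        # chi-squared(1) reference; the pair is not
                        # strictly nested, so read this as heuristic
                        "p": float(stats.chi2.sf(abs(dd), df=1)),
                    }
                )
        return CompetenceResults(
            human=human,
            human_raw_means=human_raw,
            table=pd.DataFrame(rows),
            ra=ra_reports,
            pairwise_da=pd.DataFrame(pair_rows),
            baseline_deviance=base.deviance,
        )


def evaluate_all(
    scores: pd.DataFrame, trials: TrialTable, stimuli: pd.DataFrame
) -> CompetenceResults:
    """Functional form of :class:`CompetenceEvaluation`."""
    return CompetenceEvaluation(trials, scores, stimuli).fit()
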