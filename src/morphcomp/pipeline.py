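"""End-to-end pipeline configuration and artifact plumbing.

A :class:`PipelineConfig` carries every tunable of the study design —
structure-template thresholds, stem frequency cutoff, per-kind quota,
list count, smoothing alpha, SLOR length convention, simulation
settings and seeds — with the standard values pre-filled.  Each
pipeline stage writes its artifact together with a small manifest
(config hash, seed, package version) so downstream stages can refuse
inputs produced under a different configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Dict, Optional, Tuple

import pandas as pd
import yaml

from . import __version__
from .evaluation import TrialTable, evaluate_all, preprocess_trials
from .lexicon import Lexicon, read_lexicon, write_lexicon
from .models import SmoothingConfig, load_models, save_models, train_all_models
from .scoring import score_all
from .stimuli import (
    PRODUCTIVE_PREFIXES,
    PRODUCTIVE_SUFFIXES,
    StimulusWord,
    build_lists,
    extract_templates,
    generate_stimuli,
    stimuli_to_frame,
)
from .synth import (
    JudgmentSimConfig,
    default_grammar,
    sample_lexicon,
    simulate_judgments,
    simulate_participants,
)
from .trees import parse_tree_string

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConfigError", "Pipeline"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    # lexicon generation
    n_types: int = 8000
    max_depth: int = 3
    f_max: int = 1_000_000
    flag_rate: float = 0.3
    # stimulus construction
    linear_type_freq: int = 5
    nested_type_freq: int = 2
    stem_token_freq: int = 20
    n_per_kind: int = 300
    n_lists: int = 6
    productive_suffixes: Tuple[str, ...] = tuple(sorted(PRODUCTIVE_SUFFIXES))
    productive_prefixes: Tuple[str, ...] = tuple(sorted(PRODUCTIVE_PREFIXES))
    blocklist_path: Optional[str] = None
    # models
    alpha: float = 0.1
    length_convention: str = "morphemes"
    # judgment simulation
    n_participants: int = 180
    n_non_native: int = 5
    n_foreign_born: int = 9
    beta: float = 0.5
    sd_subject: float = 0.3
    sd_word: float = 0.2
    sd_order: float = 0.1
    sd_resid: float = 1.0
    n_incomplete: int = 0
    # seeds
    seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "linear_type_freq",
            "nested_type_freq",
            "n_per_kind",
            "n_lists",
            "n_types",
            "max_depth",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.stem_token_freq < 0 or self.alpha < 0:
            raise ConfigError("stem_token_freq and alpha must be non-negative")
        if self.length_convention not in ("morphemes", "model_units"):
            raise ConfigError(f"bad length_convention {self.length_convention!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def sim_config(self, seed_offset: int = 0) -> JudgmentSimConfig:
        return JudgmentSimConfig(
            n_participants=self.n_participants,
            n_lists=self.n_lists,
            beta=self.beta,
            sd_subject=self.sd_subject,
            sd_word=self.sd_word,
            sd_order=self.sd_order,
            sd_resid=self.sd_resid,
            n_incomplete=self.n_incomplete,
            seed=self.seed + seed_offset,
        )


class Pipeline:
    """Stage runner writing artifacts plus manifests under ``out_dir``."""

    def __init__(self, config: PipelineConfig, out_dir):
        self.config = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)

    # -- manifests ----------------------------------------------------------

    def _write_manifest(self, artifact: Path, stage: str) -> None:
        manifest = {
            "stage": stage,
            "config_hash": self.config.config_hash,
            "seed": self.config.seed,
            "version": __version__,
        }
        artifact.with_suffix(artifact.suffix + ".manifest.json").write_text(
            json.dumps(manifest, indent=1), encoding="utf-8"
        )

    def _check_manifest(self, artifact: Path) -> None:
        mpath = artifact.with_suffix(artifact.suffix + ".manifest.json")
        if not mpath.exists():
            raise FileNotFoundError(
                f"missing manifest for {artifact}; run the producing stage first"
            )
        manifest = json.loads(mpath.read_text(encoding="utf-8"))
        if manifest["config_hash"] != self.config.config_hash:
            raise ConfigError(
                f"{artifact} was produced under config {manifest['config_hash']}, "
                f"current config is {self.config.config_hash}: refusing mixed inputs"
            )

    def _need(self, name: str) -> Path:
        p = self.out / name
        if not p.exists():
            raise FileNotFoundError(
                f"missing upstream artifact {p}; run the producing stage first"
            )
        self._check_manifest(p)
        return p

    # -- stages -------------------------------------------------------------

    def gen_lexicon(self) -> Path:
        cfg = self.config
        lex = sample_lexicon(
            default_grammar(),
            n_types=cfg.n_types,
            max_depth=cfg.max_depth,
            seed=cfg.seed,
            f_max=cfg.f_max,
            flag_rate=cfg.flag_rate,
        )
        path = self.out / "lexicon.tsv"
        write_lexicon(lex, path)
        self._write_manifest(path, "gen-lexicon")
        logger.info("wrote %s (%d entries)", path, len(lex))
        return path

    def _load_lexicon(self) -> Lexicon:
        return read_lexicon(self._need("lexicon.tsv"))

    def _load_blocklist(self) -> frozenset:
        if not self.config.blocklist_path:
            return frozenset()
        text = Path(self.config.blocklist_path).read_text(encoding="utf-8")
        return frozenset(w.strip() for w in text.splitlines() if w.strip())

    def gen_stimuli(self) -> Path:
        cfg = self.config
        lex = self._load_lexicon()
        linear = extract_templates(
            lex, "linear", cfg.linear_type_freq, frozenset(cfg.productive_suffixes)
        )
        nested = extract_templates(
            lex, "nested", cfg.nested_type_freq, frozenset(cfg.productive_prefixes)
        )
        stimuli = generate_stimuli(
            lex,
            linear,
            nested,
            n_per_kind=cfg.n_per_kind,
            blocklist=self._load_blocklist(),
            seed=cfg.seed,
            min_token_freq=cfg.stem_token_freq,
        )
        path = self.out / "stimuli.tsv"
        stimuli_to_frame(stimuli).to_csv(path, sep="\t", index=False)
        self._write_manifest(path, "gen-stimuli")
        return path

    def _load_stimuli(self) -> list[StimulusWord]:
        frame = pd.read_csv(self._need("stimuli.tsv"), sep="\t")
        out = []
        for _, r in frame.iterrows():
            tree = parse_tree_string(r["tree"])
            out.append(
                StimulusWord(
                    surface=r["word"],
                    morphemes=tree.leaves(),
                    tree=tree,
                    kind=r["kind"],
                    template_id=r["template_id"],
                    root=r["root"],
                    stem_surface=r["stem"],
                )
            )
        return out

    def build_lists(self) -> Path:
        design = build_lists(
            self._load_stimuli(), n_lists=self.config.n_lists, seed=self.config.seed
        )
        path = self.out / "lists.csv"
        design.to_csv(path, index=False)
        self._write_manifest(path, "build-lists")
        return path

    def train(self) -> Path:
        lex = self._load_lexicon()
        models, unigram = train_all_models(
            lex, SmoothingConfig(alpha=self.config.alpha)
        )
        path = self.out / "models.json"
        save_models(models, unigram, path)
        self._write_manifest(path, "train")
        return path

    def score(self) -> Path:
        models, unigram = load_models(self._need("models.json"))
        stimuli = self._load_stimuli()
        table = score_all(
            models, unigram, stimuli, length_convention=self.config.length_convention
        )
        path = self.out / "scores.tsv"
        table.to_csv(path, sep="\t", index=False)
        self._write_manifest(path, "score")
        return path

    def simulate_judgments(self, generating_model: str = "pcfg") -> Path:
        cfg = self.config
        scores = pd.read_csv(self._need("scores.tsv"), sep="\t")
        grp = scores[(scores["model"] == generating_model) & scores["ok"]]
        smap = dict(zip(grp["word"], grp["slor"]))
        design = pd.read_csv(self._need("lists.csv"))
        meta = simulate_participants(
            cfg.n_participants,
            n_non_native=cfg.n_non_native,
            n_foreign_born=cfg.n_foreign_born,
            seed=cfg.seed + 1,
        )
        flagged = meta.loc[
            (meta["native_language"] != "English") | (meta["birthplace"] != "USA"),
            "participant",
        ]
        ok_participants = sorted(set(meta["participant"]) - set(flagged))
        trials = simulate_judgments(
            sorted(smap),
            smap,
            cfg.sim_config(seed_offset=2),
            design=design,
            incomplete_pool=ok_participants,
        )
        tpath = self.out / "trials.csv"
        mpath = self.out / "participants.csv"
        trials.to_csv(tpath, index=False)
        meta.to_csv(mpath, index=False)
        self._write_manifest(tpath, "simulate-judgments")
        self._write_manifest(mpath, "simulate-judgments")
        return tpath

    def evaluate(self) -> Path:
        trials_raw = pd.read_csv(self._need("trials.csv"))
        meta = pd.read_csv(self._need("participants.csv"))
        scores = pd.read_csv(self._need("scores.tsv"), sep="\t")
        stim_frame = pd.read_csv(self._need("stimuli.tsv"), sep="\t")
        trials = preprocess_trials(trials_raw, meta)
        results = evaluate_all(scores, trials, stim_frame)
        path = self.out / "report.json"
        payload = results.to_dict()
        payload["n_trials"] = len(trials)
        payload["n_participants"] = trials.n_participants
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
        (self.out / "summary.txt").write_text(results.summary() + "\n", encoding="utf-8")
        self._write_manifest(path, "evaluate")
        return path

    def report(self) -> Path:
        payload = json.loads(self._need("report.json").read_text(encoding="utf-8"))
        table = pd.DataFrame(payload["models"])
        path = self.out / "accuracy_table.tsv"
        table.to_csv(path, sep="\t", index=False)
        ra_rows = []
        for model, rep in payload["ra"].items():
            for kind, v in rep["per_kind"].items():
                ra_rows.append({"model": model, "kind": kind, "ra": v})
        pd.DataFrame(ra_rows).to_csv(self.out / "ra_by_kind.tsv", sep="\t", index=False)
        self._write_manifest(path, "report")
        return path
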