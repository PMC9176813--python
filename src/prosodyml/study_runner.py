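"""End-to-end study drivers: per-language and combined diagnostic models,
permutation significance, and report export.

Model 1 classifies diagnosis (ASD vs TD) separately per language; Model 2 on
the combined corpus (language is metadata only, never a feature).  A
supplementary probe classifies *language* from rhythm features with both
diagnostic groups pooled, quantifying how strongly cross-linguistic timing
differences register in the rhythm representation.

Significance uses a permutation scheme: the observed statistic is the
median AUC over the configured repetitions; each permutation shuffles the
labels once and runs a single nested-CV repetition, giving an exchangeable
null AUC sample.  p = (b + 1) / (n_perm + 1) with b = #{null >= observed}.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import asdict, dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .corpus_io import Group, Language, SpeakerRecord
from .classifier_core import (
    ClassificationSummary,
    ClassifierError,
    CVConfig,
    DesignMatrix,
    repeated_nested_cv,
    single_repetition,
    summarize,
)
from .intonation_features import F0Config, intonation_vector
from .rhythm_features import RhythmConfig, rhythm_vector

__all__ = [
    "FeatureSet",
    "PermutationResult",
    "StudyCell",
    "StudyReport",
    "StudyConfig",
    "extract_features",
    "permutation_test",
    "run_model1",
    "run_model2",
    "run_language_probe",
    "run_study",
    "export_report",
]


@dataclass(frozen=True)
class StudyConfig:
    """Bundle of all pipeline configurations plus study-level settings."""

    rhythm: RhythmConfig = field(default_factory=RhythmConfig)
    f0: F0Config = field(default_factory=F0Config)
    cv: CVConfig = field(default_factory=CVConfig)
    n_perm: int = 200    # desk scale; 5001 for full-scale runs
    seed: int = 0


@dataclass
class FeatureSet:
    """Per-speaker feature matrices for one corpus."""

    speaker_ids: list[str]
    groups: list[Group]
    languages: list[Language]
    rhythm: Optional[np.ndarray] = None       # n_speakers x 8640
    intonation: Optional[np.ndarray] = None   # n_speakers x 400

    @staticmethod
    def from_corpus(corpus: Sequence[SpeakerRecord],
                    rhythm_cfg: Optional[RhythmConfig] = None,
                    f0_cfg: Optional[F0Config] = None,
                    which: tuple[str, ...] = ("rhythm", "intonation")) -> "FeatureSet":
        rhythm_cfg = rhythm_cfg or RhythmConfig()
        f0_cfg = f0_cfg or F0Config()
        r_rows, i_rows = [], []
        for spk in corpus:
            if "rhythm" in which:
                r_rows.append(rhythm_vector(spk, rhythm_cfg).values)
            if "intonation" in which:
                i_rows.append(intonation_vector(spk, f0_cfg).values)
        return FeatureSet(
            speaker_ids=[s.speaker_id for s in corpus],
            groups=[s.group for s in corpus],
            languages=[s.language for s in corpus],
            rhythm=np.vstack(r_rows) if r_rows else None,
            intonation=np.vstack(i_rows) if i_rows else None,
        )

    def matrix(self, feature_class: str) -> np.ndarray:
        m = self.rhythm if feature_class == "rhythm" else self.intonation
        if m is None:
            raise ClassifierError(f"{feature_class} features were not extracted")
        return m

    def design_matrix(self, feature_class: str, label: str = "group") -> DesignMatrix:
        """Design matrix with y = 1 for ASD (label='group') or EN (label='language')."""
        if label == "group":
            y = np.array([1 if g is Group.ASD else 0 for g in self.groups])
            positive = Group.ASD.value
        elif label == "language":
            y = np.array([1 if l is Language.EN else 0 for l in self.languages])
            positive = Language.EN.value
        else:
            raise ClassifierError(f"unknown label {label!r}")
        return DesignMatrix(X=self.matrix(feature_class), y=y,
                            speaker_ids=tuple(self.speaker_ids),
                            positive_label=positive)

    def to_frame(self, feature_class: str, prefix: str) -> pd.DataFrame:
        m = self.matrix(feature_class)
        cols = [f"{prefix}{i + 1:04d}" for i in range(m.shape[1])]
        df = pd.DataFrame(m, columns=cols)
        df.insert(0, "language", [l.value for l in self.languages])
        df.insert(0, "group", [g.value for g in self.groups])
        df.insert(0, "speaker_id", self.speaker_ids)
        return df

    @staticmethod
    def concatenate(a: "FeatureSet", b: "FeatureSet") -> "FeatureSet":
        def cat(x, y):
            if x is None or y is None:
                return None
            return np.vstack([x, y])
        return FeatureSet(
            speaker_ids=a.speaker_ids + b.speaker_ids,
            groups=a.groups + b.groups,
            languages=a.languages + b.languages,
            rhythm=cat(a.rhythm, b.rhythm),
            intonation=cat(a.intonation, b.intonation),
        )


def extract_features(corpus: Sequence[SpeakerRecord],
                     cfg: Optional[StudyConfig] = None,
                     which: tuple[str, ...] = ("rhythm", "intonation")) -> FeatureSet:
    cfg = cfg or StudyConfig()
    return FeatureSet.from_corpus(corpus, cfg.rhythm, cfg.f0, which)


# ---------------------------------------------------------------------------
# Permutation significance
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Null AUC distribution and permutation p-value for one classification."""

    observed_median_auc: float
    null_aucs: np.ndarray
    n_perm: int
    p_value: float


def permutation_test(dm: DesignMatrix, cfg: CVConfig, n_perm: int, seed: int,
                     observed: Optional[ClassificationSummary] = None) -> PermutationResult:
    """Label-permutation significance of the median AUC.

    Each of the ``n_perm`` permutations shuffles y uniformly (seeded) and
    runs one nested-CV repetition; p = (b + 1)/(n_perm + 1) where b counts
    null AUCs >= the observed median AUC.
    """
    if n_perm < 19:
        raise ClassifierError("n_perm must be at least 19")
    if observed is None:
        observed = summarize(repeated_nested_cv(dm, cfg), dm.y)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 1717]))
    null_aucs = np.empty(n_perm)
    for j in range(n_perm):
        yp = rng.permutation(dm.y)
        dm_p = DesignMatrix(X=dm.X, y=yp, speaker_ids=dm.speaker_ids,
                            positive_label=dm.positive_label)
        cfg_p = replace(cfg, repeats=1, seed=int(rng.integers(2**31)))
        null_aucs[j] = single_repetition(dm_p, cfg_p, rep=0).auc
    b = int(np.sum(null_aucs >= observed.median_auc))
    return PermutationResult(
        observed_median_auc=observed.median_auc, null_aucs=null_aucs,
        n_perm=n_perm, p_value=(b + 1) / (n_perm + 1),
    )


# ---------------------------------------------------------------------------
# Study cells
# ---------------------------------------------------------------------------

@dataclass
class StudyCell:
    """One (model, language-set, feature-class) classification result."""

    model: str           # "model1" | "model2" | "probe"
    language_set: str    # "EN" | "YUE" | "combined"
    feature_class: str   # "rhythm" | "intonation"
    summary: ClassificationSummary
    permutation: PermutationResult
    n_speakers: int


@dataclass
class StudyReport:
    """All study cells plus the configuration needed to reproduce them."""

    cells: list[StudyCell]
    config: StudyConfig
    seed: int


def _check_groups(corpus_features: FeatureSet, where: str) -> None:
    groups = set(corpus_features.groups)
    if groups != {Group.ASD, Group.TD}:
        raise ClassifierError(f"{where}: both diagnostic groups must be present")


def _cell_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([int(seed) % (2**31), tag]).generate_state(1)[0] % (2**31))


def _run_cell(features: FeatureSet, feature_class: str, label: str, model: str,
              language_set: str, cfg: StudyConfig, tag: int) -> StudyCell:
    dm = features.design_matrix(feature_class, label=label)
    cell_seed = _cell_seed(cfg.seed, tag)
    cv = replace(cfg.cv, seed=cell_seed)
    obs = summarize(repeated_nested_cv(dm, cv), dm.y)
    perm = permutation_test(dm, cv, cfg.n_perm, seed=cell_seed + 1, observed=obs)
    return StudyCell(model=model, language_set=language_set,
                     feature_class=feature_class, summary=obs,
                     permutation=perm, n_speakers=dm.y.size)


def run_model1(features_en: FeatureSet, features_yue: FeatureSet,
               cfg: Optional[StudyConfig] = None) -> list[StudyCell]:
    """Per-language diagnosis classification: 4 cells (EN/YUE x rhythm/intonation)."""
    cfg = cfg or StudyConfig()
    cells = []
    for features in (features_en, features_yue):
        lang = features.languages[0].value
        _check_groups(features, f"Model 1 ({lang})")
        # seed tag follows the corpus's own language so that swapping the
        # two arguments permutes cells without changing any cell's values
        ltag = 0 if lang == "EN" else 1
        for ftag, feature_class in enumerate(("rhythm", "intonation")):
            cells.append(
                _run_cell(features, feature_class, "group", "model1", lang,
                          cfg, tag=100 + 10 * ltag + ftag)
            )
    return cells


def run_model2(features_en: FeatureSet, features_yue: FeatureSet,
               cfg: Optional[StudyConfig] = None) -> list[StudyCell]:
    """Combined-corpus diagnosis classification: 2 cells (rhythm/intonation).

    Language is carried as metadata only and never enters the feature matrix.
    """
    cfg = cfg or StudyConfig()
    combined = FeatureSet.concatenate(features_en, features_yue)
    _check_groups(combined, "Model 2")
    return [
        _run_cell(combined, feature_class, "group", "model2", "combined",
                  cfg, tag=200 + ftag)
        for ftag, feature_class in enumerate(("rhythm", "intonation"))
    ]


def run_language_probe(features_en: FeatureSet, features_yue: FeatureSet,
                       cfg: Optional[StudyConfig] = None) -> StudyCell:
    """Classify language (EN vs YUE) from rhythm features, groups pooled."""
    cfg = cfg or StudyConfig()
    combined = FeatureSet.concatenate(features_en, features_yue)
    return _run_cell(combined, "rhythm", "language", "probe", "combined",
                     cfg, tag=300)


def run_study(corpus_en: Sequence[SpeakerRecord], corpus_yue: Sequence[SpeakerRecord],
              cfg: Optional[StudyConfig] = None, probe: bool = True) -> StudyReport:
    """Extract features once and run Models 1, 2 and (optionally) the probe."""
    cfg = cfg or StudyConfig()
    features_en = extract_features(corpus_en, cfg)
    features_yue = extract_features(corpus_yue, cfg)
    cells = run_model1(features_en, features_yue, cfg)
    cells += run_model2(features_en, features_yue, cfg)
    if probe:
        cells.append(run_language_probe(features_en, features_yue, cfg))
    return StudyReport(cells=cells, config=cfg, seed=cfg.seed)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_report(report: StudyReport, out_dir: str | pathlib.Path) -> list[pathlib.Path]:
    """Write summary table, AUC distributions, confusion matrices and config.

    ``summary.csv`` mirrors the headline table layout (model, language,
    features, median AUC, ACC, SENS, SPEC, p); per-cell CSVs carry the
    observed and null AUC distributions (boxplot data) and the aggregated
    confusion counts; ``config.json`` suffices to reproduce the run.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    rows = []
    for cell in report.cells:
        rows.append({
            "model": cell.model,
            "language": cell.language_set,
            "features": cell.feature_class,
            "median_auc": cell.summary.median_auc,
            "acc": cell.summary.acc,
            "sens": cell.summary.sens,
            "spec": cell.summary.spec,
            "p_value": cell.permutation.p_value,
            "n_speakers": cell.n_speakers,
        })
    summary_path = out / "summary.csv"
    pd.DataFrame(rows).to_csv(summary_path, index=False)
    written.append(summary_path)

    for cell in report.cells:
        stem = f"{cell.model}_{cell.language_set}_{cell.feature_class}"
        auc_path = out / f"auc_{stem}.csv"
        obs = cell.summary.auc_distribution
        null = cell.permutation.null_aucs
        pd.DataFrame({
            "kind": ["observed"] * obs.size + ["null"] * null.size,
            "auc": np.concatenate([obs, null]),
        }).to_csv(auc_path, index=False)
        written.append(auc_path)

        cm_path = out / f"confusion_{stem}.csv"
        cm = cell.summary.aggregated_confusion
        pd.DataFrame(
            cm, index=["true_neg_class", "true_pos_class"],
            columns=["pred_neg_class", "pred_pos_class"],
        ).to_csv(cm_path)
        written.append(cm_path)

    cfg_path = out / "config.json"
    cfg_path.write_text(json.dumps({
        "seed": report.seed,
        "rhythm": asdict(report.config.rhythm),
        "f0": asdict(report.config.f0),
        "cv": asdict(report.config.cv),
        "n_perm": report.config.n_perm,
    }, indent=2, default=str))
    written.append(cfg_path)
    return written
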