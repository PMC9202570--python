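"""Study harness: cross-validated scenarios, F1 metrics, abstention accounting.

Four scenarios are compared, crossing the training population with the
label mode:

* 1a — train an ICD-O-3 (site, histology, behavior) multitask classifier
  on reports from all age groups, then recode predictions to ICCC;
* 1b — the same, trained on childhood (age 0-19) reports only;
* 2a — train a direct ICCC subgroup classifier on childhood reports;
* 2b — direct ICCC, with the training set augmented by age-20-39 reports
  of the eight CCDI pediatric-type subgroups.

Evaluation is always on childhood reports, under stratified k-fold
cross-validation (default k=10). Metrics are per-class F1, micro-F1
(case-weighted, pooled over the full class list) and macro-F1 (the
unweighted mean over every class present in the evaluation truth set,
including classes never predicted). With a confidence model, abstained
cases are removed from the evaluation pool before F1 is computed, and
per-class retention and abstention rates are reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score

from .confidence import CalibrationSample, ConfidenceModel, confidence_score
from .recode import (
    CCDI_AGE_MAX,
    CCDI_AGE_MIN,
    CCDI_SUBGROUPS,
    ICDO3Code,
    RecodeTable,
    fixture_table,
    recode,
)
from .textcnn import CNNConfig, TrainedClassifier, train

__all__ = [
    "ScenarioSpec",
    "FoldPlan",
    "UQConfig",
    "MetricsReport",
    "stratified_folds",
    "f1_scores",
    "abstention_rate",
    "run_scenario",
    "compare_reports",
]

logger = logging.getLogger(__name__)

_SCENARIOS = {
    "1a": ("all-ages", "icdo3-then-recode"),
    "1b": ("childhood-only", "icdo3-then-recode"),
    "2a": ("childhood-only", "direct-iccc"),
    "2b": ("childhood+ccdi", "direct-iccc"),
}

ICDO3_TASKS = ("site", "histology", "behavior")
CHILDHOOD_AGE_MAX = 19


@dataclass(frozen=True)
class ScenarioSpec:
    """One of the four study scenarios."""

    scenario_id: str
    training_population: str
    label_mode: str

    def __post_init__(self) -> None:
        expected = _SCENARIOS.get(self.scenario_id)
        if expected is None:
            raise ValueError(f"unknown scenario {self.scenario_id!r}")
        if (self.training_population, self.label_mode) != expected:
            raise ValueError(
                f"scenario {self.scenario_id} requires "
                f"population={expected[0]!r}, label_mode={expected[1]!r}"
            )

    @classmethod
    def from_id(cls, scenario_id: str) -> "ScenarioSpec":
        population, mode = _SCENARIOS[scenario_id]
        return cls(scenario_id, population, mode)


@dataclass(frozen=True)
class FoldPlan:
    """Deterministic stratified partition of records into k folds."""

    k: int
    assignments: np.ndarray  # record index -> fold index
    stratify_on: str
    seed: int


def stratified_folds(
    labels: Sequence[str], k: int = 10, seed: int = 0,
    stratify_on: str = "iccc_subgroup",
) -> FoldPlan:
    """Stratified k-fold assignment tolerant of ultra-rare classes.

    Each class's members are shuffled and dealt onto folds by a single
    rotating pointer shared across classes, so per-class counts per fold
    are within +/-1 of proportionality and overall fold sizes differ by
    at most 1. Classes with fewer than k members are kept (some folds
    simply lack them), never dropped.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    assignments = np.full(len(labels), -1, dtype=int)
    pointer = 0
    for cls_label in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls_label)
        rng.shuffle(idx)
        for i in idx:
            assignments[i] = pointer % k
            pointer += 1
    return FoldPlan(k, assignments, stratify_on, seed)


def f1_scores(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_list: Sequence[str],
) -> tuple[dict[str, float], float, float]:
    """Per-class, micro- and macro-averaged F1 over a fixed class list.

    Per-class F1 is 2PR/(P+R), zero when P+R = 0; micro pools TP/FP/FN
    over the class list; macro is the unweighted mean of per-class F1.
    """
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors differ in length")
    class_list = list(class_list)
    if len(true_labels) == 0:
        return {c: 0.0 for c in class_list}, 0.0, 0.0
    per = f1_score(
        true_labels, predicted_labels, labels=class_list, average=None,
        zero_division=0,
    )
    micro = f1_score(
        true_labels, predicted_labels, labels=class_list, average="micro",
        zero_division=0,
    )
    macro = f1_score(
        true_labels, predicted_labels, labels=class_list, average="macro",
        zero_division=0,
    )
    return (
        {c: float(v) for c, v in zip(class_list, per)},
        float(micro),
        float(macro),
    )


def abstention_rate(n_cases: int, n_retained: int) -> float:
    """Fraction of cases abstained: (n_cases - n_retained) / n_cases."""
    if n_cases <= 0:
        raise ValueError("n_cases must be positive")
    if not 0 <= n_retained <= n_cases:
        raise ValueError("n_retained must lie in [0, n_cases]")
    return (n_cases - n_retained) / n_cases


@dataclass(frozen=True)
class UQConfig:
    """Abstention settings for a scenario run."""

    tau: float = 0.0
    threshold: float = 0.9
    score_mode: str = "bayes"


@dataclass
class MetricsReport:
    """Aggregated cross-validated metrics for one scenario."""

    scenario_id: str
    class_list: list[str]
    per_class_f1: dict[str, float]
    micro_f1: float
    macro_f1: float
    n_cases: dict[str, int]
    n_retained: dict[str, int]
    abstention_rate_overall: float
    abstention_rate_per_class: dict[str, float]
    # same predictions scored without removing abstained cases
    micro_f1_all: float
    macro_f1_all: float
    train_sizes: list[int] = field(default_factory=list)

    @property
    def total_cases(self) -> int:
        return sum(self.n_cases.values())

    @property
    def total_retained(self) -> int:
        return sum(self.n_retained.values())

    def to_dict(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "class_list": self.class_list,
            "per_class_f1": self.per_class_f1,
            "micro_f1": self.micro_f1,
            "macro_f1": self.macro_f1,
            "n_cases": self.n_cases,
            "n_retained": self.n_retained,
            "abstention_rate_overall": self.abstention_rate_overall,
            "abstention_rate_per_class": self.abstention_rate_per_class,
            "micro_f1_all": self.micro_f1_all,
            "macro_f1_all": self.macro_f1_all,
            "train_sizes": self.train_sizes,
        }


def _is_ccdi_eligible(subgroups: pd.Series, ages: pd.Series) -> pd.Series:
    return subgroups.isin(CCDI_SUBGROUPS) & ages.between(
        CCDI_AGE_MIN, CCDI_AGE_MAX
    )


def _population_mask(
    population: str, childhood: pd.Series, ccdi: pd.Series
) -> pd.Series:
    if population == "all-ages":
        return pd.Series(True, index=childhood.index)
    if population == "childhood-only":
        return childhood
    if population == "childhood+ccdi":
        return childhood | ccdi
    raise ValueError(f"unknown training population {population!r}")


def _predict_subgroups(
    clf: TrainedClassifier,
    texts: Sequence[str],
    label_mode: str,
    table: RecodeTable,
) -> tuple[list[str], np.ndarray]:
    """Predicted ICCC subgroups plus per-case softmax summary scores.

    For the direct model the score is the max subgroup probability; for
    the recode model it is the product of the per-task max probabilities
    (joint confidence in the predicted ICD-O-3 triple).
    """
    probas = clf.predict_proba_batch(texts)
    if label_mode == "direct-iccc":
        probs = probas[0]
        idx = probs.argmax(axis=1)
        labels = [clf.tasks[0].label_space[i] for i in idx]
        return labels, probs.max(axis=1)
    per_task_labels = []
    score = np.ones(len(texts))
    for task, probs in zip(clf.tasks, probas):
        idx = probs.argmax(axis=1)
        per_task_labels.append([task.label_space[i] for i in idx])
        score *= probs.max(axis=1)
    sites, hists, behaviors = per_task_labels
    labels = [
        recode(ICDO3Code(s, int(h), int(b)), table)
        for s, h, b in zip(sites, hists, behaviors)
    ]
    return labels, score


def run_scenario(
    spec: ScenarioSpec | str,
    corpus: pd.DataFrame,
    cnn_config: CNNConfig | None = None,
    uq_config: UQConfig | None = None,
    *,
    k: int = 10,
    seed: int | None = None,
    table: RecodeTable | None = None,
) -> MetricsReport:
    """Cross-validate one scenario over a corpus.

    Records are assigned to k folds stratified on the ICCC subgroup; for
    each round the classifier is trained on the other folds restricted
    to the scenario's training population, and evaluated on the round's
    childhood (age 0-19) records. With ``uq_config``, one additional
    training fold is carved out per round, the confidence model is
    fitted on its childhood records, and abstained cases are excluded
    from the headline F1 (scores on all cases are reported alongside).
    """
    if isinstance(spec, str):
        spec = ScenarioSpec.from_id(spec)
    cnn_config = cnn_config if cnn_config is not None else CNNConfig()
    table = table if table is not None else fixture_table()
    seed = cnn_config.seed if seed is None else seed

    df = corpus.reset_index(drop=True).copy()
    for col in ("site", "histology", "behavior", "iccc_subgroup"):
        df[col] = df[col].astype(str)
    df["age"] = df["age"].astype(int)

    childhood = df["age"] <= CHILDHOOD_AGE_MAX
    ccdi = _is_ccdi_eligible(df["iccc_subgroup"], df["age"])
    if spec.training_population == "childhood+ccdi" and not ccdi.any():
        logger.warning(
            "scenario %s: corpus has no CCDI-eligible records; "
            "proceeding with a childhood-only training population",
            spec.scenario_id,
        )
    population = _population_mask(spec.training_population, childhood, ccdi)

    plan = stratified_folds(df["iccc_subgroup"].tolist(), k, seed)
    assign = plan.assignments
    class_list = sorted(set(df.loc[childhood, "iccc_subgroup"]))

    label_columns = (
        "iccc_subgroup" if spec.label_mode == "direct-iccc"
        else list(ICDO3_TASKS)
    )

    all_true: list[str] = []
    all_pred: list[str] = []
    all_retained: list[bool] = []
    train_sizes: list[int] = []
    for fold in range(k):
        test_mask = (assign == fold) & childhood.values
        train_mask = (assign != fold) & population.values
        cal_mask = None
        if uq_config is not None:
            cal_fold = (fold + 1) % k
            cal_mask = (assign == cal_fold) & childhood.values
            train_mask &= assign != cal_fold
        train_df = df[train_mask]
        train_sizes.append(len(train_df))
        clf = train(train_df, label_columns, cnn_config)

        test_df = df[test_mask]
        pred, scores = _predict_subgroups(
            clf, test_df["text"].tolist(), spec.label_mode, table
        )
        if uq_config is None:
            retained = [True] * len(test_df)
        else:
            cal_df = df[cal_mask]
            cal_pred, cal_scores = _predict_subgroups(
                clf, cal_df["text"].tolist(), spec.label_mode, table
            )
            samples = [
                CalibrationSample(float(s), p == t)
                for s, p, t in zip(
                    cal_scores, cal_pred, cal_df["iccc_subgroup"]
                )
            ]
            model = ConfidenceModel.fit(
                samples,
                tau=uq_config.tau,
                threshold=uq_config.threshold,
                score_mode=uq_config.score_mode,
            )
            if model.score_mode == "raw":
                conf = scores
            elif model.p_incorrect == 0.0:
                conf = np.ones(len(scores))
            elif model.p_correct == 0.0:
                conf = np.zeros(len(scores))
            else:
                conf = np.array(
                    [confidence_score(float(s), model) for s in scores]
                )
            retained = list(conf >= uq_config.threshold)

        all_true.extend(test_df["iccc_subgroup"].tolist())
        all_pred.extend(pred)
        all_retained.extend(retained)

    true_arr = np.asarray(all_true)
    pred_arr = np.asarray(all_pred)
    kept = np.asarray(all_retained, dtype=bool)

    per_class_f1, micro, macro = f1_scores(
        true_arr[kept].tolist(), pred_arr[kept].tolist(), class_list
    )
    _, micro_all, macro_all = f1_scores(
        true_arr.tolist(), pred_arr.tolist(), class_list
    )
    n_cases = {
        c: int((true_arr == c).sum()) for c in class_list
    }
    n_retained = {
        c: int(((true_arr == c) & kept).sum()) for c in class_list
    }
    rates = {
        c: abstention_rate(n_cases[c], n_retained[c])
        for c in class_list if n_cases[c] > 0
    }
    return MetricsReport(
        scenario_id=spec.scenario_id,
        class_list=class_list,
        per_class_f1=per_class_f1,
        micro_f1=micro,
        macro_f1=macro,
        n_cases=n_cases,
        n_retained=n_retained,
        abstention_rate_overall=abstention_rate(
            len(true_arr), int(kept.sum())
        ),
        abstention_rate_per_class=rates,
        micro_f1_all=micro_all,
        macro_f1_all=macro_all,
        train_sizes=train_sizes,
    )


SUMMARY_ROWS = ("micro_f1", "macro_f1")


def compare_reports(
    reports: Mapping[str, MetricsReport]
) -> pd.DataFrame:
    """Side-by-side per-class F1 table: classes as rows, scenarios as
    columns, micro/macro summary rows at the bottom."""
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    ids = list(reports)
    class_list = reports[ids[0]].class_list
    for sid in ids[1:]:
        if reports[sid].class_list != class_list:
            raise ValueError("reports cover different class lists")
    data = {
        sid: [reports[sid].per_class_f1[c] for c in class_list]
        + [reports[sid].micro_f1, reports[sid].macro_f1]
        for sid in ids
    }
    index = list(class_list) + list(SUMMARY_ROWS)
    frame = pd.DataFrame(data, index=index)
    frame.index.name = "code"
    return frame


def write_comparison(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", lineterminator="\n")


def read_comparison(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="code")
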